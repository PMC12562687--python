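import numpy as np
import pytest

from macrodomains import (
    GenomeLayout,
    SimParams,
    run_pipeline,
    simulate_study,
    write_simulation,
)


@pytest.fixture
def small_layout():
    """Two small chromosomes, one with a trailing short bin."""
    return GenomeLayout([("chr1", 5000), ("chr2", 4000)], bin_size=2000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (2 x 5 Mb, ratio 5, depth 30), seed 11."""
    return simulate_study(SimParams(seed=11))


@pytest.fixture(scope="session")
def default_run(default_study, tmp_path_factory):
    """Full pipeline run on the default study; returns (study, cfg, summary, outdir)."""
    root = tmp_path_factory.mktemp("study")
    cfg = write_simulation(default_study, root)
    summary = run_pipeline(cfg)
    return default_study, cfg, summary, root / "analysis"
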