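"""Per-bin enrichment of ChIP over input by one-sided Fisher's exact test.

Each 2 kb bin contributes a 2x2 table
``[[chip_k, chip_N - chip_k], [input_k, input_N - input_k]]`` where the
margins ``chip_N`` / ``input_N`` are the genome-wide library totals of
midpoint counts. The one-sided (greater) p-value is the hypergeometric tail
probability of seeing a ChIP-in-bin count at least as large as observed given
fixed margins; bins with p < alpha (default 0.05, unadjusted) are called
enriched. Only enrichment is tested — depletion of the histone variant is not
of interest here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .errors import InvalidParameterError, LayoutMismatchError
from .genome import BinCounts, GenomeLayout

__all__ = [
    "EnrichedBins",
    "fisher_bin_test",
    "call_enriched_bins",
    "benjamini_hochberg",
]


@dataclass
class EnrichedBins:
    """Per-bin p-values and significance calls for ChIP vs input."""

    layout: GenomeLayout
    pvalues: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05
    padj: np.ndarray | None = None
    chip_counts: np.ndarray | None = None
    input_counts: np.ndarray | None = None

    def __post_init__(self):
        n = self.layout.n_bins()
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.significant = np.asarray(self.significant, dtype=bool)
        if self.pvalues.shape != (n,) or self.significant.shape != (n,):
            raise LayoutMismatchError("p-values/flags do not match the bin grid")

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def _fisher_greater(chip_k, chip_N, input_k, input_N):
    """Vectorised one-sided (greater) Fisher p via the hypergeometric tail."""
    chip_k = np.asarray(chip_k, dtype=np.int64)
    input_k = np.asarray(input_k, dtype=np.int64)
    M = chip_N + input_N
    n = chip_k + input_k
    # P(X >= chip_k), X ~ Hypergeom(M, chip_N, n)
    return np.clip(hypergeom.sf(chip_k - 1, M, chip_N, n), 0.0, 1.0)


def fisher_bin_test(chip_k: int, chip_N: int, input_k: int, input_N: int) -> float:
    """One-sided (greater) Fisher exact p-value for a single bin.

    Probability, under the hypergeometric null with fixed margins, that the
    ChIP-in-bin count is >= ``chip_k``. ``chip_N``/``input_N`` are library
    totals.
    """
    if chip_N <= 0 or input_N <= 0:
        raise InvalidParameterError("library totals must be positive")
    if not (0 <= chip_k <= chip_N) or not (0 <= input_k <= input_N):
        raise InvalidParameterError("bin counts must lie within library totals")
    return float(_fisher_greater(chip_k, chip_N, input_k, input_N))


def call_enriched_bins(
    chip: BinCounts,
    input_: BinCounts,
    alpha: float = 0.05,
    adjust: str = "none",
) -> EnrichedBins:
    """Call enriched bins genome-wide.

    With ``adjust="none"`` (default) a bin is significant when its raw
    one-sided p < alpha; with ``adjust="BH"`` the Benjamini–Hochberg adjusted
    p is thresholded instead. Untestable bins (zero counts in both samples)
    get p = 1, are never significant, and are excluded from the BH family.
    """
    if chip.layout != input_.layout:
        raise LayoutMismatchError("ChIP and input are on different layouts")
    if chip.total <= 0 or input_.total <= 0:
        raise InvalidParameterError("both libraries must contain fragments")
    if not (0 < alpha <= 1):
        raise InvalidParameterError(f"alpha must be in (0, 1], got {alpha}")
    if adjust not in ("none", "BH"):
        raise InvalidParameterError(f"adjust must be 'none' or 'BH', got {adjust!r}")

    p = _fisher_greater(chip.counts, chip.total, input_.counts, input_.total)
    testable = (chip.counts > 0) | (input_.counts > 0)
    p = np.where(testable, p, 1.0)

    padj = None
    if adjust == "BH":
        padj = np.ones_like(p)
        padj[testable] = benjamini_hochberg(p[testable])
        significant = (padj < alpha) & testable
    else:
        significant = (p < alpha) & testable
    return EnrichedBins(
        layout=chip.layout,
        pvalues=p,
        significant=significant,
        alpha=alpha,
        padj=padj,
        chip_counts=chip.counts,
        input_counts=input_.counts,
    )


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH adjustment with monotonicity enforcement.

    Returns adjusted p-values in the input order, clipped to [0, 1] and
    guaranteed elementwise >= the input.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out
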