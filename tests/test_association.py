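"""Gene, expression, DEG, enhancer and ortholog association rules."""

import math

import numpy as np
import pandas as pd
import pytest

from macrodomains import (
    DomainSet,
    EnhancerSet,
    IntervalSet,
    associate_enhancers,
    compare_expression,
    compute_fpkm,
    deg_overlap,
    deposition_associated_genes,
    filter_degs,
    gene_coverage,
    intersect_ortholog_sets,
    link_enhancers_to_genes,
    partition_domains_genic,
)
from macrodomains.errors import FormatError, InvalidParameterError, InvalidRecordError


def gene_row(gene_id="g", chrom="c", start=0, end=5000, strand="+",
             biotype="protein_coding"):
    tss = start if strand == "+" else end - 1
    return pd.Series(dict(gene_id=gene_id, chrom=chrom, start=start, end=end,
                          strand=strand, biotype=biotype, tss=tss))


def gene_frame(rows):
    return pd.DataFrame([r.to_dict() for r in rows])


class TestGeneCoverage:
    def test_partial_overlap(self):
        g = gene_row(start=1000, end=6000)
        assert gene_coverage(g, DomainSet("m", [("c", 0, 4000)])) == pytest.approx(0.6)

    def test_fully_inside_domain(self):
        g = gene_row(start=1000, end=3000)
        assert gene_coverage(g, DomainSet("m", [("c", 0, 10_000)])) == 1.0

    def test_two_domains(self):
        g = gene_row(start=0, end=5000)
        d = DomainSet("m", [("c", 1000, 2000), ("c", 3000, 4000)])
        assert gene_coverage(g, d) == pytest.approx(0.4)

    def test_monotone_under_union_growth(self):
        g = gene_row(start=0, end=5000)
        small = DomainSet("m", [("c", 0, 1000)])
        big = DomainSet("m", [("c", 0, 1000), ("c", 2000, 3000)])
        assert gene_coverage(g, big) >= gene_coverage(g, small)


class TestDepositionAssociatedGenes:
    def test_strict_threshold_semantics(self):
        # coverage exactly 0.80 excluded, 0.81 included
        genes = gene_frame([
            gene_row("exact", start=0, end=10_000),
            gene_row("above", chrom="c2", start=0, end=10_000),
        ])
        d = DomainSet("m", [("c", 0, 8000), ("c2", 0, 8100)])
        res = deposition_associated_genes(genes, d).set_index("gene_id")
        assert res.loc["exact", "coverage"] == pytest.approx(0.80)
        assert not res.loc["exact", "associated"]
        assert res.loc["above", "associated"]

    def test_non_coding_genes_excluded(self):
        genes = gene_frame([
            gene_row("pc", start=0, end=1000),
            gene_row("nc", start=0, end=1000, biotype="lincRNA"),
        ])
        res = deposition_associated_genes(genes, DomainSet("m", [("c", 0, 2000)]))
        assert set(res["gene_id"]) == {"pc"}

    def test_empty_domain_set(self):
        genes = gene_frame([gene_row()])
        res = deposition_associated_genes(genes, DomainSet("m", []))
        assert not res["associated"].any()


class TestPartitionDomainsGenic:
    def test_domain_basis(self):
        genes = gene_frame([gene_row(start=0, end=3000)])
        d = DomainSet("x", [("c", 1000, 2000), ("c", 5000, 6000), ("c", 8000, 9000)])
        assert partition_domains_genic(d, genes) == pytest.approx((1 / 3, 2 / 3))

    def test_all_inside_one_gene(self):
        genes = gene_frame([gene_row(start=0, end=50_000)])
        d = DomainSet("x", [("c", 1000, 2000), ("c", 5000, 9000)])
        for basis in ("domain", "bp"):
            assert partition_domains_genic(d, genes, basis=basis) == (1.0, 0.0)

    def test_proportions_sum_to_one_and_match_mask(self):
        rng = np.random.default_rng(4)
        L = 50_000
        genes = gene_frame([
            gene_row(f"g{i}", start=int(s), end=int(s) + 3000)
            for i, s in enumerate(rng.integers(0, L - 3000, 5))
        ])
        d = DomainSet("x", [
            ("c", int(s), int(s) + 1500) for s in rng.integers(0, L - 1500, 12)
        ])
        gmask = np.zeros(L, dtype=bool)
        for _, g in genes.iterrows():
            gmask[g.start:g.end] = True
        for basis in ("domain", "bp"):
            genic, inter = partition_domains_genic(d, genes, basis=basis)
            assert genic + inter == pytest.approx(1.0)
        # bp basis equals mask arithmetic
        dmask = np.zeros(L, dtype=bool)
        for c, s, e in d:
            dmask[s:e] = True
        genic_bp, _ = partition_domains_genic(d, genes, basis="bp")
        assert genic_bp == pytest.approx((dmask & gmask).sum() / dmask.sum())

    def test_empty_set(self):
        assert partition_domains_genic(DomainSet("x", []), gene_frame([gene_row()])) \
            == (0.0, 0.0)


class TestComputeFpkm:
    def _genes(self):
        return gene_frame([gene_row("g1", start=0, end=2000),
                           gene_row("g2", start=0, end=4000)])

    def test_formula(self):
        counts = pd.DataFrame({"gene_id": ["g1", "g2"], "count": [100, 999_900]})
        res = compute_fpkm(counts, self._genes()).set_index("gene_id")
        assert res.loc["g1", "fpkm"] == pytest.approx(100 / (2.0 * 1.0))

    def test_scale_invariance(self):
        counts = pd.DataFrame({"gene_id": ["g1", "g2"], "count": [100, 300]})
        a = compute_fpkm(counts, self._genes())["fpkm"]
        counts2 = counts.assign(count=counts["count"] * 7)
        b = compute_fpkm(counts2, self._genes())["fpkm"]
        assert np.allclose(a, b)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"gene_id": ["g1", "g2"], "count": [0, 10]})
        res = compute_fpkm(counts, self._genes()).set_index("gene_id")
        assert res.loc["g1", "fpkm"] == 0.0

    def test_explicit_library_size(self):
        counts = pd.DataFrame({"gene_id": ["g1"], "count": [100]})
        genes = gene_frame([gene_row("g1", start=0, end=2000)])
        res = compute_fpkm(counts, genes, library_size=1_000_000)
        assert res["fpkm"].iloc[0] == pytest.approx(50.0)


class TestCompareExpression:
    def test_identical_groups(self):
        res = compare_expression([1, 2, 3], [1, 2, 3])
        assert res["t"] == 0.0 and res["pvalue"] == 1.0
        assert res["median_a"] == res["median_b"]

    def test_shifted_medians(self):
        res = compare_expression([1, 2, 3], [11, 12, 13])
        assert res["median_b"] - res["median_a"] == 10

    def test_welch_matches_textbook_formula(self):
        """4-vs-5 case: t and Welch–Satterthwaite df from the explicit formula."""
        a, b = [3.1, 4.5, 2.2, 5.0], [7.9, 8.4, 6.2, 9.9, 7.0]
        res = compare_expression(a, b, log_transform=False)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        se2 = va / 4 + vb / 5
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / 4) ** 2 / 3 + (vb / 5) ** 2 / 4)
        assert res["t"] == pytest.approx(t)
        assert res["df"] == pytest.approx(df)
        from scipy.stats import t as tdist
        assert res["pvalue"] == pytest.approx(2 * tdist.sf(abs(t), df))

    def test_fraction_above_one(self):
        res = compare_expression([0.5, 2.0, 3.0, 0.1], [0.2, 0.3], log_transform=False)
        assert res["frac_gt1_a"] == 0.5 and res["frac_gt1_b"] == 0.0

    def test_too_small_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            compare_expression([1.0], [1.0, 2.0])


class TestFilterDegs:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])

    def test_strict_inequalities(self):
        t = self._table([
            ("keep", 2.5, 0.005),
            ("lfc_exact", 2.0, 0.005),   # |log2FC| exactly 2 -> dropped
            ("padj_exact", 3.0, 0.01),   # Padj exactly 0.01 -> dropped
            ("down", -4.0, 1e-5),
        ])
        res = filter_degs(t)
        assert res["up"] == {"keep"}
        assert res["down"] == {"down"}
        assert res["all"] == {"keep", "down"}

    def test_empty_table(self):
        res = filter_degs(self._table([]))
        assert res["all"] == set()

    def test_missing_column_rejected(self):
        with pytest.raises(FormatError):
            filter_degs(pd.DataFrame({"gene_id": ["a"], "log2fc": [3.0]}))


class TestDegOverlap:
    def test_counts_and_fractions(self):
        res = deg_overlap({"a", "b"}, {"b", "c", "d"}, {"a", "b", "c", "d", "e"})
        assert res["n_overlap"] == 1
        assert res["frac_of_associated"] == pytest.approx(1 / 3)
        assert res["frac_deg_of_expressed"] == pytest.approx(2 / 5)

    def test_disjoint_and_subset(self):
        assert deg_overlap({"a"}, {"b"}, {"a", "b"})["n_overlap"] == 0
        res = deg_overlap({"a", "b", "c"}, {"a", "b"}, {"a", "b", "c"})
        assert res["frac_of_associated"] == 1.0

    def test_empty_associated_flagged(self):
        res = deg_overlap({"a"}, set(), {"a"})
        assert res["frac_of_associated"] == 0.0 and res["empty_associated"]


class TestAssociateEnhancers:
    def _run(self, enh_iv, acc_iv, mito_iv, **kw):
        enh = EnhancerSet(pd.DataFrame(enh_iv, columns=["chrom", "start", "end"]))
        return associate_enhancers(enh, IntervalSet(acc_iv),
                                   DomainSet("m", mito_iv), **kw)

    def test_accessible_covered_kept(self):
        res = self._run([("c", 1000, 1600)], [("c", 900, 1700)], [("c", 0, 4000)])
        assert res["associated"].tolist() == [True]

    def test_accessible_uncovered_dropped(self):
        res = self._run([("c", 1000, 1600)], [("c", 900, 1700)], [("c", 8000, 9000)])
        assert res["associated"].tolist() == [False]

    def test_inaccessible_covered_dropped(self):
        res = self._run([("c", 1000, 1600)], [], [("c", 0, 4000)])
        assert res["associated"].tolist() == [False]

    def test_half_coverage_rule(self):
        # 600 bp enhancer, 300 bp covered: kept at cover_min=0.5, not at full
        enh = [("c", 1000, 1600)]
        acc = [("c", 0, 5000)]
        mito = [("c", 1300, 5000)]
        assert self._run(enh, acc, mito)["associated"].tolist() == [True]
        assert self._run(enh, acc, mito, mode="full")["associated"].tolist() == [False]
        assert self._run(enh, acc, mito, mode="any")["associated"].tolist() == [True]


class TestLinkEnhancersToGenes:
    def _genes(self, tss=200_000):
        return gene_frame([gene_row("g", start=tss, end=tss + 5000)])

    def _enh(self, mid):
        return pd.DataFrame({"chrom": ["c"], "start": [mid - 300], "end": [mid + 300]})

    @pytest.mark.parametrize("mid,linked", [
        (90_000, True),        # 110 kb away
        (50_000, False),       # 150 kb away
        (75_000, True),        # exactly at TSS - 125 kb: closed interval
        (325_000, True),       # exactly at TSS + 125 kb
        (325_001, False),
    ])
    def test_window_boundaries(self, mid, linked):
        links, frac = link_enhancers_to_genes(self._enh(mid), self._genes())
        assert (len(links) == 1) is linked
        assert frac == (1.0 if linked else 0.0)

    def test_many_to_many(self):
        genes = gene_frame([gene_row("g1", start=10_000, end=12_000),
                            gene_row("g2", start=20_000, end=22_000)])
        enh = pd.DataFrame({"chrom": ["c", "c"], "start": [14_000, 15_000],
                            "end": [14_600, 15_600]})
        links, frac = link_enhancers_to_genes(enh, genes, window=125_000)
        assert len(links) == 4 and frac == 1.0


class TestIntersectOrthologSets:
    def _map(self, pairs):
        return pd.DataFrame(pairs, columns=["a", "b"])

    def test_basic(self):
        res = intersect_ortholog_sets({"g1", "g2"}, {"h1"}, self._map([("g1", "h1")]))
        assert res["shared"] == {("g1", "h1")}
        assert res["a_unique"] == {"g2"} and res["b_unique"] == set()

    def test_empty_map(self):
        res = intersect_ortholog_sets({"g1"}, {"h1"}, self._map([]))
        assert res["shared"] == set()

    def test_identity_map(self):
        ids = {"x", "y"}
        res = intersect_ortholog_sets(ids, ids, self._map([("x", "x"), ("y", "y")]))
        assert res["shared"] == {("x", "x"), ("y", "y")}
        assert not res["a_unique"] and not res["b_unique"]

    def test_duplicate_mapping_strict_error(self):
        with pytest.raises(FormatError):
            intersect_ortholog_sets(
                {"g1"}, {"h1"}, self._map([("g1", "h1"), ("g1", "h2")]))
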