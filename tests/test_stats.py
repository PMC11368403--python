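import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

from napscape.consensus import ConsensusSummits
from napscape.genome import GenomeAssembly, IntervalSet, Replicon
from napscape.occupancy import OccupancyCall
from napscape.stats import (
    bh_fdr,
    class_enrichment,
    fisher_exact,
    occupancy_expression_shift,
    rank_shift_test,
    summit_region_association,
)


def oracle_p(a, b, c, d):
    """Two-sided p by explicit enumeration of the hypergeometric support."""
    m, n, k = a + b, c + d, a + c
    xs = np.arange(max(0, k - n), min(k, m) + 1)
    pmf = hypergeom.pmf(xs, m + n, m, k)
    return min(1.0, pmf[pmf <= hypergeom.pmf(a, m + n, m, k) * (1 + 1e-7)].sum())


def oracle_cmle(a, b, c, d, grid=None):
    """Arg-max of the noncentral hypergeometric likelihood on a log grid."""
    m, n, k = a + b, c + d, a + c
    xs = np.arange(max(0, k - n), min(k, m) + 1)
    if len(xs) == 1:
        return np.nan
    if a == xs[0]:
        return 0.0
    if a == xs[-1]:
        return np.inf
    grid = grid if grid is not None else np.linspace(-12, 12, 40_001)
    logw = (
        np.log(comb(m, xs))[None, :]
        + np.log(comb(n, k - xs))[None, :]
        + np.outer(grid, xs)
    )
    loglik = a * grid - np.log(np.exp(logw - logw.max(axis=1, keepdims=True)).sum(axis=1)) \
        - logw.max(axis=1)
    return float(np.exp(grid[np.argmax(loglik)]))


class TestFisherExact:
    def test_symmetric_null(self):
        r = fisher_exact([[5, 5], [5, 5]])
        assert r.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert r.p_value == pytest.approx(1.0)

    def test_perfect_separation(self):
        r = fisher_exact([[10, 0], [0, 10]])
        assert r.p_value == pytest.approx(2 / comb(20, 10))
        assert r.odds_ratio == np.inf

    def test_worked_table_against_oracles(self):
        r = fisher_exact([[1, 9], [11, 3]])
        assert r.p_value == pytest.approx(oracle_p(1, 9, 11, 3), abs=1e-12)
        assert r.odds_ratio == pytest.approx(oracle_cmle(1, 9, 11, 3), rel=1e-3)
        assert r.or_sample == pytest.approx(3 / 99)

    def test_enumeration_equivalence_small_margins(self):
        for m in range(0, 9):
            for n in range(0, 9):
                for a in range(m + 1):
                    for c in range(n + 1):
                        r = fisher_exact([[a, m - a], [c, n - c]])
                        assert r.p_value == pytest.approx(
                            oracle_p(a, m - a, c, n - c), abs=1e-12
                        )

    def test_cmle_matches_grid_oracle_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 16, 4)
            r = fisher_exact([[a, b], [c, d]])
            expect = oracle_cmle(a, b, c, d)
            if np.isnan(expect):
                assert np.isnan(r.odds_ratio)
            elif np.isinf(expect) or expect == 0.0:
                assert r.odds_ratio == expect
            else:
                assert r.odds_ratio == pytest.approx(expect, rel=2e-3)

    def test_column_swap_inverts_or_preserves_p(self):
        r = fisher_exact([[3, 7], [9, 2]])
        swapped = fisher_exact([[7, 3], [2, 9]])
        assert swapped.p_value == pytest.approx(r.p_value, abs=1e-12)
        assert swapped.odds_ratio == pytest.approx(1 / r.odds_ratio, rel=1e-6)

    def test_transpose_preserves_or_and_p(self):
        r = fisher_exact([[3, 7], [9, 2]])
        t = fisher_exact([[3, 9], [7, 2]])
        assert t.p_value == pytest.approx(r.p_value, abs=1e-12)
        assert t.odds_ratio == pytest.approx(r.odds_ratio, rel=1e-6)

    def test_matches_r_fisher_test(self):
        """Independent cross-check against the reference R implementation."""
        tables = [(1, 9, 11, 3), (5, 2, 3, 8), (12, 4, 7, 9), (2, 0, 5, 6)]
        rscript = "\n".join(
            f"r <- fisher.test(matrix(c({a},{c},{b},{d}), nrow=2)); "
            f"cat(sprintf('%.10g %.10g\\n', r$p.value, r$estimate))"
            for a, b, c, d in tables
        )
        proc = subprocess.run(["Rscript", "-e", rscript],
                              capture_output=True, text=True, check=True)
        lines = proc.stdout.strip().splitlines()
        for (a, b, c, d), line in zip(tables, lines):
            p_r, or_r = map(float, line.split())
            res = fisher_exact([[a, b], [c, d]])
            assert res.p_value == pytest.approx(p_r, rel=1e-6)
            assert res.odds_ratio == pytest.approx(or_r, rel=1e-3)  # R uniroot default tol

    @pytest.mark.parametrize("bad", [[[1, -2], [3, 4]], [[0.5, 1], [2, 3]]])
    def test_rejects_invalid_cells(self, bad):
        with pytest.raises(ValueError):
            fisher_exact(bad)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.005, 0.04, 0.9], [0.015, 0.06, 0.9]),
            ([0.2], [0.2]),
        ],
    )
    def test_closed_form(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    def test_permutation_equivariance_and_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert bh_fdr(p[perm]) == pytest.approx(bh_fdr(p)[perm])
        assert (bh_fdr(p) >= p).all()


class TestRankShift:
    def test_identical_groups(self):
        assert rank_shift_test(np.ones(6), np.ones(9)) == 1.0

    def test_complete_separation_exact(self):
        p = rank_shift_test(np.array([1., 2, 3, 4]), np.array([10., 11, 12, 13]))
        assert p == pytest.approx(2 / comb(8, 4))

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        calls = (
            [OccupancyCall(f"n{i}", "not_bound", 0.0) for i in range(40)]
            + [OccupancyCall(f"p{i}", "partial", 0.5) for i in range(40)]
            + [OccupancyCall(f"e{i}", "entire", 1.0) for i in range(40)]
        )
        lfc = pd.Series(
            {c.feature_id: (1.0 if c.klass == "entire" else 0.0)
             + rng.normal(0, 0.3) for c in calls}
        )
        out = occupancy_expression_shift(calls, lfc)
        row = out[(out.group1 == "not_bound") & (out.group2 == "entire")].iloc[0]
        assert row["flag"] == "shifted"
        same = out[(out.group1 == "not_bound") & (out.group2 == "partial")].iloc[0]
        assert same["fdr"] > row["fdr"]


class TestClassEnrichment:
    def _calls(self, bound_ids, unbound_ids):
        return [OccupancyCall(g, "entire", 1.0) for g in bound_ids] + [
            OccupancyCall(g, "not_bound", 0.0) for g in unbound_ids
        ]

    def test_class_identical_to_reference_is_null(self):
        genes = [f"g{i}" for i in range(40)]
        classes = pd.Series("transient", index=genes)
        calls = self._calls(genes[:10], genes[10:])
        out = class_enrichment(classes, calls, genes, which=["transient"])
        assert out.loc[0, "or_cmle"] == pytest.approx(1.0, abs=1e-6)
        assert out.loc[0, "flag"] == "ns"

    def test_empty_class_errors(self):
        classes = pd.Series("transient", index=["g0"])
        with pytest.raises(ValueError, match="empty margin"):
            class_enrichment(classes, self._calls(["g0"], []), ["g0"],
                             which=["late"])

    def test_planted_enrichment_flagged(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(300)]
        classes = pd.Series("plateau", index=genes)
        transient = genes[:30]
        classes[transient] = "transient"
        bound = [g for g in genes
                 if rng.random() < (0.9 if g in transient else 0.3)]
        calls = self._calls(bound, [g for g in genes if g not in bound])
        out = class_enrichment(classes, calls, genes,
                               which=["transient", "plateau"])
        flags = dict(zip(out["comparison"], out["flag"]))
        assert flags["transient"] == "enriched"


class TestSummitRegionAssociation:
    def _setup(self, positions, region_span):
        asm = GenomeAssembly([Replicon("chr", "A" * 10_000)])
        cons = ConsensusSummits(summits=[("chr", p) for p in positions])
        return cons, IntervalSet([("chr", *region_span)]), asm

    def test_all_summits_free_half_genome_covered(self):
        cons, regions, asm = self._setup(range(100, 5000, 400), (5000, 10_000))
        res = summit_region_association(cons, regions, asm)
        assert res.odds_ratio == np.inf

    def test_uniform_summits_near_null(self):
        rng = np.random.default_rng(19)
        cons, regions, asm = self._setup(
            sorted(rng.integers(0, 10_000, 60)), (0, 5000)
        )
        res = summit_region_association(cons, regions, asm)
        assert res.p_value > 0.05

    def test_planted_exclusion_orders_odds_ratios(self, small_study):
        from napscape.consensus import merge_summits

        assembly, _, truth, chip = small_study
        ors = {}
        for factor in ("SigE", "SigA"):
            cons = merge_summits(
                chip.candidate_summits[factor]["rep1"],
                chip.candidate_summits[factor]["rep2"],
                chip.control_summits,
            )
            ors[factor] = summit_region_association(
                cons, truth.nap_regions, assembly
            ).odds_ratio
        assert ors["SigE"] > ors["SigA"] > 1.0
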