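"""Rank-sum, overlap, density, and enrichment statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from essefate.stats import (
    bh_adjust,
    gene_set_enrichment,
    kde_density,
    venn_overlap_p,
    wilcoxon_rank_sum,
)

from oracles import enum_overlap_tails, enum_rank_sum_p


class TestWilcoxon:
    def test_most_extreme_ranking_exact_p(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)  # 2 * 1/20

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 3], [3, 2, 1, 2])
        assert p == 1.0

    def test_normal_approximation_close_to_exact_at_6_plus_6(self):
        # worst-case deviation of the continuity-corrected approximation
        # from full enumeration over every attainable statistic at 6+6 is
        # 0.0155 (computed by the enumeration oracle); check every case
        for w in range(21, 58):
            p_exact = enum_rank_sum_p(12, 6, w)
            mean, var = 6 * 13 / 2, 6 * 6 * 13 / 12
            z = (w - mean - np.sign(w - mean) * 0.5) / np.sqrt(var)
            p_approx = min(1.0, 2 * sps.norm.sf(abs(z)))
            assert abs(p_approx - p_exact) <= 0.016

    def test_ties_use_midranks_and_tie_corrected_variance(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0]
        y = [2.0, 4.0, 4.0, 4.0, 8.0, 9.0, 10.0]
        w, p = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        # our W = U + nx(nx+1)/2; p should agree with the tie-corrected normal
        assert w == pytest.approx(ref.statistic + 7 * 8 / 2)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(1, 1, size=9)
        w1, p1 = wilcoxon_rank_sum(x, y)
        w2, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert (w1, p1) == (w2, p2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestVennOverlap:
    def test_complete_overlap_small_universe(self):
        t = venn_overlap_p(2, 2, 2, 4)
        assert t.p_enrich == pytest.approx(1 / 6)
        assert t.expected == pytest.approx(1.0)

    def test_degenerate_empty_set(self):
        t = venn_overlap_p(0, 0, 5, 10)
        assert t.p_enrich == 1.0

    def test_expected_chance_intersection(self):
        assert venn_overlap_p(10, 100, 200, 1000).expected == pytest.approx(20.0)

    def test_impossible_k_rejected(self):
        with pytest.raises(ValueError):
            venn_overlap_p(3, 2, 5, 10)
        with pytest.raises(ValueError):
            venn_overlap_p(0, 8, 8, 10)  # minimum intersection is 6

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_on_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            N = int(rng.integers(1, 11))
            n_a, n_b = int(rng.integers(0, N + 1)), int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n_a + n_b - N), min(n_a, n_b) + 1))
            t = venn_overlap_p(k, n_a, n_b, N)
            p_ge, p_le = enum_overlap_tails(k, n_a, n_b, N)
            assert t.p_enrich == pytest.approx(p_ge, abs=1e-12)
            assert t.p_deplete == pytest.approx(p_le, abs=1e-12)


class TestKde:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        grid, dens = kde_density(rng.normal(size=300))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_input_gives_symmetric_curve(self):
        vals = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        grid, dens = kde_density(vals, bandwidth=0.5, n_grid=501)
        assert np.max(np.abs(dens - dens[::-1])) <= 1e-9

    def test_constant_input_requires_explicit_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kde_density([1.0, 1.0, 1.0])
        grid, dens = kde_density([1.0, 1.0, 1.0], bandwidth=0.2)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_scaling_values_scales_mode_location(self):
        vals = np.array([0.5, 1.0, 1.0, 1.5])
        g1, d1 = kde_density(vals, bandwidth=0.1)
        g2, d2 = kde_density(2 * vals, bandwidth=0.2)
        assert g2[np.argmax(d2)] == pytest.approx(2 * g1[np.argmax(d1)], rel=1e-6)


class TestEnrichment:
    def test_planted_set_is_strongly_enriched(self):
        bg = {f"g{i}" for i in range(1000)}
        fg = {f"g{i}" for i in range(10)}
        coll = {"S": set(fg) | {f"g{i}" for i in range(900, 990)}}
        (r,) = gene_set_enrichment(fg, bg | fg, coll)
        assert r.k_fg == 10
        assert r.p < 1e-6

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(2000)]
        bg = set(universe)
        fg = set(rng.choice(universe, size=500, replace=False))
        coll = {
            f"s{j}": set(rng.choice(universe, size=400, replace=False))
            for j in range(1000)
        }
        ps = [r.p for r in gene_set_enrichment(fg, bg, coll)]
        assert sps.kstest(ps, "uniform").statistic <= 0.1

    def test_disjoint_set_skipped_with_warning(self, caplog):
        fg, bg = {"A"}, {"A", "B"}
        coll = {"S": {"Z"}, "T": {"A"}}
        with caplog.at_level("WARNING"):
            res = gene_set_enrichment(fg, bg, coll)
        assert [r.set_name for r in res] == ["T"]
        assert "disjoint" in caplog.text

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"A"}, {"A"}, {})

    def test_restrict_mode_intersects_foreground_into_background(self):
        fg, bg = {"A", "X"}, {"A", "B", "C"}
        (r,) = gene_set_enrichment(fg, bg, {"S": {"A", "B"}},
                                   restrict_fg_to_bg=True)
        assert r.n_fg == 1  # X dropped


class TestBh:
    def test_q_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)
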