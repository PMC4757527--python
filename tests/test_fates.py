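"""Methylation contrasts, fate classes, and analysis-set builders."""

import numpy as np
import pandas as pd
import pytest

from essefate.fates import (
    EsseSetPartition,
    background_hyper_distal,
    classify_fate,
    contrast,
    foreground_hyper_esse,
    fraction_report,
    mean_beta,
    partition_esse_fates,
    reprogrammed_hypo_esse,
    undermethylated,
)
from essefate.io import MethylationMatrix


def make_matrix(beta_dict, cell_types):
    beta = pd.DataFrame(beta_dict)
    beta.index = [f"cg{i}" for i in range(len(beta))]
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(len(beta)) * 1000 + 100},
        index=beta.index,
    )
    samples = pd.DataFrame(
        {"cell_type": [cell_types[c] for c in beta.columns],
         "stage": [cell_types[c] for c in beta.columns]},
        index=beta.columns,
    )
    return MethylationMatrix(sites=sites, samples=samples, beta=beta)


class TestMeanBeta:
    def test_replicate_average_and_pairwise_missing(self):
        m = make_matrix(
            {"a1": [0.2, 0.5, np.nan], "a2": [0.4, np.nan, np.nan]},
            {"a1": "ES", "a2": "ES"},
        )
        mb = mean_beta(m, "ES")
        assert mb["cg0"] == pytest.approx(0.3)
        assert mb["cg1"] == pytest.approx(0.5)
        assert np.isnan(mb["cg2"])

    def test_unknown_cell_type_rejected(self):
        m = make_matrix({"a1": [0.2]}, {"a1": "ES"})
        with pytest.raises(ValueError):
            mean_beta(m, "HSC")


class TestFateClass:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (-0.30, "hypomethylated"),
            (-0.20, "hypomethylated"),
            (0.20, "hypermethylated"),
            (0.15, "stable"),
            (-0.19999, "stable"),
            (0.0, "stable"),
        ],
    )
    def test_inclusive_20_percent_boundaries(self, delta, expected):
        assert classify_fate(delta) == expected

    def test_missing_delta_gives_none(self):
        assert classify_fate(float("nan")) is None

    def test_antisymmetry_under_stage_swap(self):
        rng = np.random.default_rng(0)
        m = make_matrix(
            {"e1": rng.uniform(0, 1, 50), "l1": rng.uniform(0, 1, 50)},
            {"e1": "A", "l1": "B"},
        )
        fwd = classify_fate(contrast(m, "A", "B")["delta"])
        rev = classify_fate(contrast(m, "B", "A")["delta"])
        swap = {"hypomethylated": "hypermethylated",
                "hypermethylated": "hypomethylated", "stable": "stable"}
        assert list(rev) == [swap[f] for f in fwd]

    def test_fates_partition_nonmissing_sites(self):
        rng = np.random.default_rng(1)
        deltas = pd.Series(rng.uniform(-1, 1, 200))
        labels = classify_fate(deltas)
        assert labels.isin(
            ["hypomethylated", "hypermethylated", "stable"]
        ).all()


class TestUndermethylated:
    def test_inclusive_half_boundary(self):
        assert undermethylated(0.50) is True
        assert undermethylated(0.51) is False
        assert undermethylated(0.0) is True

    def test_missing_scalar_rejected(self):
        with pytest.raises(ValueError):
            undermethylated(float("nan"))


class TestFractionReport:
    def test_two_equal_counts(self):
        assert fraction_report({"a": 1, "b": 1}) == {"a": 50.0, "b": 50.0}

    def test_rounded_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = {f"c{i}": int(v) for i, v in
                      enumerate(rng.integers(1, 10_000, size=3))}
            assert sum(fraction_report(counts).values()) == pytest.approx(
                100.0, abs=0.1
            )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fraction_report({"a": 0})


class TestPartition:
    def test_hand_counted_partition(self):
        deltas = [-0.3] * 3 + [0.25] * 2 + [0.0] * 5
        cdf = pd.DataFrame(
            {"beta_early": 0.5, "beta_late": 0.5,
             "delta": pd.Series(deltas, index=[f"cg{i}" for i in range(10)])}
        )
        part = partition_esse_fates(set(cdf.index), cdf)
        assert (len(part.hypo), len(part.hyper), len(part.stable)) == (3, 2, 5)
        assert part.fractions == {
            "hypomethylated": 30.0, "hypermethylated": 20.0, "stable": 50.0
        }

    def test_empty_esse_set_reports_missing_fractions(self):
        cdf = pd.DataFrame({"beta_early": [], "beta_late": [], "delta": []})
        part = partition_esse_fates(set(), cdf)
        assert part.hypo == part.hyper == part.stable == set()
        assert part.fractions is None

    def test_universe_mismatch_rejected(self):
        cdf = pd.DataFrame(
            {"beta_early": [0.5], "beta_late": [0.5], "delta": [0.0]},
            index=["cg0"],
        )
        with pytest.raises(ValueError, match="universe"):
            partition_esse_fates({"cg0", "cgX"}, cdf)

    def test_overlapping_fate_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            EsseSetPartition(hypo={"a"}, hyper={"a"}, stable=set())

    def test_planted_cohort_counts_match_generator_truth(self, study):
        table, truth = study["table"], study["truth"]
        esse_classes = {"esse_hypo_in_cancer", "esse_hyper_in_cancer",
                        "esse_stable"}
        planted = {
            s["site_id"]: s["class"] for s in truth["sites"]
            if s["class"] in esse_classes
        }
        cdf = pd.DataFrame(
            {"beta_early": table["beta_TCELL"], "beta_late": table["beta_CANCER"],
             "delta": table["delta_cancer"]}
        )
        part = partition_esse_fates(set(planted), cdf)
        truth_hypo = {s for s, c in planted.items() if c == "esse_hypo_in_cancer"}
        truth_hyper = {s for s, c in planted.items() if c == "esse_hyper_in_cancer"}
        # recovery of planted fates is essentially perfect at these effect sizes
        assert len(part.hypo ^ truth_hypo) <= 0.05 * len(truth_hypo)
        assert len(part.hyper ^ truth_hyper) <= 0.05 * len(truth_hyper)


class TestSetBuilders:
    def setup_method(self):
        ids = [f"cg{i}" for i in range(4)]
        self.esse = set(ids[:3])
        self.distal = set(ids)
        self.normals = {
            "ES": pd.Series([0.1, 0.1, 0.6, 0.1], index=ids),
            "TCELL": pd.Series([0.2, 0.2, 0.2, 0.2], index=ids),
        }
        self.cancer = pd.DataFrame(
            {"delta": pd.Series([0.4, 0.1, 0.5, 0.6], index=ids)}
        )
        self.dev = pd.DataFrame(
            {"delta": pd.Series([0.3, 0.3, 0.0, 0.0], index=ids)}
        )

    def test_foreground_requires_all_normals_unmethylated_and_cancer_hyper(self):
        fg = foreground_hyper_esse(self.esse, self.normals, self.cancer)
        assert fg == {"cg0"}  # cg1 not hyper; cg2 methylated in ES

    def test_background_is_all_cancer_hyper_distal_sites(self):
        bg = background_hyper_distal(self.distal, self.cancer)
        assert bg == {"cg0", "cg2", "cg3"}

    def test_foreground_subset_of_background(self):
        fg = foreground_hyper_esse(self.esse, self.normals, self.cancer)
        bg = background_hyper_distal(self.distal, self.cancer)
        assert fg <= bg

    def test_reprogrammed_set_needs_dev_gain_and_cancer_loss(self):
        cancer = pd.DataFrame(
            {"delta": pd.Series([-0.4, -0.4, 0.0, 0.0],
                                index=[f"cg{i}" for i in range(4)])}
        )
        out = reprogrammed_hypo_esse(self.esse, self.dev, cancer)
        assert out == {"cg0", "cg1"}
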