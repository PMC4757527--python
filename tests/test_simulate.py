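"""Synthetic-study generator: determinism, planted contracts, limits."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from essefate.chromatin import score_sites, state_table
from essefate.fates import classify_fate, contrast
from essefate.simulate import (
    BETA_MEANS,
    SimulationConfig,
    generate_beta,
    generate_study,
    sample_transition_classes,
    simulate_fate_cohort,
    simulate_mark_cohort,
)


def checksums(d: Path) -> dict:
    return {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(d.iterdir())
        if f.is_file()
    }


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        generate_study(SimulationConfig(seed=17), tmp_path / "a")
        generate_study(SimulationConfig(seed=17), tmp_path / "b")
        assert checksums(tmp_path / "a") == checksums(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        generate_study(SimulationConfig(seed=17), tmp_path / "a")
        generate_study(SimulationConfig(seed=18), tmp_path / "b")
        a, b = checksums(tmp_path / "a"), checksums(tmp_path / "b")
        assert a["methylation.tsv"] != b["methylation.tsv"]


class TestBetaDraws:
    def test_vanishing_variance_concentrates_on_mean(self):
        cfg = SimulationConfig(beta_concentration=1e6)
        rng = np.random.default_rng(0)
        draws = [
            generate_beta("esse_hypo_in_cancer", "HSC", cfg, rng)
            for _ in range(50)
        ]
        assert np.allclose(draws, 0.75, atol=0.01)

    def test_cancer_hyper_esse_starts_unmethylated_in_es(self):
        assert BETA_MEANS["esse_hyper_in_cancer"]["ES"] <= 0.5
        for ct in ("ES", "HSC", "TCELL"):
            assert BETA_MEANS["esse_hyper_in_cancer"][ct] <= 0.5

    def test_seeded_draws_reproduce(self):
        cfg = SimulationConfig()
        a = [generate_beta("promoter", "ES", cfg, np.random.default_rng(5))
             for _ in range(3)]
        b = [generate_beta("promoter", "ES", cfg, np.random.default_rng(5))
             for _ in range(3)]
        assert a == b


class TestTransitionCohort:
    def test_fractions_converge_within_binomial_99_ci(self):
        fracs = np.array([0.615, 0.256, 0.129])
        n = 5_000
        labels = sample_transition_classes(n, fracs, np.random.default_rng(1))
        for frac, label in zip(fracs, ("lose", "retain", "gain")):
            observed = np.mean(labels == label)
            half = 2.576 * np.sqrt(frac * (1 - frac) / n)
            assert abs(observed - frac) <= half

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            sample_transition_classes(10, [0.5, 0.2], np.random.default_rng(0))


class TestNoiselessLimit:
    def test_zero_noise_recovers_all_planted_labels(self, tmp_path):
        cfg = SimulationConfig(seed=3, noise_sd=0.0, beta_concentration=1e6)
        paths, truth = generate_study(cfg, tmp_path / "s")
        from essefate.io import read_site_table
        from essefate.pipeline import PipelineConfig, run_pipeline, score_recovery

        pcfg = PipelineConfig.for_study(tmp_path / "s", tmp_path / "o", seed=3)
        run_pipeline(pcfg)
        rec = score_recovery(
            pcfg, read_site_table(pcfg.out("site_table.tsv")), truth
        )
        assert rec["overall_concordance"] == 1.0


class TestMarkCohort:
    def test_offset_peak_still_caught_by_max_rule(self):
        # a peak shifted 80 bp off the probe stays inside the +/-100 window
        cfg = SimulationConfig(peak_offset=80)
        tracks, sites, truth = simulate_mark_cohort(
            n_sites=100, n_samples=2, seed=4, config=cfg
        )
        scores = score_sites(tracks, sites)
        states = state_table(
            scores, {s: "CT" for s in scores.columns}
        )["CT"]
        concordance = float(np.mean(states.to_numpy() == truth.to_numpy()))
        assert concordance >= 0.95


class TestFateCohort:
    def test_planted_and_null_sites_separate(self):
        matrix, planted = simulate_fate_cohort(n_sites=500, seed=6)
        cdf = contrast(matrix, "early", "late")
        labels = classify_fate(cdf["delta"])
        hypo = labels == "hypomethylated"
        assert (hypo & planted).sum() / planted.sum() >= 0.95
        assert (hypo & ~planted).sum() / (~planted).sum() <= 0.05


def test_capacity_overflow_rejected():
    with pytest.raises(ValueError, match="loci"):
        SimulationConfig(
            chrom_lengths={"chr1": 120_000},
            class_counts={"promoter": 100},
        )


def test_truth_manifest_covers_every_emitted_site(study):
    truth, table = study["truth"], study["table"]
    manifest_ids = {s["site_id"] for s in truth["sites"]}
    assert manifest_ids == set(table.index)
    counts = pd.Series([s["class"] for s in truth["sites"]]).value_counts()
    cfg_counts = truth["config"]["class_counts"]
    assert counts.to_dict() == {k: v for k, v in cfg_counts.items() if v}
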