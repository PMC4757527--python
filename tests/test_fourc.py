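"""4C sliding-window profiles and differential interaction."""

import numpy as np
import pytest

from essefate.fourc import (
    FourCProfile,
    differential_interaction,
    make_windows,
    mapping_summary,
    window_percent_reads,
)
from essefate.intervals import GenomeInterval

BAIT = GenomeInterval("chr1", 500_000, 500_001)


def profile(positions, total=None, cell="a"):
    return FourCProfile(
        cell_type=cell, bait=BAIT,
        reads={"chr1": np.asarray(positions, dtype=np.int64)},
        total_reads=total,
    )


class TestWindows:
    def test_tiling_width_and_step(self):
        region = GenomeInterval("chr1", 10_000, 20_000)
        ws = make_windows(region)
        assert all(len(w) == 1_000 for w in ws)
        starts = [w.start for w in ws]
        assert starts[0] == 10_000
        assert all(b - a == 500 for a, b in zip(starts, starts[1:]))
        assert ws[-1].end <= region.end

    def test_region_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            make_windows(GenomeInterval("chr1", 0, 800))


class TestPercentReads:
    def test_point_mass_fills_both_covering_windows(self):
        p = profile([10_700] * 10)
        wp = window_percent_reads(p, GenomeInterval("chr1", 10_000, 12_000))
        full = [w.start for w, pc in zip(wp.windows, wp.percent_reads)
                if pc == 100.0]
        assert full == [10_000, 10_500]  # the two windows containing 10,700
        assert all(pc in (0.0, 100.0) for pc in wp.percent_reads)

    def test_uniform_read_grid_hand_count(self):
        # one read every 100 bp in [0, 10000): every window holds 10 reads
        reads = np.arange(0, 10_000, 100)
        p = profile(reads)
        wp = window_percent_reads(
            p, GenomeInterval("chr1", 0, 10_000), denominator="region"
        )
        assert np.allclose(wp.percent_reads, 10.0)

    def test_read_at_window_end_counts_in_next_window_only(self):
        p = profile([11_000])
        wp = window_percent_reads(p, GenomeInterval("chr1", 10_000, 13_000))
        by_start = dict(zip((w.start for w in wp.windows), wp.counts))
        assert by_start[10_000] == 0  # [10000, 11000) excludes 11000
        assert by_start[10_500] == 1
        assert by_start[11_000] == 1

    def test_overlapping_windows_double_count_interior_reads(self):
        rng = np.random.default_rng(0)
        region = GenomeInterval("chr1", 100_000, 150_000)
        # keep reads out of the half-window edges of the region
        reads = rng.integers(region.start + 500, region.end - 500, size=2_000)
        wp = window_percent_reads(profile(np.sort(reads)), region)
        assert wp.counts.sum() == 2 * len(reads)

    def test_genome_wide_denominator_by_default(self):
        p = profile([10_100] * 25 + [900_000] * 75)  # 75 reads off-region
        wp = window_percent_reads(p, GenomeInterval("chr1", 10_000, 12_000))
        assert wp.percent_reads.max() == pytest.approx(25.0)

    def test_no_mapped_reads_rejected(self):
        with pytest.raises(ValueError):
            window_percent_reads(
                FourCProfile("a", BAIT, {}),
                GenomeInterval("chr1", 0, 10_000),
            )


class TestDifferential:
    def windows(self, percents, cell="a"):
        region = GenomeInterval("chr1", 0, 1_000 + 500 * (len(percents) - 1))
        ws = make_windows(region)
        assert len(ws) == len(percents)
        from essefate.fourc import WindowProfile

        arr = np.asarray(percents, dtype=float)
        return WindowProfile(cell_type=cell, windows=ws,
                             counts=np.zeros(len(ws), dtype=np.int64),
                             percent_reads=arr)

    def test_identical_profiles_give_null_with_warning(self):
        a = self.windows([1.0, 2.0, 3.0])
        b = self.windows([1.0, 2.0, 3.0], "b")
        with pytest.warns(RuntimeWarning, match="degenerate"):
            t, p = differential_interaction(a, b)
        assert (t, p) == (0.0, 1.0)

    def test_five_window_fixture_matches_paired_t_formula(self):
        a = self.windows([2.0, 3.0, 3.5, 2.5, 4.0])
        b = self.windows([1.0, 1.0, 2.0, 2.0, 3.0], "b")
        t, p = differential_interaction(a, b)
        # d = (1, 2, 1.5, .5, 1): mean 1.2, sd sqrt(0.325), t = 1.2/(sd/sqrt 5)
        assert t == pytest.approx(4.706787243316416, abs=1e-10)
        assert p == pytest.approx(0.009261696759514423, abs=1e-10)

    def test_constant_shift_with_shrinking_jitter_drives_p_to_zero(self):
        base = np.linspace(1, 2, 21)
        rng = np.random.default_rng(0)
        jitter = rng.normal(size=21)
        last_p = 1.0
        for eps in (0.3, 0.03, 0.003):
            a = self.windows(base + 0.5 + eps * jitter)
            b = self.windows(base, "b")
            _, p = differential_interaction(a, b)
            assert p < last_p
            last_p = p
        assert last_p < 1e-20

    def test_antisymmetric_in_profile_order(self):
        a = self.windows([2.0, 3.0, 3.5, 2.5, 4.0])
        b = self.windows([1.0, 1.0, 2.0, 2.0, 3.0], "b")
        t1, p1 = differential_interaction(a, b)
        t2, p2 = differential_interaction(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_mismatched_windows_rejected(self):
        a = self.windows([1.0, 2.0, 3.0])
        b = self.windows([1.0, 2.0], "b")
        with pytest.raises(ValueError, match="window"):
            differential_interaction(a, b)

    def test_exclusion_radius_drops_center_windows(self):
        a = self.windows([1.0] * 9 + [50.0] + [1.0] * 9)
        b = self.windows([1.0] * 19, "b")
        center = a.windows[9].start + 500
        _, p_with = differential_interaction(a, b)
        with pytest.warns(RuntimeWarning):
            _, p_without = differential_interaction(
                a, b, exclusion_radius=1_000, center=center
            )
        assert p_without == 1.0 and p_with < 1.0


class TestMappingSummary:
    def test_percent_to_one_decimal(self):
        assert mapping_summary(1_000, 908) == (1_000, 90.8)
        assert mapping_summary(10, 0) == (10, 0.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            mapping_summary(0, 0)

    def test_mapped_cannot_exceed_raw(self):
        with pytest.raises(ValueError):
            mapping_summary(10, 11)
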