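"""4C-seq interaction profiling around a bait.

Percent reads are computed in 1-kb sliding windows at 50% overlap (width
1,000 bp, step 500 bp, half-open membership), with the denominator all
mapped reads of the profile.  Differential interaction between two cell
types is a two-tailed paired t-test over per-window percent differences
across a 100-kb region centered on the site of interest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .intervals import GenomeInterval

logger = logging.getLogger(__name__)

__all__ = [
    "FourCProfile",
    "WindowProfile",
    "read_read_positions",
    "make_windows",
    "window_percent_reads",
    "differential_interaction",
    "mapping_summary",
    "WINDOW_WIDTH",
    "WINDOW_STEP",
    "DIFF_SPAN",
]

WINDOW_WIDTH = 1_000
WINDOW_STEP = 500
DIFF_SPAN = 100_000


@dataclass
class FourCProfile:
    """Mapped junction-read positions for one cell type.

    ``reads`` maps chrom -> sorted array of 0-based read positions;
    ``total_reads`` is the number of raw junction reads sequenced (>= the
    number mapped).
    """

    cell_type: str
    bait: GenomeInterval
    reads: dict[str, np.ndarray]
    total_reads: int | None = None

    def __post_init__(self) -> None:
        self.reads = {
            c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in self.reads.items()
        }
        n = self.n_mapped
        if self.total_reads is None:
            self.total_reads = n
        if self.total_reads < n:
            raise ValueError("total_reads below number of mapped reads")

    @property
    def n_mapped(self) -> int:
        return int(sum(p.size for p in self.reads.values()))

    @property
    def mapped_fraction(self) -> float:
        return self.n_mapped / self.total_reads if self.total_reads else 0.0


def read_read_positions(path: str | Path) -> dict[str, np.ndarray]:
    """Read mapped positions from BED (chrom, start, ...) or 2-column TSV."""
    by_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: need >= 2 columns")
            by_chrom.setdefault(fields[0], []).append(int(fields[1]))
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}


@dataclass
class WindowProfile:
    """Sliding-window percent-read profile over one region."""

    cell_type: str
    windows: list[GenomeInterval]
    counts: np.ndarray
    percent_reads: np.ndarray = field(default=None)  # type: ignore[assignment]
    total_reads: int = 0


def make_windows(
    region: GenomeInterval,
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
) -> list[GenomeInterval]:
    """Tile a region with fixed-width windows at the given step."""
    if len(region) < width:
        raise ValueError(f"region shorter than window width {width}")
    starts = range(region.start, region.end - width + 1, step)
    return [GenomeInterval(region.chrom, s, s + width) for s in starts]


def window_percent_reads(
    profile: FourCProfile,
    region: GenomeInterval,
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
    denominator: str = "all",
) -> WindowProfile:
    """Percent of reads per sliding window (half-open membership).

    ``denominator`` "all" uses every mapped read of the profile (the
    default); "region" uses only reads inside ``region``.
    """
    n_all = profile.n_mapped
    if n_all == 0:
        raise ValueError("profile has no mapped reads")
    windows = make_windows(region, width, step)
    pos = profile.reads.get(region.chrom, np.empty(0, dtype=np.int64))
    starts = np.asarray([w.start for w in windows])
    counts = (
        np.searchsorted(pos, starts + width, side="left")
        - np.searchsorted(pos, starts, side="left")
    )
    if denominator == "region":
        denom = int(
            np.searchsorted(pos, region.end, side="left")
            - np.searchsorted(pos, region.start, side="left")
        )
        if denom == 0:
            raise ValueError("no reads in region for 'region' denominator")
    elif denominator == "all":
        denom = n_all
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return WindowProfile(
        cell_type=profile.cell_type,
        windows=windows,
        counts=counts.astype(np.int64),
        percent_reads=100.0 * counts / denom,
        total_reads=denom,
    )


def differential_interaction(
    a: WindowProfile,
    b: WindowProfile,
    exclusion_radius: int = 0,
    center: int | None = None,
) -> tuple[float, float]:
    """Two-tailed paired t-test of per-window percent reads (a vs b).

    Windows must match exactly between profiles (pairing by coordinates).
    ``exclusion_radius`` drops windows whose midpoint is within that many
    bp of ``center`` (e.g. to mask the bait-proximal zone).  An all-zero
    difference vector returns (0, 1) with a degenerate-variance warning.
    """
    if a.windows != b.windows:
        raise ValueError("window grids differ between profiles")
    d = np.asarray(a.percent_reads, dtype=float) - np.asarray(
        b.percent_reads, dtype=float
    )
    if exclusion_radius > 0:
        if center is None:
            raise ValueError("exclusion_radius requires center")
        mids = np.asarray([(w.start + w.end) / 2 for w in a.windows])
        d = d[np.abs(mids - center) > exclusion_radius]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired windows")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            warnings.warn(
                "identical window profiles: degenerate variance, p = 1",
                RuntimeWarning,
                stacklevel=2,
            )
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return float(t), min(p, 1.0)


def mapping_summary(raw_reads: int, mapped_reads: int) -> tuple[int, float]:
    """(total raw reads, mapped percent to one decimal)."""
    if raw_reads < 0 or mapped_reads < 0:
        raise ValueError("counts must be >= 0")
    if raw_reads == 0:
        raise ValueError("no reads")
    if mapped_reads > raw_reads:
        raise ValueError("mapped exceeds raw reads")
    return raw_reads, round(100.0 * mapped_reads / raw_reads, 1)
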