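"""Genomic intervals and a lightweight per-chromosome interval index.

All coordinates in this package are 0-based half-open ([start, end)),
matching BED.  Formats that use other conventions (WIG) are converted on
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["GenomeInterval", "IntervalIndex", "merge_intervals"]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is "+", "-" or "." (unstranded).  ``name`` is an optional
    label carried from/to BED.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(
    intervals: Iterable[GenomeInterval], merge_adjacent: bool = True
) -> list[GenomeInterval]:
    """Merge overlapping (and, by default, abutting) intervals.

    Returns a sorted, disjoint list.  Strand and names are dropped.
    """
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomeInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            joins = iv.start <= cur_e if merge_adjacent else iv.start < cur_e
            if joins:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomeInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomeInterval(chrom, cur_s, cur_e))
    return out


class IntervalIndex:
    """Point-membership queries against a set of disjoint intervals.

    Intervals are merged on construction, so overlapping input is fine.
    Queries are O(log n) via binary search on per-chromosome start arrays.
    """

    def __init__(self, intervals: Iterable[GenomeInterval]):
        merged = merge_intervals(list(intervals)) if intervals else []
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merged:
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[union-attr]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[union-attr]
        for chrom in self._starts:
            self._starts[chrom] = np.asarray(self._starts[chrom], dtype=np.int64)
            self._ends[chrom] = np.asarray(self._ends[chrom], dtype=np.int64)
        self.intervals = merged

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos) -> np.ndarray | bool:
        """Whether position(s) fall inside any interval (half-open)."""
        scalar = np.isscalar(pos)
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self._starts:
            res = np.zeros(pos.shape, dtype=bool)
        else:
            idx = np.searchsorted(self._starts[chrom], pos, side="right") - 1
            res = (idx >= 0) & (pos < self._ends[chrom][np.clip(idx, 0, None)])
        return bool(res[0]) if scalar else res
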