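"""Run-length encoded genomic signal tracks.

A :class:`SignalTrack` holds, per chromosome, sorted non-overlapping runs
(start, span, value).  Each covered base inside a run carries the run's
value, so a fixedStep step-1 WIG and its bedGraph conversion are the same
object after loading.  Summary statistics (mean, sd) weight every covered
base equally, i.e. runs are weighted by their span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalTrack"]


@dataclass
class SignalTrack:
    """Per-base numeric signal stored as run-length data.

    ``data`` maps chromosome -> (starts, spans, values); starts are 0-based,
    strictly increasing and non-overlapping.  ``resolution`` records the
    modal datum span in bp (informational).
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_runs(
        cls, runs: dict[str, list[tuple[int, int, float]]]
    ) -> "SignalTrack":
        """Build from {chrom: [(start, span, value), ...]}, validating order."""
        data = {}
        for chrom, rr in runs.items():
            if not rr:
                continue
            starts = np.asarray([r[0] for r in rr], dtype=np.int64)
            spans = np.asarray([r[1] for r in rr], dtype=np.int64)
            values = np.asarray([r[2] for r in rr], dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, spans, values = starts[order], spans[order], values[order]
            if np.any(spans <= 0):
                raise ValueError(f"{chrom}: non-positive span")
            if np.any(starts[:-1] + spans[:-1] > starts[1:]):
                raise ValueError(f"{chrom}: overlapping or non-monotone runs")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: non-finite signal value")
            data[chrom] = (starts, spans, values)
        return cls(data=data)

    @property
    def resolution(self) -> int:
        spans = np.concatenate([s for _, s, _ in self.data.values()]) if self.data else np.array([1])
        vals, counts = np.unique(spans, return_counts=True)
        return int(vals[np.argmax(counts)])

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def n_covered_bases(self) -> int:
        return int(sum(s.sum() for _, s, _ in self.data.values()))

    def point_value(self, chrom: str, pos: int) -> float:
        """Signal at a single base; NaN if uncovered."""
        if chrom not in self.data:
            return float("nan")
        starts, spans, values = self.data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < starts[i] + spans[i]:
            return float(values[i])
        return float("nan")

    def _overlapping(self, chrom: str, start: int, end: int):
        """Indices of runs overlapping the half-open query [start, end)."""
        starts, spans, values = self.data[chrom]
        lo = int(np.searchsorted(starts + spans, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return starts[lo:hi], spans[lo:hi], values[lo:hi]

    def values_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Run values overlapping [start, end); empty array if no coverage."""
        if chrom not in self.data or end <= start:
            return np.empty(0)
        _, _, values = self._overlapping(chrom, start, end)
        return values

    def max_in(self, chrom: str, start: int, end: int) -> float:
        """Max signal over covered bases in [start, end); NaN if uncovered."""
        v = self.values_in(chrom, start, end)
        return float(v.max()) if v.size else float("nan")

    def mean_in(self, chrom: str, start: int, end: int) -> float:
        """Per-base mean over covered bases in [start, end); NaN if uncovered."""
        if chrom not in self.data or end <= start:
            return float("nan")
        starts, spans, values = self._overlapping(chrom, start, end)
        if values.size == 0:
            return float("nan")
        w = np.minimum(starts + spans, end) - np.maximum(starts, start)
        return float(np.average(values, weights=w))

    def mean_sd(self) -> tuple[float, float]:
        """Genome-wide per-base mean and population sd of the signal."""
        tot_w = 0.0
        tot_v = 0.0
        for _, spans, values in self.data.values():
            tot_w += spans.sum()
            tot_v += float(np.dot(spans, values))
        if tot_w == 0:
            raise ValueError("empty track")
        mean = tot_v / tot_w
        ss = 0.0
        for _, spans, values in self.data.values():
            ss += float(np.dot(spans, (values - mean) ** 2))
        return mean, float(np.sqrt(ss / tot_w))

    def affine(self, a: float, b: float) -> "SignalTrack":
        """New track with values a*v + b (coverage unchanged)."""
        return SignalTrack(
            data={
                c: (s.copy(), sp.copy(), a * v + b)
                for c, (s, sp, v) in self.data.items()
            }
        )
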