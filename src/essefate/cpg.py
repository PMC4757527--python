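"""CpG-island detection by the classic sequence criteria.

A window qualifies when GC fraction >= 0.5 and the observed/expected CpG
ratio >= 0.6; qualifying 200-bp windows slid at 1 bp are merged and merged
regions of at least 200 bp are reported.  The scan is vectorized with
cumulative counts; an exhaustive per-window evaluation is equivalent (and
is what the test suite compares against).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomeInterval

__all__ = ["CpgIslandParams", "gc_fraction", "obs_exp_cpg", "scan_cpg_islands",
           "scan_genome_islands"]

# Unambiguous bases count directly; other IUPAC ambiguity codes are treated
# like N (excluded from all counts).
_IUPAC = set("ACGTUNRYSWKMBDHV")


@dataclass
class CpgIslandParams:
    """Thresholds for the island scan.

    min_length/window in bp; min_gc a fraction; min_obs_exp a ratio.
    ``step`` > 1 is a speed knob that coarsens the scan.  ``recheck_merged``
    re-applies the criteria to each merged region (a historical variant);
    by default merged regions are reported as-is.
    """

    min_length: int = 200
    min_gc: float = 0.50
    min_obs_exp: float = 0.60
    window: int = 200
    step: int = 1
    recheck_merged: bool = False
    max_n_frac: float = 0.50

    def __post_init__(self) -> None:
        if self.min_length < self.window:
            raise ValueError("min_length must be >= window")
        if not 0 < self.min_gc <= 1:
            raise ValueError("min_gc must be in (0, 1]")
        if self.min_obs_exp <= 0:
            raise ValueError("min_obs_exp must be > 0")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def _seq_to_arrays(seq: str):
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    bad = set(chr(c) for c in np.unique(b)) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    is_c = b == ord("C")
    is_g = b == ord("G")
    is_n = ~(is_c | is_g | (b == ord("A")) | (b == ord("T")) | (b == ord("U")))
    return is_c, is_g, is_n


def gc_fraction(seq: str) -> float:
    """(G + C) / (length excluding N); NaN when no countable base."""
    if not seq:
        raise ValueError("empty sequence")
    is_c, is_g, is_n = _seq_to_arrays(seq)
    denom = len(seq) - int(is_n.sum())
    if denom == 0:
        return float("nan")
    return (int(is_c.sum()) + int(is_g.sum())) / denom


def obs_exp_cpg(seq: str) -> float:
    """Observed/expected CpG: (N_CpG * L) / (N_C * N_G), L excluding N.

    Overlapping "CG" dinucleotides are counted (CG cannot self-overlap, so
    this equals the plain substring count).  NaN when N_C * N_G == 0.
    """
    if len(seq) < 2:
        raise ValueError("sequence must be >= 2 bp")
    is_c, is_g, is_n = _seq_to_arrays(seq)
    n_c, n_g = int(is_c.sum()), int(is_g.sum())
    if n_c * n_g == 0:
        return float("nan")
    n_cpg = int((is_c[:-1] & is_g[1:]).sum())
    length = len(seq) - int(is_n.sum())
    return (n_cpg * length) / (n_c * n_g)


def _window_counts(flags: np.ndarray, window: int) -> np.ndarray:
    """Count of True in each length-``window`` window (starts 0..L-window)."""
    cs = np.concatenate(([0], np.cumsum(flags, dtype=np.int64)))
    return cs[window:] - cs[: flags.size - window + 1]


def scan_cpg_islands(
    seq: str,
    params: CpgIslandParams | None = None,
    chrom: str = "seq",
) -> list[GenomeInterval]:
    """Report merged qualifying-window regions as sorted disjoint intervals.

    Windows with more than ``max_n_frac`` ambiguous bases are disqualified.
    """
    params = params or CpgIslandParams()
    w = params.window
    if len(seq) < w:
        return []
    is_c, is_g, is_n = _seq_to_arrays(seq)
    n_c = _window_counts(is_c, w)
    n_g = _window_counts(is_g, w)
    n_n = _window_counts(is_n, w)
    # CG dinucleotides fully inside the window: starts i..i+w-2
    cg = np.zeros(len(seq), dtype=bool)
    cg[:-1] = is_c[:-1] & is_g[1:]
    n_cpg = _window_counts(cg[:-1], w - 1) if len(seq) >= 2 else np.zeros(0)

    length = w - n_n
    ok = (n_n <= params.max_n_frac * w) & (length > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(ok, (n_c + n_g) / np.maximum(length, 1), 0.0)
        denom = (n_c * n_g).astype(float)
        oe = np.where(ok & (denom > 0), n_cpg * length / np.maximum(denom, 1), 0.0)
    qual = ok & (gc >= params.min_gc) & (denom > 0) & (oe >= params.min_obs_exp)
    starts = np.nonzero(qual)[0]
    if params.step > 1:
        starts = starts[starts % params.step == 0]
    if starts.size == 0:
        return []

    # merge overlapping/abutting qualifying windows [s, s+w)
    islands: list[GenomeInterval] = []
    cur_s = cur_e = None
    for s in starts:
        s = int(s)
        if cur_s is None:
            cur_s, cur_e = s, s + w
        elif s <= cur_e:
            cur_e = s + w
        else:
            islands.append(GenomeInterval(chrom, cur_s, cur_e))
            cur_s, cur_e = s, s + w
    islands.append(GenomeInterval(chrom, cur_s, cur_e))

    islands = [iv for iv in islands if len(iv) >= params.min_length]
    if params.recheck_merged:
        kept = []
        for iv in islands:
            sub = seq[iv.start : iv.end]
            if (
                gc_fraction(sub) >= params.min_gc
                and obs_exp_cpg(sub) >= params.min_obs_exp
            ):
                kept.append(iv)
        islands = kept
    return islands


def scan_genome_islands(
    genome: dict[str, str], params: CpgIslandParams | None = None
) -> list[GenomeInterval]:
    """Scan every chromosome of a {name: sequence} genome."""
    out: list[GenomeInterval] = []
    for chrom in sorted(genome):
        if len(genome[chrom]) >= (params.window if params else 200):
            out.extend(scan_cpg_islands(genome[chrom], params, chrom=chrom))
    return out
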