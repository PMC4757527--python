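"""Histone-mark scoring, per-cell-type state calls, and transitions.

Tracks are z-normalized genome-wide (mean 0, population sd 1 over every
covered base).  A site's per-sample score is the maximum normalized signal
within +/-100 bp of the probe coordinate (inclusive at both ends); a cell
type is *positive* for the mark when the average of its samples' scores is
strictly greater than 0.  Transitions between two stages are lose / retain /
gain / absent, and an ESSE (ES-specific enhancer) is a distal site positive
in ES and negative in HSC (strict mode also requires negativity in every
supplied differentiated cell type).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .tracks import SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_track",
    "site_mark_score",
    "call_mark_state",
    "classify_transition",
    "call_esse",
    "score_sites",
    "state_table",
    "transition_table",
    "MARK_HALF_WINDOW",
]

MARK_HALF_WINDOW = 100


def normalize_track(track: SignalTrack) -> SignalTrack:
    """z = (v - mean) / sd over all covered bases; population sd.

    Raises on a constant track (sd = 0).
    """
    mean, sd = track.mean_sd()
    if sd == 0:
        raise ValueError("constant track: sd is 0, cannot normalize")
    return track.affine(1.0 / sd, -mean / sd)


def site_mark_score(
    ztrack: SignalTrack,
    chrom: str,
    pos: int,
    half_window: int = MARK_HALF_WINDOW,
    stat: str = "max",
) -> float:
    """Score within [pos - half_window, pos + half_window], inclusive.

    ``stat`` "max" (default) or "mean" (per-base mean, the documented
    alternative reading of the averaging rule).  NaN when the window has no
    coverage.
    """
    start, end = pos - half_window, pos + half_window + 1
    if stat == "max":
        return ztrack.max_in(chrom, start, end)
    if stat == "mean":
        return ztrack.mean_in(chrom, start, end)
    raise ValueError(f"unknown stat {stat!r}")


def call_mark_state(scores) -> tuple[str | None, float]:
    """(state, mean score) from per-sample scores of one cell type.

    Positive iff the mean of non-missing scores is strictly > 0.  Returns
    (None, NaN) when every score is missing.
    """
    arr = np.asarray(list(scores), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return None, float("nan")
    m = float(arr.mean())
    return ("positive" if m > 0 else "negative"), m


def classify_transition(state_a: str | None, state_b: str | None) -> str | None:
    """lose / retain / gain / absent between two stages; None if either missing."""
    if state_a is None or state_b is None:
        return None
    table = {
        ("positive", "negative"): "lose",
        ("positive", "positive"): "retain",
        ("negative", "positive"): "gain",
        ("negative", "negative"): "absent",
    }
    try:
        return table[(state_a, state_b)]
    except KeyError:
        raise ValueError(f"invalid states {(state_a, state_b)!r}") from None


def call_esse(
    states: dict[str, str | None],
    es: str = "ES",
    hsc: str = "HSC",
    differentiated: list[str] | None = None,
    strict: bool = False,
) -> bool | None:
    """ESSE flag from per-cell-type H3K4me1 states.

    Default: positive in ES and negative in HSC.  Strict: additionally
    negative in every supplied differentiated cell type.  None when a
    required state is missing.
    """
    s_es, s_hsc = states.get(es), states.get(hsc)
    if s_es is None or s_hsc is None:
        return None
    flag = s_es == "positive" and s_hsc == "negative"
    if strict and flag:
        for ct in differentiated or []:
            s = states.get(ct)
            if s is None:
                return None
            if s == "positive":
                return False
    return flag


# ---------------------------------------------------------------------------
# batch helpers over a site frame


def score_sites(
    tracks: dict[str, SignalTrack],
    sites: pd.DataFrame,
    half_window: int = MARK_HALF_WINDOW,
    stat: str = "max",
    normalized: bool = False,
) -> pd.DataFrame:
    """Per-site, per-sample scores: DataFrame sites x sample_ids.

    ``tracks`` maps sample_id -> raw (or pre-normalized) track.
    """
    cols = {}
    for sample_id, track in tracks.items():
        z = track if normalized else normalize_track(track)
        cols[sample_id] = [
            site_mark_score(z, chrom, int(pos), half_window, stat)
            for chrom, pos in zip(sites["chrom"], sites["pos"])
        ]
    return pd.DataFrame(cols, index=sites.index)


def state_table(
    scores: pd.DataFrame, sample_cell_types: dict[str, str]
) -> pd.DataFrame:
    """Per-site, per-cell-type states from a per-sample score frame.

    Cell types appear in first-seen order of ``sample_cell_types``.  Cells
    are "positive"/"negative" or NA when all samples are missing.
    """
    by_ct: dict[str, list[str]] = {}
    for sample_id, ct in sample_cell_types.items():
        if sample_id in scores.columns:
            by_ct.setdefault(ct, []).append(sample_id)
    out = {}
    for ct, sample_ids in by_ct.items():
        states = []
        for _, row in scores[sample_ids].iterrows():
            state, _ = call_mark_state(row.to_numpy())
            states.append(state)
        out[ct] = states
    return pd.DataFrame(out, index=scores.index)


def transition_table(
    states: pd.DataFrame, contrasts: list[tuple[str, str]]
) -> pd.DataFrame:
    """Transition class per site for each (from_stage, to_stage) contrast."""
    out = {}
    n_dropped = 0
    for a, b in contrasts:
        col = []
        for sa, sb in zip(states[a], states[b]):
            sa = None if (sa is None or (isinstance(sa, float) and math.isnan(sa))) else sa
            sb = None if (sb is None or (isinstance(sb, float) and math.isnan(sb))) else sb
            cls = classify_transition(sa, sb)
            if cls is None:
                n_dropped += 1
            col.append(cls)
        out[f"{a}_to_{b}"] = col
    if n_dropped:
        logger.info("%d site/contrast pairs dropped for missing states", n_dropped)
    return pd.DataFrame(out, index=states.index)
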