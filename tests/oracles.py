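"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (string slicing, exhaustive
enumeration of subsets) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache


def brute_cpg_islands(
    seq: str,
    window: int = 200,
    min_gc: float = 0.50,
    min_obs_exp: float = 0.60,
    min_length: int = 200,
    max_n_frac: float = 0.50,
) -> list[tuple[int, int]]:
    """Evaluate every window explicitly with string operations."""
    seq = seq.upper()
    qualifying = []
    for i in range(len(seq) - window + 1):
        win = seq[i : i + window]
        n_n = sum(1 for b in win if b not in "ACGT")
        if n_n > max_n_frac * window:
            continue
        length = window - n_n
        if length == 0:
            continue
        n_c, n_g = win.count("C"), win.count("G")
        if (n_c + n_g) / length < min_gc:
            continue
        if n_c * n_g == 0:
            continue
        n_cpg = win.count("CG")  # CG cannot overlap itself
        if n_cpg * length / (n_c * n_g) < min_obs_exp:
            continue
        qualifying.append(i)
    # merge overlapping/abutting windows
    merged: list[list[int]] = []
    for i in qualifying:
        if merged and i <= merged[-1][1]:
            merged[-1][1] = i + window
        else:
            merged.append([i, i + window])
    return [(s, e) for s, e in merged if e - s >= min_length]


@lru_cache(maxsize=None)
def rank_sum_distribution(n: int, nx: int) -> dict[int, int]:
    """#(nx-subsets of ranks 1..n) per rank-sum, by full enumeration."""
    counts: dict[int, int] = {}
    for combo in itertools.combinations(range(1, n + 1), nx):
        s = sum(combo)
        counts[s] = counts.get(s, 0) + 1
    return counts


def enum_rank_sum_p(n: int, nx: int, w: int) -> float:
    """Two-sided exact p = min(1, 2 * min tail) from the enumerated null."""
    counts = rank_sum_distribution(n, nx)
    total = sum(counts.values())
    p_le = sum(c for s, c in counts.items() if s <= w) / total
    p_ge = sum(c for s, c in counts.items() if s >= w) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def enum_overlap_tails(k: int, n_a: int, n_b: int, N: int) -> tuple[float, float]:
    """(P(X >= k), P(X <= k)) by enumerating every n_a-subset of the universe."""
    universe = range(N)
    b = set(range(n_b))
    n_ge = n_le = total = 0
    for combo in itertools.combinations(universe, n_a):
        x = len(b.intersection(combo))
        total += 1
        if x >= k:
            n_ge += 1
        if x <= k:
            n_le += 1
    return n_ge / total, n_le / total
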