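"""Statistics used throughout the analyses.

Wilcoxon rank-sum contrasts (exact by enumeration for small tie-free
samples, normal approximation with tie and continuity corrections
otherwise), hypergeometric Venn-overlap significance, Gaussian kernel
density summaries, and foreground-vs-background gene-set enrichment with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "wilcoxon_rank_sum",
    "OverlapTest",
    "venn_overlap_p",
    "kde_density",
    "EnrichmentResult",
    "gene_set_enrichment",
    "bh_adjust",
]

_EXACT_MAX_N = 12


def _rank_sum_null_counts(n: int, nx: int) -> np.ndarray:
    """counts[s] = number of nx-subsets of ranks {1..n} with sum s."""
    max_sum = n * (n + 1) // 2
    f = np.zeros((nx + 1, max_sum + 1), dtype=np.int64)
    f[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(nx, r), 0, -1):
            f[k, r:] += f[k - 1, : max_sum - r + 1]
    return f[nx]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the sum of midranks of ``x`` in the pooled sample.  With at most
    12 pooled observations and no ties, p is exact by enumeration of rank
    assignments (two-sided p = min(1, 2 * min tail)); otherwise the normal
    approximation with tie correction and a 0.5 continuity correction
    toward the null mean is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, nx, ny = pooled.size, x.size, y.size
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[:nx].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n <= _EXACT_MAX_N and not has_ties:
        counts = _rank_sum_null_counts(n, nx)
        total = counts.sum()
        wi = int(round(w))
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        return w, min(1.0, 2.0 * min(p_le, p_ge))

    mean = nx * (n + 1) / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0  # all observations identical
    z = (w - mean - np.sign(w - mean) * 0.5) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


@dataclass
class OverlapTest:
    """Hypergeometric significance of a Venn intersection.

    ``expected`` is the chance intersection n_a * n_b / N; p_enrich is
    P(X >= k), p_deplete is P(X <= k) for X the intersection of a random
    n_a-subset with a fixed n_b-subset of an N universe.
    """

    k: int
    n_a: int
    n_b: int
    N: int
    expected: float
    p_enrich: float
    p_deplete: float


def venn_overlap_p(k: int, n_a: int, n_b: int, N: int) -> OverlapTest:
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError("need 0 <= n_a, n_b <= N")
    if k > min(n_a, n_b):
        raise ValueError(f"k={k} exceeds min(n_a, n_b)={min(n_a, n_b)}")
    if k < max(0, n_a + n_b - N):
        raise ValueError(f"k={k} below the minimum possible intersection")
    if N == 0:
        return OverlapTest(k, n_a, n_b, N, 0.0, 1.0, 1.0)
    expected = n_a * n_b / N
    dist = sps.hypergeom(N, n_b, n_a)
    p_enrich = float(dist.sf(k - 1))
    p_deplete = float(dist.cdf(k))
    return OverlapTest(k, n_a, n_b, N, expected,
                       min(p_enrich, 1.0), min(p_deplete, 1.0))


def kde_density(
    values,
    bandwidth: float | None = None,
    n_grid: int = 512,
    grid_pad: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate sampled on a regular grid.

    Bandwidth defaults to Silverman's rule, 0.9 * min(sd, IQR/1.34) *
    n^(-1/5).  Returns (grid, density); the density integrates to ~1 over
    the grid (which extends ``grid_pad`` bandwidths past the data range).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if bandwidth is None:
        sd = v.std(ddof=1)
        iqr = np.subtract(*np.percentile(v, [75, 25]))
        scale = min(sd, iqr / 1.34) if iqr > 0 else sd
        if scale == 0:
            raise ValueError(
                "constant input: automatic bandwidth is 0; pass an explicit "
                "bandwidth"
            )
        bandwidth = 0.9 * scale * v.size ** (-0.2)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    grid = np.linspace(v.min() - grid_pad * bandwidth,
                       v.max() + grid_pad * bandwidth, n_grid)
    z = (grid[:, None] - v[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (v.size * bandwidth * np.sqrt(2 * np.pi))
    return grid, dens


@dataclass
class EnrichmentResult:
    set_name: str
    k_fg: int
    n_fg: int
    k_bg: int
    n_bg: int
    p: float
    p_deplete: float
    odds_ratio: float
    q: float = float("nan")


def gene_set_enrichment(
    fg_genes,
    bg_genes,
    collection: dict[str, set[str]],
    restrict_fg_to_bg: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each gene set in foreground vs background.

    The universe is fg | bg (or bg alone with ``restrict_fg_to_bg``, which
    intersects fg into bg first).  Per set: p = P(X >= |S & fg|) drawing
    |fg| genes from the universe with |S & universe| successes.  Results
    carry BH-adjusted q across sets and are sorted by p.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    fg = {g.upper() for g in fg_genes}
    bg = {g.upper() for g in bg_genes}
    if restrict_fg_to_bg:
        fg = fg & bg
        universe = bg
    else:
        universe = fg | bg
    if not fg or not universe:
        raise ValueError("empty foreground or universe")
    results = []
    for name in sorted(collection):
        members = {g.upper() for g in collection[name]} & universe
        if not members:
            logger.warning("gene set %r disjoint from universe; skipped", name)
            continue
        k_fg = len(members & fg)
        k_bg = len(members & bg)
        test = venn_overlap_p(k_fg, len(fg), len(members), len(universe))
        a, b = k_fg, len(fg) - k_fg
        c, d = k_bg, len(bg) - k_bg
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        results.append(
            EnrichmentResult(
                set_name=name, k_fg=k_fg, n_fg=len(fg), k_bg=k_bg,
                n_bg=len(bg), p=test.p_enrich, p_deplete=test.p_deplete,
                odds_ratio=odds,
            )
        )
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return sorted(results, key=lambda r: (r.p, r.set_name))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
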