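"""Regulatory classification of methylation sites relative to TSSs.

A site is a *promoter* site when it lies within 2,500 bp of any TSS
(inclusive); a *distal regulatory* site when it is at least 5,000 bp from
every TSS and not inside a CpG island; everything else (the open distance
band, or island-overlapping distal sites) is *excluded*.  Distances use the
single-bp array-probe coordinate; the reported signed distance is relative
to the nearest gene's strand (negative = upstream).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GenomeInterval, IntervalIndex
from .io import GeneModel

__all__ = ["TssIndex", "nearest_tss", "classify_site", "annotate_sites",
           "PROMOTER_MAX_DIST", "DISTAL_MIN_DIST"]

PROMOTER_MAX_DIST = 2_500
DISTAL_MIN_DIST = 5_000


class TssIndex:
    """Sorted per-chromosome TSS arrays for nearest-gene queries."""

    def __init__(self, genes: list[GeneModel]):
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.tss_chrom, []).append(g)
        self._pos: dict[str, np.ndarray] = {}
        self._genes: dict[str, list[GeneModel]] = {}
        for chrom, gg in by_chrom.items():
            # position-sorted; gene_id as secondary key so the documented
            # lexicographic tie-break is a plain left-to-right scan
            gg = sorted(gg, key=lambda g: (g.tss_pos, g.gene_id))
            self._pos[chrom] = np.asarray([g.tss_pos for g in gg], dtype=np.int64)
            self._genes[chrom] = gg

    def nearest(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        """Nearest gene by |TSS - pos| and its signed strand-relative distance.

        Ties in |distance| go to the lexicographically smallest gene_id.
        Returns None when the chromosome has no gene.
        """
        if chrom not in self._pos:
            return None
        tss = self._pos[chrom]
        i = int(np.searchsorted(tss, pos))
        best: GeneModel | None = None
        best_d = None
        for j in (i - 1, i):
            if 0 <= j < tss.size:
                d = abs(int(tss[j]) - pos)
                if best_d is None or d < best_d:
                    best_d, best = d, self._genes[chrom][j]
        assert best is not None and best_d is not None
        # collect every gene whose TSS attains |d| = best_d (could sit on
        # either side), then take the smallest gene_id
        candidates = []
        for p in (pos - best_d, pos + best_d):
            lo = int(np.searchsorted(tss, p, side="left"))
            hi = int(np.searchsorted(tss, p, side="right"))
            candidates.extend(self._genes[chrom][lo:hi])
        best = min(candidates, key=lambda g: g.gene_id)
        signed = pos - best.tss_pos if best.strand == "+" else best.tss_pos - pos
        return best, signed

    def min_abs_distance(self, chrom: str, pos: int) -> int | None:
        """Distance to the closest of all TSSs (promoter membership test)."""
        if chrom not in self._pos:
            return None
        tss = self._pos[chrom]
        i = int(np.searchsorted(tss, pos))
        ds = [abs(int(tss[j]) - pos) for j in (i - 1, i) if 0 <= j < tss.size]
        return min(ds)


def nearest_tss(
    chrom: str, pos: int, genes: list[GeneModel] | TssIndex
) -> tuple[str, int] | None:
    """(gene_id, signed distance) of the nearest TSS, or None if unassigned."""
    index = genes if isinstance(genes, TssIndex) else TssIndex(genes)
    hit = index.nearest(chrom, pos)
    if hit is None:
        return None
    gene, signed = hit
    return gene.gene_id, signed


def classify_site(
    chrom: str,
    pos: int,
    genes: list[GeneModel] | TssIndex,
    islands: list[GenomeInterval] | IntervalIndex,
    promoter_max_dist: int = PROMOTER_MAX_DIST,
    distal_min_dist: int = DISTAL_MIN_DIST,
) -> str:
    """One of {"promoter", "distal_regulatory", "excluded", "unassigned"}."""
    index = genes if isinstance(genes, TssIndex) else TssIndex(genes)
    isl = islands if isinstance(islands, IntervalIndex) else IntervalIndex(islands)
    dmin = index.min_abs_distance(chrom, pos)
    if dmin is None:
        return "unassigned"
    if dmin <= promoter_max_dist:
        return "promoter"
    if dmin >= distal_min_dist and not isl.contains(chrom, pos):
        return "distal_regulatory"
    return "excluded"


def annotate_sites(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    islands: list[GenomeInterval],
    promoter_max_dist: int = PROMOTER_MAX_DIST,
    distal_min_dist: int = DISTAL_MIN_DIST,
) -> pd.DataFrame:
    """Annotate a sites frame (index site_id; columns chrom, pos).

    Adds nearest_gene, distance_to_tss (signed, relative to gene strand),
    in_cpg_island, and site_class.
    """
    index = TssIndex(genes)
    isl = IntervalIndex(islands)
    nearest_gene, dist, in_isl, cls = [], [], [], []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        pos = int(pos)
        hit = index.nearest(chrom, pos)
        if hit is None:
            nearest_gene.append(None)
            dist.append(np.nan)
        else:
            nearest_gene.append(hit[0].gene_id)
            dist.append(hit[1])
        in_isl.append(bool(isl.contains(chrom, pos)))
        cls.append(
            classify_site(chrom, pos, index, isl, promoter_max_dist, distal_min_dist)
        )
    out = sites.copy()
    out["nearest_gene"] = nearest_gene
    out["distance_to_tss"] = dist
    out["in_cpg_island"] = in_isl
    out["site_class"] = cls
    return out
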