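"""Methylation contrasts and fate classification.

A contrast compares a later stage to an earlier stage on per-cell-type mean
beta values.  A site is *hypomethylated* when delta = beta_late -
beta_early <= -0.20, *hypermethylated* when delta >= +0.20 (both inclusive,
"at least 20%"), *stable* otherwise; *undermethylated* means mean beta
<= 0.50.  Thresholds operate on the [0, 1] beta scale; percent figures are
display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MethylationMatrix

__all__ = [
    "FATE_THRESHOLD",
    "UNDERMETHYLATED_MAX",
    "mean_beta",
    "contrast",
    "classify_fate",
    "undermethylated",
    "fraction_report",
    "EsseSetPartition",
    "partition_esse_fates",
    "foreground_hyper_esse",
    "background_hyper_distal",
    "reprogrammed_hypo_esse",
]

FATE_THRESHOLD = 0.20
UNDERMETHYLATED_MAX = 0.50


def mean_beta(matrix: MethylationMatrix, cell_type: str) -> pd.Series:
    """Per-site arithmetic mean beta over the cell type's samples.

    Missing betas are excluded pairwise; a site with no non-missing sample
    is NaN.
    """
    samples = matrix.samples_of(cell_type)
    if not samples:
        raise ValueError(f"no samples of cell type {cell_type!r}")
    return matrix.beta[samples].mean(axis=1, skipna=True)


def contrast(
    matrix: MethylationMatrix, early: str, late: str
) -> pd.DataFrame:
    """beta_early, beta_late, delta (= late - early) per site."""
    be = mean_beta(matrix, early)
    bl = mean_beta(matrix, late)
    return pd.DataFrame(
        {"beta_early": be, "beta_late": bl, "delta": bl - be},
        index=matrix.beta.index,
    )


def classify_fate(delta, threshold: float = FATE_THRESHOLD):
    """"hypomethylated" / "hypermethylated" / "stable" (vectorized).

    Boundary |delta| == threshold is hypo/hyper ("at least").  NaN deltas
    give None.
    """
    scalar = np.isscalar(delta)
    d = np.atleast_1d(np.asarray(delta, dtype=float))
    out = np.where(
        np.isnan(d),
        None,
        np.where(
            d <= -threshold,
            "hypomethylated",
            np.where(d >= threshold, "hypermethylated", "stable"),
        ),
    )
    return out[0] if scalar else pd.Series(out, index=getattr(delta, "index", None))


def undermethylated(beta, threshold: float = UNDERMETHYLATED_MAX):
    """True iff mean beta <= threshold (inclusive)."""
    b = np.asarray(beta, dtype=float)
    res = b <= threshold
    if np.isscalar(beta):
        if np.isnan(b):
            raise ValueError("beta is missing")
        return bool(res)
    return pd.Series(res, index=getattr(beta, "index", None))


def fraction_report(counts: dict[str, int]) -> dict[str, float]:
    """Percentages (100 * count / total) rounded to one decimal."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be > 0")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be >= 0")
    return {k: round(100.0 * c / total, 1) for k, c in counts.items()}


@dataclass
class EsseSetPartition:
    """Fate partition of an ESSE set under one cancer-vs-normal contrast."""

    hypo: set[str]
    hyper: set[str]
    stable: set[str]
    fractions: dict[str, float] | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hypo & self.hyper or self.hypo & self.stable or self.hyper & self.stable:
            raise ValueError("fate sets must be disjoint")
        if not self.counts:
            self.counts = {
                "hypomethylated": len(self.hypo),
                "hypermethylated": len(self.hyper),
                "stable": len(self.stable),
            }


def partition_esse_fates(
    esse_sites: set[str],
    contrast_df: pd.DataFrame,
    threshold: float = FATE_THRESHOLD,
) -> EsseSetPartition:
    """Split an ESSE set by its fate under a normal-vs-cancer contrast.

    ``contrast_df`` (from :func:`contrast`) must cover every ESSE site
    (same site universe); sites with a missing delta are left out of all
    three fate sets.  Fractions are None for an empty ESSE set.
    """
    missing = esse_sites - set(contrast_df.index)
    if missing:
        raise ValueError(
            f"{len(missing)} ESSE sites absent from the contrast universe "
            f"(e.g. {sorted(missing)[:3]})"
        )
    ids = sorted(esse_sites)
    deltas = contrast_df.loc[ids, "delta"]
    hypo = set(deltas.index[deltas <= -threshold])
    hyper = set(deltas.index[deltas >= threshold])
    stable = set(deltas.index[deltas.abs() < threshold])
    part = EsseSetPartition(hypo=hypo, hyper=hyper, stable=stable)
    classified = len(hypo) + len(hyper) + len(stable)
    part.fractions = fraction_report(part.counts) if classified else None
    return part


def foreground_hyper_esse(
    esse_sites: set[str],
    normal_means: dict[str, pd.Series],
    cancer_contrast: pd.DataFrame,
    under_threshold: float = UNDERMETHYLATED_MAX,
    fate_threshold: float = FATE_THRESHOLD,
) -> set[str]:
    """ESSEs unmethylated in every normal cell type and hyper in cancer.

    ``normal_means`` maps each normal cell type (ES, HSC, differentiated)
    to its per-site mean beta.  "Unmethylated in all the normal cells" uses
    the <= 50% undermethylation rule in each normal cell type.
    """
    ids = sorted(esse_sites)
    keep = pd.Series(True, index=ids)
    for means in normal_means.values():
        keep &= means.loc[ids] <= under_threshold
    keep &= cancer_contrast.loc[ids, "delta"] >= fate_threshold
    return set(keep.index[keep.fillna(False)])


def background_hyper_distal(
    distal_sites: set[str],
    cancer_contrast: pd.DataFrame,
    fate_threshold: float = FATE_THRESHOLD,
) -> set[str]:
    """All distal regulatory sites (ESSE or not) hypermethylated in cancer."""
    ids = sorted(distal_sites)
    d = cancer_contrast.loc[ids, "delta"]
    return set(d.index[(d >= fate_threshold).fillna(False)])


def reprogrammed_hypo_esse(
    esse_sites: set[str],
    dev_contrast: pd.DataFrame,
    cancer_contrast: pd.DataFrame,
    fate_threshold: float = FATE_THRESHOLD,
) -> set[str]:
    """Cancer-hypomethylated ESSEs that had gained methylation in development.

    Sites hypermethylated in the developmental contrast (e.g. HSC vs ES)
    whose methylation drops back (hypo) in the cancer contrast — the
    reversion-to-ES-state set.
    """
    ids = sorted(esse_sites)
    dev = dev_contrast.loc[ids, "delta"] >= fate_threshold
    can = cancer_contrast.loc[ids, "delta"] <= -fate_threshold
    keep = (dev & can).fillna(False)
    return set(keep.index[keep])
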