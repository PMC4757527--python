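"""Synthetic miniature study with planted ground truth.

Generates, from one seed, a complete input set for the pipeline: a
CpG-depleted two-chromosome genome with CG-rich island blocks at planted
promoters, gene models, a per-stage 450K-style beta matrix (Beta-distributed
per planted class), H3K4me1 WIG tracks per ChIP sample with plateaued
signal domains at mark-positive sites (and decoy domains elsewhere, so
every track's covered-base mean sits between background and domain level),
expression values coupled to promoter methylation, 4C junction reads with a
distance decay and one planted differential interaction domain, and a JSON
truth manifest keyed by site.

The defaults are the study conditions every recovery test runs under; they
are documented in the methods note and are not tuned per test.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomeInterval
from .io import (
    GeneModel,
    MethylationMatrix,
    write_bed_intervals,
    write_fasta,
    write_gene_models,
    write_gene_sets,
)
from .tracks import SignalTrack

__all__ = [
    "SimulationConfig",
    "generate_study",
    "generate_beta",
    "simulate_mark_cohort",
    "simulate_fate_cohort",
    "simulate_fourc_reads",
    "sample_transition_classes",
    "PLANTED_CLASSES",
]

PLANTED_CLASSES = [
    "promoter",
    "constitutive_enhancer",
    "enhancer_hyper_in_cancer",
    "esse_hypo_in_cancer",
    "esse_hyper_in_cancer",
    "esse_stable",
    "hsc_enhancer",
    "inert_distal",
]

# Planted H3K4me1 state per class and ChIP cell type.
MARK_STATES: dict[str, dict[str, bool]] = {
    "promoter": {"ES": False, "HSC": False, "TCELL": False},
    "inert_distal": {"ES": False, "HSC": False, "TCELL": False},
    "constitutive_enhancer": {"ES": True, "HSC": True, "TCELL": True},
    "enhancer_hyper_in_cancer": {"ES": True, "HSC": True, "TCELL": True},
    "esse_hypo_in_cancer": {"ES": True, "HSC": False, "TCELL": False},
    "esse_hyper_in_cancer": {"ES": True, "HSC": False, "TCELL": False},
    "esse_stable": {"ES": True, "HSC": False, "TCELL": False},
    "hsc_enhancer": {"ES": False, "HSC": True, "TCELL": True},
}

# Planted mean beta per class and methylation cell type.  The trajectories
# mirror the developmental/cancer structure under study: ESSEs start
# unmethylated in ES; most gain methylation in blood; the cancer-hyper group
# stays low in every normal cell type and methylates only in cancer; the
# cancer-hypo group reverts toward its ES state.
BETA_MEANS: dict[str, dict[str, float]] = {
    "promoter": {"ES": 0.10, "HSC": 0.10, "TCELL": 0.10, "CANCER": 0.10},
    "inert_distal": {"ES": 0.80, "HSC": 0.80, "TCELL": 0.80, "CANCER": 0.80},
    "constitutive_enhancer": {"ES": 0.20, "HSC": 0.20, "TCELL": 0.20, "CANCER": 0.20},
    "enhancer_hyper_in_cancer": {"ES": 0.20, "HSC": 0.25, "TCELL": 0.25, "CANCER": 0.75},
    "esse_hypo_in_cancer": {"ES": 0.15, "HSC": 0.75, "TCELL": 0.75, "CANCER": 0.30},
    "esse_hyper_in_cancer": {"ES": 0.15, "HSC": 0.25, "TCELL": 0.25, "CANCER": 0.75},
    "esse_stable": {"ES": 0.15, "HSC": 0.75, "TCELL": 0.75, "CANCER": 0.75},
    "hsc_enhancer": {"ES": 0.70, "HSC": 0.20, "TCELL": 0.20, "CANCER": 0.20},
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    # one site per locus; loci tile each chromosome at this spacing
    locus_spacing: int = 12_000
    site_offset: int = 3_000  # site position within its locus
    # TSS offset range for non-promoter loci; the upper bound keeps each
    # locus's own gene strictly nearer than any neighbour's (spacing minus
    # max offset > max offset)
    distal_gene_offset: tuple[int, int] = (5_000, 5_900)
    # class counts: the marked-distal mix echoes the observed lose/retain/
    # gain split (~61/26/13) of ES-vs-HSC H3K4me1 sites
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "promoter": 60,
            "constitutive_enhancer": 34,
            "enhancer_hyper_in_cancer": 30,
            "esse_hypo_in_cancer": 70,
            "esse_hyper_in_cancer": 46,
            "esse_stable": 38,
            "hsc_enhancer": 32,
            "inert_distal": 22,
        }
    )
    # methylation replicate structure (per cell type)
    meth_samples: dict[str, int] = field(
        default_factory=lambda: {"ES": 3, "HSC": 2, "TCELL": 2, "CANCER": 2}
    )
    # the source datasets carry several replicates per cell type (six ES
    # lines, seven HSC samples, twelve T/B derivatives); three per cell
    # type keeps that structure at miniature scale
    chip_samples: dict[str, int] = field(
        default_factory=lambda: {"ES": 3, "HSC": 3, "TCELL": 3}
    )
    stages: dict[str, str] = field(
        default_factory=lambda: {
            "ES": "es", "HSC": "stem", "TCELL": "differentiated",
            "CANCER": "cancer",
        }
    )
    beta_concentration: float = 50.0  # Beta(mean*k, (1-mean)*k)
    # mark-track signal model
    peak_height: float = 4.0  # domain level, in units of noise sd
    noise_sd: float = 1.0
    domain_halfwidth: int = 3_000
    taper_sd: int = 200
    decoy_offset: int = 5_500  # decoy-domain center offset at negative sites
    resolution: int = 100  # bp per WIG datum
    peak_offset: int = 0  # shift of signal domains off the probe coordinate
    # promoter CpG-island blocks
    island_halfwidth: int = 300
    # 4C model
    fourc_bait_chrom: str = "chr1"
    fourc_bait_pos: int = 1_000_000
    fourc_site_offset: int = 60_000  # interacting site, relative to bait
    fourc_domain_halfwidth: int = 10_000
    fourc_cells: dict[str, dict] = field(
        default_factory=lambda: {
            "bcell": {"n_mapped": 40_000, "mapped_fraction": 0.959,
                      "peak_fraction": 0.12},
            "erythroid": {"n_mapped": 40_000, "mapped_fraction": 0.908,
                          "peak_fraction": 0.0},
        }
    )
    fourc_decay_scale: int = 80_000
    # expression coupling: expr = base - slope * beta + noise
    expr_base: float = 10.0
    expr_slope: float = 8.0
    expr_noise_sd: float = 0.5
    n_random_gene_sets: int = 20

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        n_loci = sum(
            length // self.locus_spacing for length in self.chrom_lengths.values()
        )
        if sum(self.class_counts.values()) > n_loci:
            raise ValueError(
                f"{sum(self.class_counts.values())} planted sites exceed the "
                f"{n_loci} available loci"
            )


def generate_beta(cls: str, cell_type: str, config: SimulationConfig, rng) -> float:
    """One beta draw for a site of planted class ``cls`` in ``cell_type``."""
    mean = BETA_MEANS[cls][cell_type]
    k = config.beta_concentration
    return float(rng.beta(mean * k, (1.0 - mean) * k))


def sample_transition_classes(n: int, fractions, rng) -> np.ndarray:
    """Multinomial draw of lose/retain/gain labels at the given fractions."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size != 3 or not np.isclose(fractions.sum(), 1.0, atol=1e-6):
        raise ValueError("fractions must be 3 values summing to 1")
    labels = np.array(["lose", "retain", "gain"])
    return labels[rng.choice(3, size=n, p=fractions / fractions.sum())]


# ---------------------------------------------------------------------------
# genome sequence


def _random_depleted_sequence(length: int, rng) -> np.ndarray:
    """CpG-depleted background sequence as a uint8 base array."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=length, p=[0.31, 0.19, 0.19, 0.31])
    cg = np.nonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))[0]
    mutate = cg[rng.random(cg.size) < 0.95] + 1
    seq[mutate] = ord("A")
    return seq


def _island_block(length: int, rng) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=length, p=[0.15, 0.35, 0.35, 0.15])


# ---------------------------------------------------------------------------
# mark tracks


def _domain_profile(grid: np.ndarray, center: float, halfwidth: float,
                    taper_sd: float, height: float) -> np.ndarray:
    """Plateau of ``height`` over +/-halfwidth with Gaussian shoulders."""
    excess = np.abs(grid - center) - halfwidth
    out = np.where(excess <= 0, height,
                   height * np.exp(-0.5 * (np.maximum(excess, 0) / taper_sd) ** 2))
    out[excess > 6 * taper_sd] = 0.0
    return out


def _make_track(
    chrom_lengths: dict[str, int],
    domain_centers: dict[str, np.ndarray],
    config: SimulationConfig,
    rng,
) -> SignalTrack:
    res = config.resolution
    # peak height is in units of the noise sd; in the noiseless limit it
    # falls back to an absolute height so the signal does not vanish
    h = config.peak_height * (config.noise_sd if config.noise_sd > 0 else 1.0)
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, length in sorted(chrom_lengths.items()):
        n = length // res
        grid = np.arange(n, dtype=np.float64) * res + res / 2.0
        signal = rng.normal(0.0, config.noise_sd, size=n)
        reach = config.domain_halfwidth + 6 * config.taper_sd
        for c in domain_centers.get(chrom, ()):
            lo = max(0, int((c - reach) // res))
            hi = min(n, int((c + reach) // res) + 1)
            signal[lo:hi] += _domain_profile(
                grid[lo:hi], c, config.domain_halfwidth, config.taper_sd, h
            )
        starts = np.arange(n, dtype=np.int64) * res
        runs[chrom] = list(zip(starts.tolist(), [res] * n,
                               np.round(signal, 4).tolist()))
    return SignalTrack.from_runs(runs)


def simulate_mark_cohort(
    n_sites: int = 1_000,
    frac_positive: float = 0.5,
    n_samples: int = 2,
    seed: int = 0,
    config: SimulationConfig | None = None,
):
    """Tracks + planted states for a focused mark-recovery experiment.

    Returns (tracks: {sample_id: SignalTrack}, sites frame, truth Series of
    "positive"/"negative").  One cell type; ``n_samples`` replicate tracks.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    spacing, offset = config.locus_spacing, config.site_offset
    length = n_sites * spacing + spacing
    chrom = "chrSim"
    pos = np.arange(n_sites, dtype=np.int64) * spacing + offset
    positive = np.zeros(n_sites, dtype=bool)
    positive[rng.permutation(n_sites)[: int(round(frac_positive * n_sites))]] = True
    centers = np.where(
        positive, pos + config.peak_offset, pos + config.decoy_offset
    ).astype(float)
    tracks = {
        f"sim{i + 1}": _make_track(
            {chrom: length}, {chrom: centers}, config, rng
        )
        for i in range(n_samples)
    }
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos},
        index=pd.Index([f"cg{i:05d}" for i in range(n_sites)], name="site_id"),
    )
    truth = pd.Series(
        np.where(positive, "positive", "negative"), index=sites.index
    )
    return tracks, sites, truth


# ---------------------------------------------------------------------------
# fate cohort


def simulate_fate_cohort(
    n_sites: int = 2_000,
    frac_planted: float = 0.5,
    delta: float = -0.3,
    noise_sd: float = 0.05,
    n_replicates: int = 2,
    base_beta: float = 0.7,
    seed: int = 0,
) -> tuple[MethylationMatrix, pd.Series]:
    """Two-stage beta matrix with a planted methylation shift.

    Planted sites move by ``delta`` between "early" and "late"; the rest
    are null.  Per-replicate measurement noise is Gaussian with the given
    sd, clipped into [0, 1].  Returns (matrix, truth flags).
    """
    rng = np.random.default_rng(seed)
    planted = np.zeros(n_sites, dtype=bool)
    planted[rng.permutation(n_sites)[: int(round(frac_planted * n_sites))]] = True
    ids = [f"cg{i:05d}" for i in range(n_sites)]
    cols = {}
    sample_rows = []
    for stage, shift in (("early", 0.0), ("late", delta)):
        for r in range(n_replicates):
            name = f"{stage}{r + 1}"
            vals = base_beta + shift * planted + rng.normal(0, noise_sd, n_sites)
            cols[name] = np.clip(vals, 0.0, 1.0)
            sample_rows.append((name, stage, stage))
    beta = pd.DataFrame(cols, index=pd.Index(ids, name="site_id"))
    sites = pd.DataFrame(
        {"chrom": "chrSim", "pos": np.arange(n_sites) * 1_000 + 500},
        index=beta.index,
    )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "cell_type", "stage"]
    ).set_index("sample_id")
    matrix = MethylationMatrix(sites=sites, samples=samples, beta=beta)
    return matrix, pd.Series(planted, index=beta.index, name="planted")


# ---------------------------------------------------------------------------
# 4C reads


def simulate_fourc_reads(
    config: SimulationConfig, cell: str, rng
) -> np.ndarray:
    """Mapped junction-read positions for one 4C cell type.

    Background contacts decay exponentially with distance from the bait;
    a fraction of reads is placed uniformly in the planted interaction
    domain around the interacting site.
    """
    pars = config.fourc_cells[cell]
    n = int(pars["n_mapped"])
    peak_frac = float(pars.get("peak_fraction", 0.0))
    chrom_len = config.chrom_lengths[config.fourc_bait_chrom]
    n_peak = int(round(peak_frac * n))
    n_bg = n - n_peak
    dist = rng.exponential(config.fourc_decay_scale, size=n_bg)
    side = rng.choice([-1, 1], size=n_bg)
    bg = config.fourc_bait_pos + side * dist
    center = config.fourc_bait_pos + config.fourc_site_offset
    hw = config.fourc_domain_halfwidth
    peak = rng.uniform(center - hw, center + hw, size=n_peak)
    pos = np.concatenate([bg, peak])
    return np.sort(np.clip(np.round(pos), 0, chrom_len - 1).astype(np.int64))


# ---------------------------------------------------------------------------
# the full study


def generate_study(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], dict]:
    """Write the full synthetic study to ``outdir``.

    Returns (paths, truth manifest).  Outputs are byte-identical for
    identical configs (one seeded generator, fixed draw order, fixed float
    formatting).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- site layout -------------------------------------------------------
    loci = []  # (chrom, site_pos)
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n = length // config.locus_spacing
        # keep the last locus's decoy/gene inside the chromosome
        while (n - 1) * config.locus_spacing + config.site_offset + \
                config.locus_spacing > length:
            n -= 1
        for i in range(n):
            loci.append((chrom, i * config.locus_spacing + config.site_offset))
    labels = [c for c in PLANTED_CLASSES for _ in range(config.class_counts.get(c, 0))]
    if len(labels) < len(loci):  # unused loci carry no site
        labels += [None] * (len(loci) - len(labels))
    order = rng.permutation(len(loci))
    assignment = [(loci[i], labels[j]) for j, i in enumerate(order)]
    assignment = [(lc, lb) for lc, lb in assignment if lb is not None]
    assignment.sort(key=lambda t: (t[0][0], t[0][1]))

    site_ids = [f"cg{i + 1:05d}" for i in range(len(assignment))]
    site_chrom = [lc[0] for lc, _ in assignment]
    site_pos = [lc[1] for lc, _ in assignment]
    site_class = [lb for _, lb in assignment]

    # --- genes -------------------------------------------------------------
    genes: list[GeneModel] = []
    island_centers: dict[str, list[int]] = {}
    prom_offsets = rng.integers(-2_000, 2_001, size=len(assignment))
    lo, hi = config.distal_gene_offset
    distal_offsets = rng.integers(lo, hi + 1, size=len(assignment))
    strands = np.where(rng.random(len(assignment)) < 0.5, "+", "-")
    for i, ((chrom, pos), cls) in enumerate(assignment):
        strand = str(strands[i])
        if cls == "promoter":
            tss = pos + int(prom_offsets[i])
            island_centers.setdefault(chrom, []).append(tss)
        else:
            tss = pos + int(distal_offsets[i])
        body = (
            GenomeInterval(chrom, tss, tss + 1_500, strand)
            if strand == "+"
            else GenomeInterval(chrom, tss - 1_499, tss + 1, strand)
        )
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:04d}", symbol=f"G{i + 1:04d}",
                tss_chrom=chrom, tss_pos=tss, strand=strand, body=body,
            )
        )

    # --- genome sequence ---------------------------------------------------
    genome: dict[str, str] = {}
    for chrom in sorted(config.chrom_lengths):
        seq = _random_depleted_sequence(config.chrom_lengths[chrom], rng)
        for c in island_centers.get(chrom, ()):
            lo = max(0, c - config.island_halfwidth)
            hi = min(len(seq), c + config.island_halfwidth)
            seq[lo:hi] = _island_block(hi - lo, rng)
        genome[chrom] = seq.tobytes().decode("ascii")

    # --- methylation matrix ------------------------------------------------
    meth_cols: dict[str, np.ndarray] = {}
    sample_rows = []
    for ct in config.meth_samples:
        for r in range(config.meth_samples[ct]):
            name = f"{ct}{r + 1}"
            meth_cols[name] = np.array(
                [generate_beta(cls, ct, config, rng) for cls in site_class]
            )
            sample_rows.append((name, ct, config.stages[ct]))

    # --- chip tracks -------------------------------------------------------
    track_rows = []
    track_paths: dict[str, Path] = {}
    for ct in config.chip_samples:
        centers: dict[str, np.ndarray] = {}
        for chrom in sorted(config.chrom_lengths):
            cc = []
            for (schrom, pos), cls in assignment:
                if schrom != chrom:
                    continue
                if MARK_STATES[cls][ct]:
                    cc.append(pos + config.peak_offset)
                else:
                    cc.append(pos + config.decoy_offset)
            centers[chrom] = np.asarray(cc, dtype=float)
        for r in range(config.chip_samples[ct]):
            name = f"{ct}_chip{r + 1}"
            track = _make_track(config.chrom_lengths, centers, config, rng)
            path = outdir / f"{name}_H3K4me1.wig"
            _write_fixedstep_wig(track, path, config.resolution, name)
            track_rows.append((name, ct, "H3K4me1", path.name))
            track_paths[name] = path

    # --- expression --------------------------------------------------------
    expr_rows = []
    for i, cls in enumerate(site_class):
        for ct in config.meth_samples:
            expr = (
                config.expr_base
                - config.expr_slope * BETA_MEANS[cls][ct]
                + rng.normal(0, config.expr_noise_sd)
            )
            expr_rows.append((genes[i].gene_id, ct, round(float(expr), 4)))

    # --- 4C reads ----------------------------------------------------------
    fourc_paths = {}
    fourc_meta = {
        "bait_chrom": config.fourc_bait_chrom,
        "bait_pos": config.fourc_bait_pos,
        "site_center": config.fourc_bait_pos + config.fourc_site_offset,
        "cells": {},
    }
    for cell in config.fourc_cells:
        reads = simulate_fourc_reads(config, cell, rng)
        path = outdir / f"fourc_{cell}.bed"
        with open(path, "w") as fh:
            for p in reads:
                fh.write(f"{config.fourc_bait_chrom}\t{p}\t{p + 1}\n")
        frac = float(config.fourc_cells[cell]["mapped_fraction"])
        fourc_paths[cell] = path
        fourc_meta["cells"][cell] = {
            "path": path.name,
            "n_mapped": int(reads.size),
            "n_raw": int(round(reads.size / frac)),
        }

    # --- gene sets ---------------------------------------------------------
    symbols = [g.symbol for g in genes]
    hyper_symbols = {
        genes[i].symbol for i, c in enumerate(site_class)
        if c == "esse_hyper_in_cancer"
    }
    sets = {"POLYCOMB_TARGETS": set(hyper_symbols)}
    for j in range(config.n_random_gene_sets):
        size = int(rng.integers(15, 60))
        members = set(rng.choice(symbols, size=size, replace=False))
        sets[f"RANDOM_{j + 1:02d}"] = members

    # --- write everything --------------------------------------------------
    paths = {name: outdir / fname for name, fname in [
        ("genome", "genome.fa"), ("genes", "genes.bed"),
        ("islands", "islands.bed"), ("methylation", "methylation.tsv"),
        ("samples", "samples.tsv"), ("tracks", "tracks.tsv"),
        ("expression", "expression.tsv"), ("gene_sets", "gene_sets.gmt"),
        ("fourc", "fourc.json"), ("truth", "truth.json"),
    ]}
    write_fasta(genome, paths["genome"])
    write_gene_models(genes, paths["genes"])
    write_bed_intervals(
        [GenomeInterval(ch, max(0, c - config.island_halfwidth),
                        c + config.island_halfwidth, name=f"island_{ch}_{c}")
         for ch in sorted(island_centers) for c in sorted(island_centers[ch])],
        paths["islands"],
    )
    with open(paths["methylation"], "w") as fh:
        samples_order = [r[0] for r in sample_rows]
        fh.write("site_id\tchrom\tpos\t" + "\t".join(samples_order) + "\n")
        for i, sid in enumerate(site_ids):
            vals = "\t".join(f"{meth_cols[s][i]:.4f}" for s in samples_order)
            fh.write(f"{sid}\t{site_chrom[i]}\t{site_pos[i]}\t{vals}\n")
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tcell_type\tstage\n")
        for row in sample_rows:
            fh.write("\t".join(row) + "\n")
    with open(paths["tracks"], "w") as fh:
        fh.write("sample_id\tcell_type\tmark\tpath\n")
        for row in track_rows:
            fh.write("\t".join(row) + "\n")
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\tcell_type\texpression\n")
        for row in expr_rows:
            fh.write(f"{row[0]}\t{row[1]}\t{row[2]}\n")
    write_gene_sets(sets, paths["gene_sets"])
    with open(paths["fourc"], "w") as fh:
        json.dump(fourc_meta, fh, indent=1, sort_keys=True)

    truth = {
        "config": {k: v for k, v in asdict(config).items()},
        "sites": [
            {
                "site_id": sid, "chrom": site_chrom[i], "pos": int(site_pos[i]),
                "class": site_class[i], "nearest_gene": genes[i].gene_id,
                "mark_states": {
                    ct: ("positive" if MARK_STATES[site_class[i]][ct] else "negative")
                    for ct in config.chip_samples
                },
                "beta_means": BETA_MEANS[site_class[i]],
            }
            for i, sid in enumerate(site_ids)
        ],
        "fourc": fourc_meta,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths, truth


def _write_fixedstep_wig(
    track: SignalTrack, path: Path, resolution: int, name: str
) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in track.chroms():
            starts, spans, values = track.data[chrom]
            fh.write(
                f"fixedStep chrom={chrom} start={int(starts[0]) + 1} "
                f"step={resolution} span={resolution}\n"
            )
            fh.write("\n".join(f"{v:.4f}" for v in values) + "\n")
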