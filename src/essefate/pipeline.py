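"""Pipeline orchestration: compose the stages into reproducible runs.

Stages communicate through the site table TSV in the output directory, so
each stage is resumable from the previous stage's output:

  annotate  -> site_table.tsv (coordinates, nearest gene, regulatory class)
  chromatin -> + per-cell-type mark states, transitions, ESSE flag
  fates     -> + per-contrast mean betas, deltas, fate classes; summary.json
  enrich    -> enrichment.tsv (foreground vs background gene sets)
  fourc     -> fourc_windows.tsv + fourc_test.json
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import chromatin, fates, fourc, stats
from .cpg import CpgIslandParams, scan_genome_islands
from .intervals import GenomeInterval
from .io import (
    read_bed_intervals,
    read_fasta,
    read_gene_models,
    read_gene_sets,
    read_methylation_table,
    read_signal_track,
    read_site_table,
    write_bed_intervals,
    write_site_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report_fractions",
           "score_recovery", "stage_annotate", "stage_chromatin",
           "stage_fates", "stage_enrich", "stage_fourc"]


@dataclass
class PipelineConfig:
    """All inputs, thresholds and stage wiring of one pipeline run."""

    inputs: dict[str, str]
    outdir: str
    seed: int = 0
    thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "promoter_max_dist": 2_500,
            "distal_min_dist": 5_000,
            "mark_half_window": 100,
            "fate_threshold": 0.20,
            "undermethylated_max": 0.50,
        }
    )
    esse: dict = field(
        default_factory=lambda: {
            "es": "ES", "hsc": "HSC", "differentiated": ["TCELL"],
            "mode": "default",
        }
    )
    contrasts: list[dict] = field(
        default_factory=lambda: [
            {"name": "dev", "early": "ES", "late": "HSC"},
            {"name": "diff", "early": "HSC", "late": "TCELL"},
            {"name": "cancer", "early": "TCELL", "late": "CANCER"},
        ]
    )
    dev_contrast: str = "dev"
    cancer_contrast: str = "cancer"
    mark_contrasts: list[list[str]] = field(
        default_factory=lambda: [["ES", "HSC"], ["HSC", "TCELL"]]
    )
    _base: Path = field(default_factory=Path, repr=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg._base = path.parent
        return cfg

    @classmethod
    def for_study(cls, study_dir: str | Path, outdir: str | Path,
                  seed: int = 0) -> "PipelineConfig":
        """Config pointing at a directory written by ``generate_study``."""
        study_dir = Path(study_dir)
        cfg = cls(
            inputs={
                "genome_fasta": "genome.fa",
                "genes_bed": "genes.bed",
                "methylation_tsv": "methylation.tsv",
                "sample_sheet": "samples.tsv",
                "tracks_tsv": "tracks.tsv",
                "gene_sets_gmt": "gene_sets.gmt",
                "fourc_json": "fourc.json",
            },
            outdir=str(outdir),
            seed=seed,
        )
        cfg._base = study_dir
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        """Write the config; input paths are resolved to absolute first."""
        data = {
            "inputs": {k: str(self.path(k)) for k in self.inputs},
            "outdir": self.outdir,
            "seed": self.seed,
            "thresholds": dict(self.thresholds),
            "esse": dict(self.esse),
            "contrasts": list(self.contrasts),
            "dev_contrast": self.dev_contrast,
            "cancer_contrast": self.cancer_contrast,
            "mark_contrasts": [list(c) for c in self.mark_contrasts],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def path(self, key: str) -> Path:
        p = Path(self.inputs[key])
        return p if p.is_absolute() else self._base / p

    def out(self, name: str) -> Path:
        d = Path(self.outdir)
        d.mkdir(parents=True, exist_ok=True)
        return d / name


def _load_islands(cfg: PipelineConfig) -> list[GenomeInterval]:
    """Precomputed island BED if configured, else scan the genome FASTA."""
    if "islands_bed" in cfg.inputs:
        return read_bed_intervals(cfg.path("islands_bed"))
    genome = read_fasta(cfg.path("genome_fasta"))
    islands = scan_genome_islands(genome, CpgIslandParams())
    write_bed_intervals(islands, cfg.out("islands_scanned.bed"))
    return islands


def stage_annotate(cfg: PipelineConfig) -> pd.DataFrame:
    matrix = read_methylation_table(
        cfg.path("methylation_tsv"), cfg.path("sample_sheet")
    )
    genes = read_gene_models(cfg.path("genes_bed"))
    islands = _load_islands(cfg)
    th = cfg.thresholds
    table = ann.annotate_sites(
        matrix.sites, genes, islands,
        promoter_max_dist=int(th["promoter_max_dist"]),
        distal_min_dist=int(th["distal_min_dist"]),
    )
    logger.info("annotated %d sites (%s)", len(table),
                table["site_class"].value_counts().to_dict())
    write_site_table(table, cfg.out("site_table.tsv"))
    return table


def stage_chromatin(cfg: PipelineConfig) -> pd.DataFrame:
    table = read_site_table(cfg.out("site_table.tsv"))
    tracks_sheet = pd.read_csv(cfg.path("tracks_tsv"), sep="\t", dtype=str)
    track_dir = cfg.path("tracks_tsv").parent
    hw = int(cfg.thresholds["mark_half_window"])
    for mark in sorted(tracks_sheet["mark"].unique()):
        sub = tracks_sheet[tracks_sheet["mark"] == mark]
        tracks = {
            row.sample_id: read_signal_track(track_dir / row.path)
            for row in sub.itertuples()
        }
        scores = chromatin.score_sites(tracks, table, half_window=hw)
        ct_of = dict(zip(sub["sample_id"], sub["cell_type"]))
        states = chromatin.state_table(scores, ct_of)
        for ct in states.columns:
            table[f"{mark}_{ct}"] = states[ct]
        contrasts = [
            (a, b) for a, b in cfg.mark_contrasts
            if a in states.columns and b in states.columns
        ]
        trans = chromatin.transition_table(states, contrasts)
        for col in trans.columns:
            table[f"{mark}_{col}"] = trans[col]
        if mark == "H3K4me1":
            es, hsc = cfg.esse["es"], cfg.esse["hsc"]
            strict = cfg.esse.get("mode", "default") == "strict"
            diff = list(cfg.esse.get("differentiated", []))
            flags = []
            for _, row in states.iterrows():
                st = {
                    ct: (None if pd.isna(row[ct]) else row[ct])
                    for ct in states.columns
                }
                distal = (
                    table.loc[row.name, "site_class"] == "distal_regulatory"
                )
                f = chromatin.call_esse(st, es, hsc, diff, strict)
                # stored as 1/0/NA so the column survives TSV round trips
                flags.append(np.nan if f is None else float(f and distal))
            table["esse"] = flags
    write_site_table(table, cfg.out("site_table.tsv"))
    return table


def stage_fates(cfg: PipelineConfig) -> pd.DataFrame:
    table = read_site_table(cfg.out("site_table.tsv"))
    matrix = read_methylation_table(
        cfg.path("methylation_tsv"), cfg.path("sample_sheet")
    )
    th = cfg.thresholds
    fate_th = float(th["fate_threshold"])
    contrast_frames = {}
    for spec_ in cfg.contrasts:
        name, early, late = spec_["name"], spec_["early"], spec_["late"]
        cdf = fates.contrast(matrix, early, late)
        contrast_frames[name] = cdf
        table[f"beta_{early}"] = cdf["beta_early"]
        table[f"beta_{late}"] = cdf["beta_late"]
        table[f"delta_{name}"] = cdf["delta"]
        table[f"fate_{name}"] = fates.classify_fate(cdf["delta"], fate_th)
    write_site_table(table, cfg.out("site_table.tsv"))

    summary = _summarize(cfg, table, matrix, contrast_frames)
    with open(cfg.out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return table


def _summarize(cfg, table, matrix, contrast_frames) -> dict:
    th = cfg.thresholds
    fate_th = float(th["fate_threshold"])
    under_th = float(th["undermethylated_max"])
    es, hsc = cfg.esse["es"], cfg.esse["hsc"]
    summary: dict = {
        "thresholds": dict(th),
        "n_sites": int(len(table)),
        "site_classes": table["site_class"].value_counts().to_dict(),
    }

    # transition fractions over marked sites (positive in either stage)
    trans_col = f"H3K4me1_{es}_to_{hsc}"
    if trans_col in table.columns:
        distal = table[table["site_class"] == "distal_regulatory"]
        marked = distal[distal[trans_col].isin(["lose", "retain", "gain"])]
        counts = marked[trans_col].value_counts().to_dict()
        counts = {k: int(counts.get(k, 0)) for k in ("lose", "retain", "gain")}
        summary["h3k4me1_transitions"] = {
            "counts": counts,
            "percent": fates.fraction_report(counts) if marked.size else None,
        }

    esse_sites = set(table.index[table["esse"] == 1])
    summary["n_esse"] = len(esse_sites)

    cancer = contrast_frames.get(cfg.cancer_contrast)
    dev = contrast_frames.get(cfg.dev_contrast)
    if cancer is not None and esse_sites:
        part = fates.partition_esse_fates(esse_sites, cancer, fate_th)
        summary["esse_cancer_fates"] = {
            "counts": part.counts, "percent": part.fractions,
        }
        normal_cts = [es, hsc, *cfg.esse.get("differentiated", [])]
        normal_means = {
            ct: fates.mean_beta(matrix, ct)
            for ct in normal_cts if ct in matrix.cell_types()
        }
        fg = fates.foreground_hyper_esse(
            esse_sites, normal_means, cancer, under_th, fate_th
        )
        distal_sites = set(table.index[table["site_class"] == "distal_regulatory"])
        bg = fates.background_hyper_distal(distal_sites, cancer, fate_th)
        summary["foreground_hyper_esse"] = {"n": len(fg)}
        summary["background_hyper_distal"] = {"n": len(bg)}
        # undermethylation of the cancer-hyper ESSE set in ES
        if part.hyper:
            es_means = fates.mean_beta(matrix, es).loc[sorted(part.hyper)]
            under = fates.undermethylated(es_means, under_th)
            summary["esse_hyper_undermeth_in_es"] = {
                "n_under": int(under.sum()), "n": int(len(under)),
                "percent": round(100.0 * float(under.mean()), 1),
            }
        if dev is not None:
            repro = fates.reprogrammed_hypo_esse(esse_sites, dev, cancer, fate_th)
            summary["reprogrammed_hypo_esse"] = {"n": len(repro)}
            # Venn: cancer-hypo ESSEs vs developmentally hypermethylated ESSEs
            ids = sorted(esse_sites)
            set_a = set(pd.Index(ids)[(cancer.loc[ids, "delta"] <= -fate_th)])
            set_b = set(pd.Index(ids)[(dev.loc[ids, "delta"] >= fate_th)])
            test = stats.venn_overlap_p(
                len(set_a & set_b), len(set_a), len(set_b), len(ids)
            )
            summary["venn_cancer_hypo_vs_dev_hyper"] = {
                "k": test.k, "n_a": test.n_a, "n_b": test.n_b, "N": test.N,
                "expected": test.expected, "p_enrich": test.p_enrich,
                "p_deplete": test.p_deplete,
            }
    return summary


def stage_enrich(cfg: PipelineConfig) -> pd.DataFrame | None:
    if "gene_sets_gmt" not in cfg.inputs:
        return None
    table = read_site_table(cfg.out("site_table.tsv"))
    matrix = read_methylation_table(
        cfg.path("methylation_tsv"), cfg.path("sample_sheet")
    )
    collection = read_gene_sets(cfg.path("gene_sets_gmt"))
    th = cfg.thresholds
    fate_th = float(th["fate_threshold"])
    es, hsc = cfg.esse["es"], cfg.esse["hsc"]
    cspec = next(c for c in cfg.contrasts if c["name"] == cfg.cancer_contrast)
    cancer = fates.contrast(matrix, cspec["early"], cspec["late"])
    esse_sites = set(table.index[table["esse"] == 1])
    normal_cts = [es, hsc, *cfg.esse.get("differentiated", [])]
    normal_means = {
        ct: fates.mean_beta(matrix, ct)
        for ct in normal_cts if ct in matrix.cell_types()
    }
    fg_sites = fates.foreground_hyper_esse(
        esse_sites, normal_means, cancer, float(th["undermethylated_max"]), fate_th
    )
    distal_sites = set(table.index[table["site_class"] == "distal_regulatory"])
    bg_sites = fates.background_hyper_distal(distal_sites, cancer, fate_th)
    fg_genes = set(table.loc[sorted(fg_sites), "nearest_gene"].dropna())
    bg_genes = set(table.loc[sorted(bg_sites), "nearest_gene"].dropna())
    if not fg_genes or not bg_genes:
        logger.warning("empty foreground or background gene set; enrichment skipped")
        return None
    results = stats.gene_set_enrichment(fg_genes, bg_genes, collection)
    df = pd.DataFrame(
        [
            {
                "set_name": r.set_name, "k_fg": r.k_fg, "n_fg": r.n_fg,
                "k_bg": r.k_bg, "n_bg": r.n_bg, "odds_ratio": r.odds_ratio,
                "p": r.p, "q": r.q,
            }
            for r in results
        ]
    )
    df.to_csv(cfg.out("enrichment.tsv"), sep="\t", index=False)
    return df


def stage_fourc(cfg: PipelineConfig) -> dict | None:
    if "fourc_json" not in cfg.inputs:
        return None
    with open(cfg.path("fourc_json")) as fh:
        meta = json.load(fh)
    base = cfg.path("fourc_json").parent
    chrom = meta["bait_chrom"]
    bait = GenomeInterval(chrom, int(meta["bait_pos"]), int(meta["bait_pos"]) + 1)
    center = int(meta["site_center"])
    span = fourc.DIFF_SPAN
    region = GenomeInterval(chrom, center - span // 2, center + span // 2)
    profiles = {}
    result: dict = {"cells": {}}
    for cell, info in sorted(meta["cells"].items()):
        reads = fourc.read_read_positions(base / info["path"])
        prof = fourc.FourCProfile(
            cell_type=cell, bait=bait, reads=reads,
            total_reads=int(info.get("n_raw", 0)) or None,
        )
        profiles[cell] = fourc.window_percent_reads(prof, region)
        raw, pct = fourc.mapping_summary(prof.total_reads, prof.n_mapped)
        result["cells"][cell] = {
            "n_raw": raw, "n_mapped": prof.n_mapped, "mapped_percent": pct,
        }
    rows = []
    for cell, wp in profiles.items():
        for w, c, p in zip(wp.windows, wp.counts, wp.percent_reads):
            rows.append((cell, w.chrom, w.start, w.end, int(c), p))
    pd.DataFrame(
        rows, columns=["cell_type", "chrom", "start", "end", "count",
                       "percent_reads"],
    ).to_csv(cfg.out("fourc_windows.tsv"), sep="\t", index=False)
    cells = sorted(profiles)
    if len(cells) == 2:
        t, p = fourc.differential_interaction(profiles[cells[0]], profiles[cells[1]])
        result["differential"] = {
            "a": cells[0], "b": cells[1], "t": t, "p": p,
            "region": [region.chrom, region.start, region.end],
        }
    with open(cfg.out("fourc_test.json"), "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True)
    return result


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also on disk as JSON)."""
    stage_annotate(cfg)
    stage_chromatin(cfg)
    stage_fates(cfg)
    stage_enrich(cfg)
    stage_fourc(cfg)
    with open(cfg.out("summary.json")) as fh:
        return json.load(fh)


def report_fractions(table: pd.DataFrame, fate_col: str) -> dict:
    """Per-class counts and one-decimal percentages for a fate column."""
    sub = table[fate_col].dropna()
    counts = sub.value_counts().to_dict()
    counts = {k: int(v) for k, v in counts.items()}
    return {
        "counts": counts,
        "percent": fates.fraction_report(counts) if counts else None,
    }


# ---------------------------------------------------------------------------
# truth scoring


def predict_planted_class(cfg: PipelineConfig, row: pd.Series) -> str | None:
    """Map a fully annotated site-table row back to a planted class label."""
    es, hsc = cfg.esse["es"], cfg.esse["hsc"]
    if row["site_class"] == "promoter":
        return "promoter"
    if row["site_class"] != "distal_regulatory":
        return None
    trans = row.get(f"H3K4me1_{es}_to_{hsc}")
    if pd.isna(trans):
        return None
    fate = row.get(f"fate_{cfg.cancer_contrast}")
    if trans == "retain":
        if fate == "hypermethylated":
            return "enhancer_hyper_in_cancer"
        return "constitutive_enhancer"
    if trans == "gain":
        return "hsc_enhancer"
    if trans == "absent":
        return "inert_distal"
    if fate == "hypomethylated":
        return "esse_hypo_in_cancer"
    if fate == "hypermethylated":
        return "esse_hyper_in_cancer"
    return "esse_stable"


def score_recovery(cfg: PipelineConfig, table: pd.DataFrame, truth: dict) -> dict:
    """Per-class sensitivity/specificity of planted-class recovery."""
    truth_by_site = {s["site_id"]: s["class"] for s in truth["sites"]}
    pred = {
        sid: predict_planted_class(cfg, row) for sid, row in table.iterrows()
    }
    classes = sorted({c for c in truth_by_site.values()})
    out = {}
    sids = list(truth_by_site)
    for cls in classes:
        tp = sum(1 for s in sids if truth_by_site[s] == cls and pred.get(s) == cls)
        fn = sum(1 for s in sids if truth_by_site[s] == cls and pred.get(s) != cls)
        fp = sum(1 for s in sids if truth_by_site[s] != cls and pred.get(s) == cls)
        tn = sum(1 for s in sids if truth_by_site[s] != cls and pred.get(s) != cls)
        out[cls] = {
            "n": tp + fn,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        }
    out["overall_concordance"] = float(
        np.mean([pred.get(s) == truth_by_site[s] for s in sids])
    )
    return out
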