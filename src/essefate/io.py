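"""Readers and writers for the external formats the pipeline touches.

Coordinate policy: everything is converted to 0-based half-open on read.
WIG (1-based, both fixedStep and variableStep dialects, with span) and
bedGraph become :class:`~essefate.tracks.SignalTrack` run-length data;
BED stays as-is; methylation tables are plain TSV with one beta column per
sample.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomeInterval
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "MethylationMatrix",
    "read_signal_track",
    "write_wig",
    "write_bedgraph",
    "read_methylation_table",
    "read_gene_models",
    "write_gene_models",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_gene_sets",
    "write_gene_sets",
    "read_fasta",
    "write_fasta",
    "write_site_table",
    "read_site_table",
    "PRIMARY_CHROM_RE",
]

# chr1..chr22, chrX/Y (or bare 1..22/X/Y); excludes chrM, chrUn_*, *_random etc.
PRIMARY_CHROM_RE = re.compile(r"^(chr)?([0-9]{1,2}|[XY])$")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# signal tracks


def _parse_wig_attrs(line: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for tok in line.split()[1:]:
        if "=" not in tok:
            raise ParseError(f"line {lineno}: malformed WIG header token {tok!r}")
        k, v = tok.split("=", 1)
        attrs[k] = v
    return attrs


def read_signal_track(path: str | Path, format: str | None = None) -> SignalTrack:
    """Load a WIG (fixedStep/variableStep) or bedGraph signal track.

    ``format`` is "wig", "bedgraph", or None to infer from the extension.
    WIG 1-based starts are shifted to 0-based; ``span`` attributes expand to
    run lengths.  Positions must be non-decreasing per chromosome.
    """
    path = Path(path)
    if format is None:
        format = "bedgraph" if path.suffix.lower() in (".bedgraph", ".bg") else "wig"
    if format not in ("wig", "bedgraph"):
        raise ValueError(f"unknown track format {format!r}")

    runs: dict[str, list[tuple[int, int, float]]] = {}
    if format == "bedgraph":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) != 4:
                    raise ParseError(
                        f"line {lineno}: bedGraph needs 4 columns, got {len(fields)}"
                    )
                chrom, start, end, value = fields
                start, end = int(start), int(end)
                if end <= start:
                    raise ParseError(f"line {lineno}: empty interval")
                runs.setdefault(chrom, []).append((start, end - start, float(value)))
        return SignalTrack.from_runs(runs)

    mode = None  # "fixed" | "variable"
    chrom = ""
    step = span = 1
    nxt = 0  # next 0-based start for fixedStep
    last_end: dict[str, int] = {}

    def _append(ch: str, pos: int, sp: int, value: float, lineno: int) -> None:
        if pos < last_end.get(ch, 0):
            raise ParseError(
                f"line {lineno}: non-monotone or overlapping position on {ch}"
            )
        last_end[ch] = pos + sp
        runs.setdefault(ch, []).append((pos, sp, value))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                attrs = _parse_wig_attrs(line, lineno)
                try:
                    chrom = attrs["chrom"]
                    nxt = int(attrs["start"]) - 1  # 1-based -> 0-based
                    step = int(attrs.get("step", 1))
                except KeyError as e:
                    raise ParseError(f"line {lineno}: fixedStep missing {e}") from None
                span = int(attrs.get("span", 1))
                if nxt < 0 or step < 1 or span < 1 or span > step and step > 1:
                    raise ParseError(f"line {lineno}: invalid fixedStep header")
                mode = "fixed"
            elif line.startswith("variableStep"):
                attrs = _parse_wig_attrs(line, lineno)
                if "chrom" not in attrs:
                    raise ParseError(f"line {lineno}: variableStep missing chrom")
                chrom = attrs["chrom"]
                span = int(attrs.get("span", 1))
                mode = "variable"
            elif mode == "fixed":
                _append(chrom, nxt, span, float(line), lineno)
                nxt += step
            elif mode == "variable":
                fields = line.split()
                if len(fields) != 2:
                    raise ParseError(
                        f"line {lineno}: variableStep data needs 2 columns"
                    )
                _append(chrom, int(fields[0]) - 1, span, float(fields[1]), lineno)
            else:
                raise ParseError(f"line {lineno}: data before any WIG header")
    try:
        return SignalTrack.from_runs(runs)
    except ValueError as e:
        raise ParseError(str(e)) from None


def write_wig(track: SignalTrack, path: str | Path, name: str = "track") -> None:
    """Write as variableStep WIG, one declaration per (chrom, span) block."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in track.chroms():
            starts, spans, values = track.data[chrom]
            cur_span = None
            for s, sp, v in zip(starts, spans, values):
                if sp != cur_span:
                    fh.write(f"variableStep chrom={chrom} span={int(sp)}\n")
                    cur_span = sp
                fh.write(f"{int(s) + 1}\t{v:.6g}\n")


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, spans, values = track.data[chrom]
            for s, sp, v in zip(starts, spans, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(s + sp)}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# methylation matrix


@dataclass
class MethylationMatrix:
    """450K-style beta matrix with site coordinates and sample metadata.

    ``sites``: index site_id, columns chrom, pos (0-based bp).
    ``samples``: index sample_id, columns cell_type, stage (table order).
    ``beta``: sites x samples DataFrame, values in [0, 1] or NaN.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    beta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sites.index.is_unique:
            dup = self.sites.index[self.sites.index.duplicated()][0]
            raise ValueError(f"duplicated site_id {dup!r}")
        vals = self.beta.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta out of [0,1] at site {self.beta.index[i]!r}, "
                f"sample {self.beta.columns[j]!r}: {vals[i, j]}"
            )

    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.samples["cell_type"]))

    def samples_of(self, cell_type: str) -> list[str]:
        return list(self.samples.index[self.samples["cell_type"] == cell_type])


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cell_type", "stage"}
    if not required.issubset(sheet.columns):
        raise ParseError(
            f"sample sheet must have columns {sorted(required)}, "
            f"got {list(sheet.columns)}"
        )
    return sheet.set_index("sample_id")


def read_methylation_table(
    path: str | Path,
    sample_sheet: str | Path,
    include_nonprimary: bool = False,
) -> MethylationMatrix:
    """Read a site x sample beta TSV plus its sample sheet.

    The table header is ``site_id  chrom  pos  <sample> ...``; "NA"/empty
    cells are missing.  Betas outside [0, 1] are rejected with the offending
    site and sample named.  Sites on non-primary chromosomes (chrM,
    scaffolds) are dropped unless ``include_nonprimary``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "chrom": str},
                     na_values=["NA"], keep_default_na=True)
    for col in ("site_id", "chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"methylation table missing column {col!r}")
    sheet = read_sample_sheet(sample_sheet)
    sample_cols = [c for c in df.columns if c not in ("site_id", "chrom", "pos")]
    missing = [s for s in sample_cols if s not in sheet.index]
    if missing:
        raise ParseError(
            f"samples in table absent from sample sheet: {', '.join(missing)}"
        )
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ParseError(f"duplicated site_id {dup!r}")
    if not include_nonprimary:
        keep = df["chrom"].map(lambda c: bool(PRIMARY_CHROM_RE.match(c)))
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d sites on non-primary chromosomes", n_drop)
        df = df[keep]
    sites = df[["site_id", "chrom", "pos"]].set_index("site_id")
    sites["pos"] = sites["pos"].astype(np.int64)
    beta = df.set_index("site_id")[sample_cols].astype(float)
    samples = sheet.loc[sample_cols]
    return MethylationMatrix(sites=sites, samples=samples, beta=beta)


# ---------------------------------------------------------------------------
# gene models and BED


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS (strand-resolved) and body interval."""

    gene_id: str
    symbol: str
    tss_chrom: str
    tss_pos: int
    strand: str
    body: GenomeInterval

    def __post_init__(self) -> None:
        if not self.body.start <= self.tss_pos < self.body.end:
            raise ValueError(
                f"{self.gene_id}: TSS {self.tss_pos} outside body "
                f"[{self.body.start}, {self.body.end})"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read genes from BED6/BED12; TSS = start for "+", end-1 for "-"."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"line {lineno}: gene BED needs >= 6 columns (strand required)"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"line {lineno}: gene {name!r} has strand {strand!r}; "
                    "TSS undefined"
                )
            start, end = int(start), int(end)
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneModel(
                    gene_id=name,
                    symbol=name.upper(),
                    tss_chrom=chrom,
                    tss_pos=tss,
                    strand=strand,
                    body=GenomeInterval(chrom, start, end, strand, name=name),
                )
            )
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.body.chrom}\t{g.body.start}\t{g.body.end}\t"
                f"{g.gene_id}\t0\t{g.strand}\n"
            )


def read_bed_intervals(path: str | Path) -> list[GenomeInterval]:
    """Read plain intervals (>= 3 columns) from BED."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 columns")
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 else "."
            out.append(
                GenomeInterval(
                    fields[0], int(fields[1]), int(fields[2]), strand, name=name
                )
            )
    return out


def write_bed_intervals(intervals: list[GenomeInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: set of uppercase gene symbols}.

    Duplicate genes within a line are deduplicated; empty sets are dropped
    with a warning; a repeated set name is an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"line {lineno}: GMT needs >= 2 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"line {lineno}: duplicate gene set {name!r}")
            members = {g.strip().upper() for g in fields[2:] if g.strip()}
            if not members:
                logger.warning("gene set %r is empty; dropped", name)
                continue
            sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "na", *sorted(sets[name])]) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA into {name: uppercase sequence}."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ParseError(f"duplicate FASTA record {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# site table

#: Fixed column order of the per-site annotation table.  Stage-dependent
#: columns (mark states, contrasts) follow these, in the order produced by
#: the pipeline; the order is stable for a given configuration.
SITE_TABLE_FIXED_COLS = ["site_id", "chrom", "pos"]


def write_site_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-site annotation table as TSV (NaN as "NA").

    The table index is site_id; the write is bit-stable for identical input
    (Python float repr is deterministic and round-trips exactly).
    """
    out = table.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_site_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "chrom": str},
                     na_values=["NA"], keep_default_na=True)
    return df.set_index("site_id")
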