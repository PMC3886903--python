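"""File-format readers and writers for the pipeline.

All tables are plain TSV; trees and manifests are JSON; the annotation is
GFF3-lite plus a two-column term TSV; variants round-trip through a
minimal VCF dialect (CHROM, POS, ID, REF, ALT, QUAL, FILTER, INFO with
DP/AD/CP/BQ2 keys).  Coordinates are 1-based inclusive internally; BED
input (0-based half-open) is converted on ingest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .synthdata import AnnotationSet
from .variants import CnvSegment, VariantCall

__all__ = [
    "FormatError",
    "read_trajectories",
    "write_trajectories",
    "read_competitions",
    "write_fitness_estimates",
    "read_fitness_estimates",
    "read_landscape_table",
    "write_landscape_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_term_annotation",
    "write_term_annotation",
    "write_annotation_gff",
    "read_annotation_gff",
    "read_vcf",
    "write_vcf",
    "read_bed_segments",
    "write_cnv_segments",
    "load_config",
]


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# -- trajectory tables -------------------------------------------------------

TRAJECTORY_COLUMNS = ["mutation_id", "locus", "generation", "frequency",
                      "final_deepseq_freq"]


def write_trajectories(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRAJECTORY_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing trajectory columns {missing}")
    return df


# -- competition assays ------------------------------------------------------

def read_competitions(path):
    """Read competition assays from TSV.

    Columns: ``assay_id, generation`` and either ``ratio`` or both
    ``count_evolved`` and ``count_reference``.  Optional
    ``reference_genotype``.  Returns a list of CompetitionSeries.
    """
    from .fitness import CompetitionSeries

    df = pd.read_csv(path, sep="\t")
    if "assay_id" not in df.columns or "generation" not in df.columns:
        raise FormatError(f"{path}: need assay_id and generation columns")
    has_ratio = "ratio" in df.columns
    has_counts = {"count_evolved", "count_reference"} <= set(df.columns)
    if not (has_ratio or has_counts):
        raise FormatError(
            f"{path}: need a ratio column or count_evolved/count_reference"
        )
    out = []
    for assay, grp in df.groupby("assay_id", sort=True):
        grp = grp.sort_values("generation")
        ref = (
            str(grp["reference_genotype"].iloc[0])
            if "reference_genotype" in grp.columns
            else "ancestor"
        )
        if has_ratio and grp["ratio"].notna().all():
            series = CompetitionSeries(
                generations=grp["generation"].to_numpy(),
                ratio=grp["ratio"].to_numpy(),
                label=str(assay),
                reference_genotype=ref,
            )
        else:
            series = CompetitionSeries(
                generations=grp["generation"].to_numpy(),
                count_evolved=grp["count_evolved"].to_numpy(),
                count_reference=grp["count_reference"].to_numpy(),
                label=str(assay),
                reference_genotype=ref,
            )
        out.append(series)
    return out


def write_fitness_estimates(estimates, path) -> None:
    rows = [
        {
            "assay_id": e.label,
            "s": e.s,
            "se": e.se,
            "ci95_low": e.ci95[0],
            "ci95_high": e.ci95[1],
            "n_points": e.n_points,
            "relative_fitness": e.relative_fitness,
            "reference_genotype": e.reference_genotype,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fitness_estimates(path):
    from .fitness import FitnessEstimate

    df = pd.read_csv(path, sep="\t")
    return [
        FitnessEstimate(
            s=float(r.s),
            se=float(r.se),
            ci95=(float(r.ci95_low), float(r.ci95_high)),
            n_points=int(r.n_points),
            label=str(r.assay_id),
            reference_genotype=str(getattr(r, "reference_genotype", "ancestor")),
        )
        for r in df.itertuples()
    ]


# -- fitness landscapes ------------------------------------------------------

def read_landscape_table(path):
    """Read a genotype fitness table: ``genotype`` (allele list joined with
    ``+``, or ``wt``), ``s``, ``se``.  Returns a FitnessLandscape."""
    from .fitness import FitnessEstimate
    from .landscape import FitnessLandscape

    df = pd.read_csv(path, sep="\t")
    for col in ("genotype", "s", "se"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    pairs = {}
    loci: set[str] = set()
    for r in df.itertuples():
        combo = () if r.genotype in ("wt", "") else tuple(str(r.genotype).split("+"))
        loci.update(combo)
        half = 1.959963984540054 * float(r.se)
        pairs[combo] = FitnessEstimate(
            s=float(r.s),
            se=float(r.se),
            ci95=(float(r.s) - half, float(r.s) + half),
            n_points=int(getattr(r, "n_points", 0)),
            label=str(r.genotype),
        )
    return FitnessLandscape.from_estimates(tuple(sorted(loci)), pairs)


def write_landscape_table(landscape, path) -> None:
    rows = [
        {
            "genotype": "+".join(sorted(combo)) or "wt",
            "s": est.s,
            "se": est.se,
            "n_points": est.n_points,
        }
        for combo, est in sorted(
            landscape.estimates.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        )
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- expression --------------------------------------------------------------

def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_expression_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene identifiers")
    return df


def write_term_annotation(terms: dict[str, set[str]], path) -> None:
    rows = [
        {"term": t, "gene": g} for t in sorted(terms) for g in sorted(terms[t])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_term_annotation(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"term", "gene"} <= set(df.columns):
        raise FormatError(f"{path}: term annotation needs columns term, gene")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.term), set()).add(str(r.gene))
    return out


# -- annotation (GFF3-lite) --------------------------------------------------

GFF_HEADER = "##gff-version 3"


def write_annotation_gff(annotation: AnnotationSet, path) -> None:
    lines = [GFF_HEADER, f"##sequence-region chrI 1 {annotation.genome_length}"]
    for r in annotation.genes.itertuples():
        lines.append(
            "\t".join(
                [
                    "chrI",
                    "chemevolve",
                    "gene",
                    str(r.start),
                    str(r.end),
                    ".",
                    str(r.strand),
                    ".",
                    f"ID={r.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_gff(path, terms: dict[str, set[str]] | None = None) -> AnnotationSet:
    genome_length = 0
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("##sequence-region"):
            genome_length = int(line.split()[-1])
            continue
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 GFF fields")
        if fields[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        if "ID" not in attrs:
            raise FormatError(f"{path}:{lineno}: gene record without ID attribute")
        rows.append(
            {
                "gene_id": attrs["ID"],
                "start": int(fields[3]),
                "end": int(fields[4]),
                "strand": fields[6],
            }
        )
    genes = pd.DataFrame(rows)
    if genome_length == 0 and not genes.empty:
        genome_length = int(genes["end"].max())
    return AnnotationSet(genes=genes, terms=terms or {}, genome_length=genome_length)


# -- variants (minimal VCF) --------------------------------------------------

VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternative read count">',
    '##INFO=<ID=CP,Number=1,Type=Float,Description="Caller p-value">',
    '##INFO=<ID=BQ2,Number=1,Type=Integer,Description="Called at both BQ tiers (1/0)">',
    '##INFO=<ID=SK,Number=1,Type=String,Description="Sample kind">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
]


def write_vcf(calls: Sequence[VariantCall], path) -> None:
    lines = list(VCF_HEADER)
    for c in sorted(calls, key=lambda c: (c.chromosome, c.position, c.alt)):
        info = (
            f"DP={c.total_count};AD={c.alt_count};CP={c.caller_p!r};"
            f"BQ2={int(c.in_both_bq_tiers)};SK={c.sample_kind or 'population'}"
        )
        lines.append(
            "\t".join(
                [
                    c.chromosome,
                    str(c.position),
                    c.sample_id or ".",
                    c.ref,
                    c.alt,
                    ".",
                    ".",
                    info,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> list[VariantCall]:
    calls = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise FormatError(f"{path}:{lineno}: expected >= 8 VCF fields")
        info = dict(
            kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
        )
        for req in ("DP", "AD"):
            if req not in info:
                raise FormatError(
                    f"{path}:{lineno}: INFO field {req} required for read counts"
                )
        calls.append(
            VariantCall(
                chromosome=fields[0],
                position=int(fields[1]),
                ref=fields[3],
                alt=fields[4],
                alt_count=int(info["AD"]),
                total_count=int(info["DP"]),
                caller_p=float(info.get("CP", 0.0)),
                in_both_bq_tiers=bool(int(info.get("BQ2", 1))),
                sample_id=fields[2] if fields[2] != "." else "",
                sample_kind=info.get("SK", "population"),
            )
        )
    return calls


# -- CNV segments ------------------------------------------------------------

def read_bed_segments(path) -> list[CnvSegment]:
    """Read BED-like segments (chrom, start, end, log2) and convert the
    0-based half-open coordinates to 1-based inclusive."""
    segments = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(
                f"{path}:{lineno}: expected chrom, start, end, log2 columns"
            )
        start0, end0 = int(fields[1]), int(fields[2])
        if end0 <= start0:
            raise FormatError(f"{path}:{lineno}: empty or inverted interval")
        segments.append(
            CnvSegment(
                chromosome=fields[0],
                start=start0 + 1,
                end=end0,
                mean_log2=float(fields[3]),
            )
        )
    return segments


def write_cnv_segments(segments: Sequence[CnvSegment], path) -> None:
    rows = [
        {
            "chromosome": s.chromosome,
            "start": s.start,
            "end": s.end,
            "length": s.length,
            "mean_log2": s.mean_log2,
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- configuration -----------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
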