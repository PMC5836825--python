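"""Reading and writing genomic interval formats; promoter and context annotation.

Supported inputs are BED3/6, ENCODE broadPeak (9 columns) / narrowPeak
(10 columns), GENCODE-dialect GTF for gene models, and blacklist BED.
All coordinates are converted to 0-based half-open on read.
"""
from __future__ import annotations

from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, PeakSet, TssRecord

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
_PEAK_EXTRA = ["signal", "p_log10", "q_log10", "summit"]

_DIALECT_NCOLS = {"bed": (3, 6), "broadPeak": (9, 9), "narrowPeak": (10, 10)}


class ParseError(ValueError):
    """Malformed record in an interval or annotation file."""


def read_intervals(path, dialect: str = "bed", resolution: str = "broad") -> PeakSet:
    """Read a BED / broadPeak / narrowPeak file into a :class:`PeakSet`.

    For the ENCODE peak dialects, column 9 holds -log10(q) and is converted
    to a plain q-value.
    """
    if dialect not in _DIALECT_NCOLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    lo, hi = _DIALECT_NCOLS[dialect]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if not (lo <= len(fields) <= hi):
                raise ParseError(
                    f"{path}:{lineno}: expected {lo}-{hi} columns for {dialect}, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            q_value = np.nan
            if dialect in ("broadPeak", "narrowPeak"):
                try:
                    q_log10 = float(fields[8])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric qValue column") from exc
                # MACS writes -1 when the value is unavailable
                q_value = np.nan if q_log10 < 0 else 10.0 ** (-q_log10)
            rows.append((name, chrom, start, end, strand, score, q_value))
    df = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "strand", "score", "q_value"]
    ).set_index("peak_id")
    if df.index.has_duplicates:
        df.index = [f"{pid}_{i}" for i, pid in enumerate(df.index)]
    return PeakSet(df, resolution=resolution)


def write_bed(peaks: PeakSet, path) -> None:
    """Write peaks as BED6 (round-trips coordinates exactly)."""
    df = peaks.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df.index,
            "score": df["score"],
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GeneAnnotation:
    """Gene model: gene bodies, exons, and deduplicated TSS records."""

    genes: pd.DataFrame  # index gene_id: chrom, start, end, strand, gene_name
    exons: pd.DataFrame  # chrom, start, end, gene_id
    tss: list[TssRecord]


def read_annotation(path) -> GeneAnnotation:
    """Parse a GENCODE-dialect GTF into a :class:`GeneAnnotation`.

    GTF is 1-based inclusive; coordinates are converted to 0-based half-open.
    TSS is the 5' end of each transcript (gene when no transcripts present),
    collapsed to unique (gene_id, position).
    """
    genes, exons = {}, []
    tss_gene_level: dict[tuple[str, int], TssRecord] = {}
    tss_tx_level: dict[tuple[str, int], TssRecord] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.strand not in ("+", "-"):
            raise ParseError(f"{path}: feature without strand at {feat.seqid}:{feat.start}")
        try:
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ParseError(f"{path}: feature missing gene_id attribute") from exc
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        start0, end0 = feat.start - 1, feat.end  # to half-open
        if feat.featuretype == "gene":
            genes[gene_id] = (feat.seqid, start0, end0, feat.strand, gene_name)
        elif feat.featuretype == "exon":
            exons.append((feat.seqid, start0, end0, gene_id))
        if feat.featuretype in ("transcript", "gene"):
            pos = start0 if feat.strand == "+" else end0 - 1
            target = tss_tx_level if feat.featuretype == "transcript" else tss_gene_level
            target.setdefault(
                (gene_id, pos), TssRecord(gene_id, gene_name, pos, feat.strand, feat.seqid)
            )
    # transcripts define TSS positions when present; gene records fill in
    # only for genes lacking any transcript feature
    tss_seen = dict(tss_tx_level)
    tx_genes = {gid for gid, _ in tss_tx_level}
    for key, rec in tss_gene_level.items():
        if key[0] not in tx_genes:
            tss_seen.setdefault(key, rec)
    gene_df = pd.DataFrame.from_dict(
        genes, orient="index", columns=["chrom", "start", "end", "strand", "gene_name"]
    )
    gene_df.index.name = "gene_id"
    exon_df = pd.DataFrame(exons, columns=["chrom", "start", "end", "gene_id"])
    records = sorted(tss_seen.values(), key=lambda r: (r.chrom, r.tss, r.gene_id))
    return GeneAnnotation(genes=gene_df, exons=exon_df, tss=records)


def read_tss(path) -> list[TssRecord]:
    """TSS records from a GTF (see :func:`read_annotation`)."""
    return read_annotation(path).tss


def promoter_regions(tss: list[TssRecord], flank: int = 1000) -> list[GenomicInterval]:
    """Promoter windows of ±``flank`` bp around each TSS, clamped at 0."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    return [
        GenomicInterval(t.chrom, max(0, t.tss - flank), t.tss + flank, t.strand) for t in tss
    ]


def _promoter_trees(tss: list[TssRecord], flank: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, t in enumerate(tss):
        trees.setdefault(t.chrom, IntervalTree()).addi(max(0, t.tss - flank), t.tss + flank, i)
    return trees


def _check_chrom_overlap(peak_chroms, other_chroms, what: str) -> None:
    if not set(peak_chroms) & set(other_chroms):
        raise ValueError(
            f"no chromosome names shared between peaks and {what} "
            f"(e.g. 'chr1' vs '1'); use normalize_chrom_names() if needed"
        )


def normalize_chrom_names(names: pd.Series | list[str]) -> list[str]:
    """Strip a leading 'chr' prefix (opt-in harmonizer; mismatch is otherwise an error)."""
    return [n[3:] if n.startswith("chr") else n for n in names]


def assign_peaks(peaks: PeakSet, tss: list[TssRecord], flank: int = 1000) -> PeakSet:
    """Assign peaks to genes whose ±``flank`` promoter window they overlap.

    Records all overlapping genes, the nearest gene by midpoint-to-TSS distance
    (ties broken lexicographically by gene_id), and a bidirectional-promoter
    flag: true when at least two assigned genes have TSS on opposite strands.
    """
    if not tss:
        raise ValueError("empty TSS list")
    _check_chrom_overlap(peaks.df["chrom"].unique(), {t.chrom for t in tss}, "TSS records")
    trees = _promoter_trees(tss, flank)
    assignments: dict[str, list[str]] = {}
    nearest: dict[str, str] = {}
    bidirectional: dict[str, bool] = {}
    for pid, row in peaks.df.iterrows():
        tree = trees.get(row["chrom"])
        hits = sorted(tree.overlap(row["start"], row["end"]), key=lambda iv: iv.data) if tree else []
        hit_tss = [tss[iv.data] for iv in hits]
        genes = sorted({t.gene_id for t in hit_tss})
        if genes:
            assignments[pid] = genes
            mid = (row["start"] + row["end"]) // 2
            nearest[pid] = min(hit_tss, key=lambda t: (abs(t.tss - mid), t.gene_id)).gene_id
            strands = {t.strand for t in hit_tss}
            bidirectional[pid] = len(genes) >= 2 and strands == {"+", "-"}
        else:
            bidirectional[pid] = False
    return PeakSet(
        peaks.df.copy(),
        resolution=peaks.resolution,
        subpeak_parent=peaks.subpeak_parent,
        gene_assignments=assignments,
        nearest_gene=nearest,
        bidirectional=bidirectional,
        context=dict(peaks.context),
    )


def classify_context(peaks: PeakSet, annotation: GeneAnnotation, flank: int = 1000):
    """Label each peak by its midpoint: promoter > exon > intron > intergenic.

    Returns ``(labels, proportions)`` where labels maps peak_id to category.
    """
    prom_trees = _promoter_trees(annotation.tss, flank)
    exon_trees: dict[str, IntervalTree] = {}
    for _, row in annotation.exons.iterrows():
        exon_trees.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"])
    gene_trees: dict[str, IntervalTree] = {}
    for gid, row in annotation.genes.iterrows():
        gene_trees.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"])
    labels: dict[str, str] = {}
    for pid, row in peaks.df.iterrows():
        mid = (row["start"] + row["end"]) // 2
        chrom = row["chrom"]
        if chrom in prom_trees and prom_trees[chrom].overlap(mid, mid + 1):
            labels[pid] = "promoter"
        elif chrom in exon_trees and exon_trees[chrom].overlap(mid, mid + 1):
            labels[pid] = "exon"
        elif chrom in gene_trees and gene_trees[chrom].overlap(mid, mid + 1):
            labels[pid] = "intron"
        else:
            labels[pid] = "intergenic"
    counts = pd.Series(labels).value_counts()
    proportions = (counts / counts.sum()).reindex(
        ["promoter", "exon", "intron", "intergenic"], fill_value=0.0
    )
    return labels, proportions


def subtract_blacklist(peaks: PeakSet, blacklist: list[GenomicInterval]) -> PeakSet:
    """Drop peaks with >=1 bp overlap with any blacklist interval."""
    if not blacklist:
        return peaks
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    keep = [
        pid
        for pid, row in peaks.df.iterrows()
        if row["chrom"] not in trees or not trees[row["chrom"]].overlap(row["start"], row["end"])
    ]
    return peaks.subset(keep)


def read_blacklist(path) -> list[GenomicInterval]:
    """Blacklist BED (3+ columns) as plain intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_annotated_table(peaks: PeakSet, path) -> None:
    """Annotated peak table: coordinates, q, genes, bidirectional flag, context."""
    df = peaks.df.copy()
    df["genes"] = [",".join(peaks.gene_assignments.get(p, [])) for p in df.index]
    df["nearest_gene"] = [peaks.nearest_gene.get(p, "") for p in df.index]
    df["bidirectional"] = [peaks.bidirectional.get(p, False) for p in df.index]
    df["context"] = [peaks.context.get(p, "") for p in df.index]
    df.rename_axis("peak_id").to_csv(path, sep="\t")
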