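"""Readers and writers for the standard text formats the pipeline touches.

FASTA goes through Biopython, GTF through pyranges (which performs the
1-based -> 0-based conversion); BED/narrowPeak and bedGraph are simple
tabular formats handled directly. All writers round-trip with their readers.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr
from Bio import SeqIO

from .types import CoverageTrack, GenomeSequence, Interval, PeakSet


class ParseError(ValueError):
    """Malformed input file; message names the offending line where known."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records (uppercased; U rejected)."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise ParseError(f"record {rec.id!r}: RNA base 'U' not permitted")
        try:
            gs = GenomeSequence(rec.id, seq)
        except ValueError as e:
            raise ParseError(str(e)) from e
        if gs.name in seen:
            raise ParseError(f"duplicate contig name {gs.name!r}")
        seen.add(gs.name)
        records.append(gs)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_intervals(path, dialect: str = "BED") -> PeakSet:
    """Read a BED or narrowPeak file into a PeakSet.

    narrowPeak column 10 (0-based summit offset from start) is mapped to an
    absolute summit; the sentinel -1 means the summit is absent.
    """
    if dialect not in ("BED", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                start, end = int(f[1]), int(f[2])
            except (IndexError, ValueError) as e:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from e
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else "."
            summit = None
            if dialect == "narrowPeak":
                if len(f) < 10:
                    raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns")
                off = int(f[9])
                if off != -1:
                    summit = start + off
            peaks.append(
                Interval(f[0], start, end, strand=strand, summit=summit,
                         score=score, name=name)
            )
    return PeakSet(name=Path(path).stem, peaks=peaks)


def write_intervals(peakset: PeakSet, path, dialect: str = "BED") -> None:
    with open(path, "w") as fh:
        for p in peakset:
            score = "." if p.score is None else f"{p.score:g}"
            row = [p.contig, str(p.start), str(p.end), p.name, score, p.strand]
            if dialect == "narrowPeak":
                off = -1 if p.summit is None else p.summit - p.start
                row += [".", ".", ".", str(off)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, genome: dict[str, int]) -> CoverageTrack:
    """Expand a bedGraph into dense per-base coverage.

    ``genome`` maps contig name -> length. Uncovered positions are 0.
    Overlapping intervals, or intervals beyond the contig end, are errors.
    """
    data = {c: np.zeros(n, dtype=float) for c, n in genome.items()}
    last_end: dict[str, int] = {}
    prev_contig = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            try:
                contig, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            except (IndexError, ValueError) as e:
                raise ParseError(f"{path}:{lineno}: bad bedGraph record") from e
            if contig not in data:
                raise ParseError(f"{path}:{lineno}: unknown contig {contig!r}")
            if end > len(data[contig]):
                raise ParseError(
                    f"{path}:{lineno}: interval end {end} beyond contig length "
                    f"{len(data[contig])}"
                )
            if contig != prev_contig:
                prev_contig = contig
            if start < last_end.get(contig, 0):
                raise ParseError(f"{path}:{lineno}: overlapping intervals on {contig}")
            last_end[contig] = end
            data[contig][start:end] = value
    return CoverageTrack(data)


def write_bedgraph(track: CoverageTrack, path, decimals: int | None = None) -> None:
    """Write coverage as bedGraph, merging runs of equal values; zeros omitted."""
    with open(path, "w") as fh:
        for contig in track.contigs():
            vec = track[contig]
            if decimals is not None:
                vec = np.round(vec, decimals)
            # boundaries of constant runs
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vec)]])
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# GTF gene annotation


def read_gene_annotation(path) -> pd.DataFrame:
    """Load a GTF into a per-gene table.

    Returns a DataFrame indexed by gene_id with columns: contig, strand,
    start, end (0-based half-open gene body), tss, tts (0-based positions),
    exons (list of (start, end) tuples, sorted). TSS is the 5' end of the
    gene: start for + strand, end-1 for - strand.
    """
    df = pr.read_gtf(str(path)).df
    if df.empty:
        raise ParseError(f"{path}: no GTF features")
    genes = df[df.Feature == "gene"]
    if genes.empty:
        # fall back to the span of each gene's exons
        genes = (
            df[df.Feature == "exon"]
            .groupby("gene_id")
            .agg(Chromosome=("Chromosome", "first"), Start=("Start", "min"),
                 End=("End", "max"), Strand=("Strand", "first"))
            .reset_index()
        )
    exon_df = df[df.Feature == "exon"]
    exon_map: dict[str, list[tuple[int, int]]] = {}
    for gid, sub in exon_df.groupby("gene_id"):
        exon_map[gid] = sorted(zip(sub.Start.astype(int), sub.End.astype(int)))
    rows = {}
    for _, g in genes.iterrows():
        strand = str(g.Strand)
        if strand not in ("+", "-"):
            raise ParseError(f"gene {g.gene_id!r}: missing strand")
        start, end = int(g.Start), int(g.End)
        tss = start if strand == "+" else end - 1
        tts = end - 1 if strand == "+" else start
        rows[g.gene_id] = dict(
            contig=str(g.Chromosome), strand=strand, start=start, end=end,
            tss=tss, tts=tts, exons=exon_map.get(g.gene_id, []),
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# generic tables


def write_tsv(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
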