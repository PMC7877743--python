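"""Readers and writers for BED, bedGraph, and alignment files.

Alignments are accepted either as SAM/BAM (via pysam) or as the 6-column
tabular dialect ``chrom  start  end  name  n_hits  strand`` (BED6-shaped,
with the score column carrying the alignment multiplicity).  The 5' end
of each read is derived from its strand: leftmost coordinate on plus,
rightmost on minus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .model import READ_COLUMNS, GenomicBin, reads_to_frame

__all__ = [
    "BedInterval",
    "read_bed_intervals",
    "read_alignments",
    "write_alignments",
    "write_bedgraph",
    "read_bedgraph",
    "read_bins_bed",
    "write_bins_bed",
]


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: Optional[str] = None


class BedParseError(ValueError):
    """Malformed BED/tabular line; message carries the 1-based line number."""


def read_bed_intervals(path: str | Path, min_fields: int = 3) -> list[BedInterval]:
    """Parse a BED3/BED6 file into labelled intervals.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Zero-length or inverted intervals and non-numeric coordinates raise
    :class:`BedParseError` naming the offending line.
    """
    intervals: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields or len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >= {max(min_fields, 3)} fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0:
                raise BedParseError(f"{path}: line {lineno}: negative coordinate")
            if start >= end:
                raise BedParseError(f"{path}: line {lineno}: start >= end (zero-length interval)")
            name = fields[3] if len(fields) > 3 else "."
            score = 0.0
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = None
            if len(fields) > 5:
                if fields[5] not in ("+", "-", "."):
                    raise BedParseError(f"{path}: line {lineno}: bad strand {fields[5]!r}")
                strand = None if fields[5] == "." else fields[5]
            intervals.append(BedInterval(fields[0], start, end, name, score, strand))
    return intervals


def _read_tabular_alignments(path: str | Path) -> tuple[pd.DataFrame, int]:
    chroms: list[str] = []
    five: list[int] = []
    lengths: list[int] = []
    strands: list[str] = []
    hits: list[int] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}: line {lineno}: expected 6 fields")
            chrom = fields[0]
            if chrom == "*":  # unmapped record in the tabular dialect
                skipped += 1
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
                n_hits = int(fields[4])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer field") from exc
            if start < 0:
                raise ValueError(f"{path}: line {lineno}: negative coordinate")
            if start >= end:
                raise BedParseError(f"{path}: line {lineno}: start >= end")
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
            chroms.append(chrom)
            five.append(start if strand == "+" else end - 1)
            lengths.append(end - start)
            strands.append(strand)
            hits.append(n_hits)
    frame = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object),
            "five_prime": np.array(five, dtype=np.int64),
            "length": np.array(lengths, dtype=np.int64),
            "strand": np.array(strands, dtype=object),
            "n_hits": np.array(hits, dtype=np.int64),
        },
        columns=list(READ_COLUMNS),
    )
    return frame, skipped


def _read_sam_alignments(path: str | Path) -> tuple[pd.DataFrame, int]:
    chroms, five, lengths, strands, hits = [], [], [], [], []
    skipped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                skipped += 1
                continue
            start = rec.reference_start  # pysam is already 0-based
            end = rec.reference_end
            if end is None:
                end = start + rec.query_length
            strand = "-" if rec.is_reverse else "+"
            try:
                n_hits = int(rec.get_tag("NH"))
            except KeyError:
                n_hits = 1
            chroms.append(rec.reference_name)
            five.append(start if strand == "+" else end - 1)
            lengths.append(end - start)
            strands.append(strand)
            hits.append(n_hits)
    frame = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object),
            "five_prime": np.array(five, dtype=np.int64),
            "length": np.array(lengths, dtype=np.int64),
            "strand": np.array(strands, dtype=object),
            "n_hits": np.array(hits, dtype=np.int64),
        },
        columns=list(READ_COLUMNS),
    )
    return frame, skipped


def read_alignments(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Load alignments from SAM/BAM or the tabular dialect.

    Returns ``(reads, n_skipped)`` where ``reads`` is the columnar read
    table and ``n_skipped`` tallies unmapped records.
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam"):
        return _read_sam_alignments(path)
    return _read_tabular_alignments(path)


def write_alignments(reads: pd.DataFrame, path: str | Path) -> None:
    """Write the columnar read table in the 6-column tabular dialect."""
    frame = reads_to_frame(reads)
    plus = frame["strand"].to_numpy() == "+"
    five = frame["five_prime"].to_numpy()
    length = frame["length"].to_numpy()
    start = np.where(plus, five, five - length + 1)
    end = np.where(plus, five + length, five + 1)
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "start": start,
            "end": end,
            "name": [f"r{i}" for i in range(len(frame))],
            "n_hits": frame["n_hits"],
            "strand": frame["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(
    bins: Sequence[GenomicBin], values: Sequence[float], path: str | Path
) -> None:
    """Write per-bin values as a 4-column bedGraph.

    Bins must be sorted by (chrom, start); values are written with six
    decimal places so a round-trip read reproduces them.
    """
    if len(bins) != len(values):
        raise ValueError("bins and values differ in length")
    keys = [(b.chrom, b.start) for b in bins]
    if keys != sorted(keys):
        raise ValueError("bins must be sorted by chrom, start")
    with open(path, "w") as fh:
        fh.write("# bedGraph section generated by pirnasl\n")
        for b, v in zip(bins, values):
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{float(v):.6f}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}: line {lineno}: expected 4 fields")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return rows


def write_bins_bed(bins: Sequence[GenomicBin], path: str | Path) -> None:
    """Bins as BED6: name=group label, score=mappability, strand=feature strand."""
    with open(path, "w") as fh:
        for b in bins:
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{b.group}\t{b.mappability:.6f}\t{b.feature_strand}\n"
            )


def read_bins_bed(path: str | Path) -> list[GenomicBin]:
    out = []
    for iv in read_bed_intervals(path, min_fields=6):
        out.append(
            GenomicBin(
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                mappability=float(iv.score),
                group=iv.name if iv.name != "." else "NONE",
                feature_strand=iv.strand or "+",
            )
        )
    return out
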