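"""Domain types: bins, reads, libraries, and the genome annotation bundle.

Coordinates are 0-based half-open (BED convention) everywhere inside the
package; 1-based inputs (SAM POS) are converted on ingest.  A read is
located by its 5'-end coordinate: a plus-strand read with 5' end ``p`` and
length ``L`` occupies ``[p, p+L)``, a minus-strand read occupies
``[p-L+1, p+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_LABELS",
    "GenomicBin",
    "ReadAlignment",
    "Cluster",
    "TransposonFamily",
    "GenomeAnnotation",
    "Library",
    "READ_COLUMNS",
    "reads_to_frame",
    "frame_to_reads",
    "read_interval",
    "bin_id",
]

#: The four source-locus groups plus the unlabelled state.
GROUP_LABELS = ("RD_SL", "RI_SL", "SO_SL", "HET_NON_SL", "NONE")

#: Column layout of the columnar read table carried by a Library.
READ_COLUMNS = ("chrom", "five_prime", "length", "strand", "n_hits")


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-width genomic interval with mappability and group label.

    ``feature_strand`` is the sense orientation of the bin's parent
    feature, used for sense/antisense read selection.  Dual-strand
    clusters use the genomic plus strand as "sense" by convention.
    """

    chrom: str
    start: int
    end: int
    mappability: float = 1.0
    group: str = "NONE"
    feature_strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty bin [{self.start}, {self.end})")
        if not 0.0 <= self.mappability <= 1.0:
            raise ValueError(f"mappability {self.mappability} outside [0, 1]")
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group!r}")
        if self.feature_strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.feature_strand!r}")


def bin_id(b: GenomicBin) -> str:
    """Stable string key for a bin ('chrom:start-end')."""
    return f"{b.chrom}:{b.start}-{b.end}"


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read, located by its 5'-end coordinate."""

    chrom: str
    five_prime: int
    length: int
    strand: str
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.length < 1:
            raise ValueError("read length must be >= 1")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        if self.five_prime < 0:
            raise ValueError("negative coordinate")


def read_interval(read: ReadAlignment) -> tuple[int, int]:
    """Occupied half-open interval of a read derived from 5' end and strand."""
    if read.strand == "+":
        return read.five_prime, read.five_prime + read.length
    return read.five_prime - read.length + 1, read.five_prime + 1


@dataclass(frozen=True)
class Cluster:
    """A piRNA cluster: a genomic interval transcribed on one or both strands."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    cluster_type: str  # "dual_strand" | "uni_strand"
    strand: str = "+"  # sense strand for uni-strand clusters

    def __post_init__(self) -> None:
        if self.cluster_type not in ("dual_strand", "uni_strand"):
            raise ValueError(f"bad cluster_type {self.cluster_type!r}")
        if self.start >= self.end:
            raise ValueError("empty cluster interval")


@dataclass(frozen=True)
class TransposonFamily:
    consensus_id: str
    consensus_length: int

    def __post_init__(self) -> None:
        if self.consensus_length <= 0:
            raise ValueError("consensus_length must be positive")


@dataclass
class GenomeAnnotation:
    """Everything the pipeline needs to know about the reference.

    ``bins`` tile regions of interest at a uniform width (the last bin of
    a chromosome may be shorter); ``mirna_loci`` are the intervals whose
    reads provide the miRNA normalisation factor.
    """

    chrom_sizes: dict[str, int]
    clusters: list[Cluster] = field(default_factory=list)
    transposon_families: list[TransposonFamily] = field(default_factory=list)
    mirna_loci: list[tuple[str, int, int]] = field(default_factory=list)
    bins: list[GenomicBin] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in self.bins:
            self._check_interval(b.chrom, b.start, b.end)
        for c in self.clusters:
            self._check_interval(c.chrom, c.start, c.end)
        for chrom, start, end in self.mirna_loci:
            self._check_interval(chrom, start, end)

    def _check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chrom_sizes:
            raise ValueError(f"interval on unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.chrom_sizes[chrom]):
            raise ValueError(
                f"interval [{start}, {end}) outside {chrom} "
                f"(length {self.chrom_sizes[chrom]})"
            )

    def bin_frame(self) -> pd.DataFrame:
        """Bins as a DataFrame (chrom, start, end, mappability, group, feature_strand)."""
        return pd.DataFrame(
            {
                "chrom": [b.chrom for b in self.bins],
                "start": [b.start for b in self.bins],
                "end": [b.end for b in self.bins],
                "mappability": [b.mappability for b in self.bins],
                "group": [b.group for b in self.bins],
                "feature_strand": [b.feature_strand for b in self.bins],
            }
        )


def reads_to_frame(reads: Iterable[ReadAlignment] | pd.DataFrame) -> pd.DataFrame:
    """Columnar representation of a read collection.

    Large libraries are carried as DataFrames throughout; this is the
    bridge from per-record :class:`ReadAlignment` fixtures.
    """
    if isinstance(reads, pd.DataFrame):
        missing = set(READ_COLUMNS) - set(reads.columns)
        if missing:
            raise ValueError(f"read table missing columns {sorted(missing)}")
        return reads.loc[:, list(READ_COLUMNS)].reset_index(drop=True)
    reads = list(reads)
    return pd.DataFrame(
        {
            "chrom": np.array([r.chrom for r in reads], dtype=object),
            "five_prime": np.array([r.five_prime for r in reads], dtype=np.int64),
            "length": np.array([r.length for r in reads], dtype=np.int64),
            "strand": np.array([r.strand for r in reads], dtype=object),
            "n_hits": np.array([r.n_hits for r in reads], dtype=np.int64),
        },
        columns=list(READ_COLUMNS),
    )


def frame_to_reads(frame: pd.DataFrame) -> list[ReadAlignment]:
    return [
        ReadAlignment(row.chrom, int(row.five_prime), int(row.length), row.strand, int(row.n_hits))
        for row in frame.itertuples(index=False)
    ]


@dataclass
class Library:
    """One sequencing library: sample metadata plus its aligned reads.

    ``depth`` is the retained uniquely-mapped read count used for
    per-million scaling; ``mirna_count`` is the miRNA normalisation
    factor (small-RNA libraries only, set by quantification).
    """

    sample_id: str
    condition: str
    replicate: int
    assay: str  # "smallRNA" | "chip_IP" | "chip_input"
    reads: pd.DataFrame
    depth: int
    mirna_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.assay not in ("smallRNA", "chip_IP", "chip_input"):
            raise ValueError(f"unknown assay {self.assay!r}")
        self.reads = reads_to_frame(self.reads)
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.assay != "smallRNA" and self.mirna_count is not None:
            raise ValueError("mirna_count is undefined for ChIP assays")

    def n_reads(self) -> int:
        return len(self.reads)
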