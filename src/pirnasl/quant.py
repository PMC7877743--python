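"""Small-RNA filtering, per-bin counting and the normalisation chain.

The chain, applied per condition: scale each replicate's raw per-bin
counts to reads-per-million of that replicate's retained unique-mapper
depth, sum the scaled values across replicates, divide by the bin's
mappability fraction.  Bins with zero mappability, and bins whose pooled
raw count is zero, are excluded and remembered with a reason so that
downstream comparisons can apply the zero rule on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .model import Cluster, GenomeAnnotation, GenomicBin, Library, bin_id, reads_to_frame

__all__ = [
    "FilterStats",
    "BinSignal",
    "filter_pirna_reads",
    "count_mirna_factor",
    "count_bins",
    "pool_and_normalize",
    "cluster_abundance",
    "transposon_rpkm",
]

STRAND_SELECTIONS = ("sense", "antisense", "both")


@dataclass
class FilterStats:
    n_input: int = 0
    removed_length: int = 0
    removed_multimapper: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.removed_length - self.removed_multimapper


@dataclass
class BinSignal:
    """Pooled, depth- and mappability-normalised per-bin abundance.

    ``values`` holds one finite non-negative number per retained bin id;
    ``excluded`` maps every dropped bin id to the reason
    (``zero_mappability`` or ``zero_count``).  The two key sets are
    disjoint and together cover the input bin set.
    """

    condition: str
    strand_selection: str
    values: pd.Series
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.values.index) & set(self.excluded)
        if overlap:
            raise ValueError(f"bins both valued and excluded: {sorted(overlap)[:3]}")
        arr = self.values.to_numpy(dtype=float)
        if len(arr) and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ValueError("signal values must be finite and non-negative")

    def universe(self) -> set[str]:
        return set(self.values.index) | set(self.excluded)

    def dense_values(self, fill: float = 0.0) -> pd.Series:
        """Values over the full universe with zero-count exclusions filled.

        Bins excluded for zero mappability stay absent — no signal can be
        reconstructed for them — while zero-count bins reappear at
        ``fill``.  Used by the ChIP track arithmetic, where pseudocounts
        (not exclusion) handle empty bins.
        """
        zero_count = [b for b, r in self.excluded.items() if r == "zero_count"]
        filled = pd.concat([self.values, pd.Series(fill, index=zero_count, dtype=float)])
        return filled.sort_index()


def filter_pirna_reads(lib: Library, config: AnalysisConfig) -> tuple[Library, FilterStats]:
    """Keep unique-mapper reads inside the piRNA length window.

    Returns the filtered library plus per-filter removal tallies.
    """
    if lib.assay != "smallRNA":
        raise ValueError("piRNA filtering applies to small-RNA libraries")
    reads = lib.reads
    length_ok = (reads["length"] >= config.pirna_min_len) & (
        reads["length"] <= config.pirna_max_len
    )
    unique = reads["n_hits"] == 1
    stats = FilterStats(
        n_input=len(reads),
        removed_length=int((~length_ok).sum()),
        removed_multimapper=int((length_ok & ~unique).sum()),
    )
    kept = reads.loc[length_ok & unique].reset_index(drop=True)
    out = Library(
        sample_id=lib.sample_id,
        condition=lib.condition,
        replicate=lib.replicate,
        assay=lib.assay,
        reads=kept,
        depth=lib.depth,
        mirna_count=lib.mirna_count,
    )
    return out, stats


def _five_prime_in_intervals(
    reads: pd.DataFrame, intervals: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Boolean mask: read 5' end falls in any of the (possibly overlapping) intervals."""
    mask = np.zeros(len(reads), dtype=bool)
    chroms = reads["chrom"].to_numpy()
    pos = reads["five_prime"].to_numpy()
    for chrom, start, end in intervals:
        mask |= (chroms == chrom) & (pos >= start) & (pos < end)
    return mask


def count_mirna_factor(lib: Library, annotation: GenomeAnnotation) -> int:
    """miRNA normalisation factor: unique-mapper reads with 5' end in a miRNA locus.

    The factor is stored on the library; a zero factor is an error
    because the library could not be miRNA-normalised.
    """
    if not annotation.mirna_loci:
        raise ValueError("annotation has no miRNA loci")
    reads = lib.reads
    unique = reads["n_hits"].to_numpy() == 1
    mask = _five_prime_in_intervals(reads, annotation.mirna_loci) & unique
    factor = int(mask.sum())
    if factor == 0:
        raise ValueError(f"library {lib.sample_id} has no miRNA reads; cannot normalise")
    lib.mirna_count = factor
    return factor


def _prepare_bins(bins: Sequence[GenomicBin]):
    """Group bins per chromosome, sorted, rejecting overlaps."""
    frame = pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "feature_strand": [b.feature_strand for b in bins],
            "order": np.arange(len(bins)),
        }
    )
    per_chrom = {}
    for chrom, sub in frame.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping bins on {chrom}: read assignment would be ambiguous")
        per_chrom[chrom] = (
            starts,
            ends,
            sub["feature_strand"].to_numpy(),
            sub["order"].to_numpy(),
        )
    return per_chrom


def count_bins(
    lib: Library, bins: Sequence[GenomicBin], strand_selection: str = "both"
) -> np.ndarray:
    """Raw 5'-end read counts per bin, in the order the bins were given.

    A read contributes to the bin containing its 5'-end coordinate;
    ``sense``/``antisense`` select reads on / opposite to the bin's
    feature strand.  Reads outside all bins contribute nothing.
    """
    if strand_selection not in STRAND_SELECTIONS:
        raise ValueError(f"strand_selection must be one of {STRAND_SELECTIONS}")
    per_chrom = _prepare_bins(bins)
    counts = np.zeros(len(bins), dtype=np.int64)
    reads = lib.reads
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in per_chrom:
            continue
        starts, ends, fstrand, order = per_chrom[chrom]
        pos = sub["five_prime"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        if strand_selection != "both":
            sense = sub["strand"].to_numpy() == fstrand[np.clip(idx, 0, None)]
            inside &= sense if strand_selection == "sense" else ~sense
        hit = idx[inside]
        if len(hit):
            counts += np.bincount(order[hit], minlength=len(bins))
    return counts


def pool_and_normalize(
    replicate_counts: Sequence[np.ndarray],
    depths: Sequence[int],
    bins: Sequence[GenomicBin],
    condition: str = "",
    strand_selection: str = "both",
    exclude_zero: bool = True,
) -> BinSignal:
    """Depth-normalise, pool replicates, divide by mappability.

    Each replicate's counts are scaled to reads-per-million of its depth,
    the scaled values are summed, and the sum is divided by the bin's
    mappability.  Zero-mappability bins are always excluded; with
    ``exclude_zero`` (default) bins whose pooled raw count is zero are
    excluded too, implementing the zero-read rule.
    """
    if not replicate_counts:
        raise ValueError("at least one replicate is required")
    if len(replicate_counts) != len(depths):
        raise ValueError("counts and depths differ in length")
    if any(d <= 0 for d in depths):
        raise ValueError("library depth must be positive")
    n = len(bins)
    pooled = np.zeros(n, dtype=float)
    raw_total = np.zeros(n, dtype=np.int64)
    for counts, depth in zip(replicate_counts, depths):
        counts = np.asarray(counts)
        if counts.shape != (n,):
            raise ValueError("replicate count vector does not match bin set")
        pooled += counts * (1e6 / depth)
        raw_total += counts.astype(np.int64)
    mapp = np.array([b.mappability for b in bins])
    ids = [bin_id(b) for b in bins]

    excluded: dict[str, str] = {}
    keep = np.ones(n, dtype=bool)
    zero_map = mapp == 0
    keep &= ~zero_map
    for i in np.flatnonzero(zero_map):
        excluded[ids[i]] = "zero_mappability"
    if exclude_zero:
        zero_cnt = (raw_total == 0) & ~zero_map
        keep &= ~zero_cnt
        for i in np.flatnonzero(zero_cnt):
            excluded[ids[i]] = "zero_count"

    values = pd.Series(
        pooled[keep] / mapp[keep], index=[ids[i] for i in np.flatnonzero(keep)], dtype=float
    )
    return BinSignal(
        condition=condition,
        strand_selection=strand_selection,
        values=values,
        excluded=excluded,
    )


def cluster_abundance(
    lib: Library,
    clusters: Sequence[Cluster],
    strand_selection: str = "both",
) -> pd.Series:
    """Per-cluster piRNA abundance normalised to the library's miRNA factor.

    Abundance = (unique piRNA reads with 5' end in the cluster, per the
    strand selection) / miRNA factor.  Sense for a uni-strand cluster is
    its annotated strand; dual-strand clusters use genomic '+' as sense.
    """
    if lib.mirna_count is None:
        raise ValueError("miRNA factor not set; run count_mirna_factor first")
    if lib.mirna_count <= 0:
        raise ValueError("miRNA factor must be positive")
    cluster_bins = [
        GenomicBin(
            chrom=c.chrom,
            start=c.start,
            end=c.end,
            mappability=1.0,
            feature_strand=c.strand,
        )
        for c in clusters
    ]
    counts = count_bins(lib, cluster_bins, strand_selection)
    return pd.Series(
        counts / lib.mirna_count,
        index=[c.cluster_id for c in clusters],
        dtype=float,
    )


def transposon_rpkm(
    counts: Mapping[str, int],
    family_lengths: Mapping[str, int],
    depth: int,
) -> pd.Series:
    """RPKM per transposon family from unique-mapper counts.

    RPKM = count / (length_kb * depth_millions).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    out = {}
    for family, count in counts.items():
        length = family_lengths[family]
        if length <= 0:
            raise ValueError(f"family {family} has non-positive length")
        out[family] = count / ((length / 1e3) * (depth / 1e6))
    return pd.Series(out, dtype=float)
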