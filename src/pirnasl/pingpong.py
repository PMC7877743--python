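"""Ping-pong signature: 5'-overlap profiles, z-scores, length histograms.

The ping-pong amplification cycle produces complementary piRNA pairs
whose 5' ends overlap by exactly 10 nt.  For a plus-strand read with 5'
end ``p`` and a minus-strand read with 5' end ``q`` on the same
chromosome, the pair overlaps by ``k = q - p + 1`` bases; the profile
tallies all read pairs per overlap length ``k`` in ``[1, overlap_max]``
and the z-score compares the count at the 10-nt focus against the mean
and population standard deviation of the remaining overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .model import reads_to_frame

__all__ = [
    "PingPongProfile",
    "LengthHistogram",
    "overlap_profile",
    "pingpong_zscore",
    "length_histogram",
    "antisense_abundance_by_family",
]


@dataclass
class PingPongProfile:
    """Complementary pair counts per 5'-overlap length, plus the focus z-score.

    ``overlap_counts`` is indexed by overlap length 1..overlap_max; each
    pair counts once and the whole profile is scaled by 1/miRNA factor
    when a factor is supplied.  ``zscore`` is None until computed, and
    stays None when the background is degenerate (sd = 0).
    """

    overlap_counts: pd.Series
    focus: int
    zscore: Optional[float] = None
    background_mean: Optional[float] = None
    background_sd: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"overlap": self.overlap_counts.index, "pairs": self.overlap_counts.to_numpy()}
        )


@dataclass
class LengthHistogram:
    """Read counts per length and strand, scaled by the miRNA factor."""

    counts: pd.DataFrame  # columns: length, strand, value
    mirna_factor: float


def overlap_profile(
    reads, config: AnalysisConfig, mirna_factor: Optional[float] = None
) -> PingPongProfile:
    """Tally complementary read pairs by 5'-overlap length.

    Every (plus-read, minus-read) pair on the same chromosome with
    ``1 <= q - p + 1 <= overlap_max`` contributes one pair count; reads
    sharing a 5' position multiply (all pairs are counted).  Counts are
    divided by ``mirna_factor`` when given.
    """
    frame = reads_to_frame(reads)
    kmax = config.overlap_max
    counts = np.zeros(kmax, dtype=float)
    for _, sub in frame.groupby("chrom", sort=False):
        strands = sub["strand"].to_numpy()
        pos = sub["five_prime"].to_numpy()
        plus_pos, plus_mult = np.unique(pos[strands == "+"], return_counts=True)
        minus_pos, minus_mult = np.unique(pos[strands == "-"], return_counts=True)
        if not len(plus_pos) or not len(minus_pos):
            continue
        for k in range(1, kmax + 1):
            target = plus_pos + k - 1
            j = np.searchsorted(minus_pos, target)
            j = np.clip(j, 0, len(minus_pos) - 1)
            match = minus_pos[j] == target
            counts[k - 1] += float(np.dot(plus_mult[match], minus_mult[j[match]]))
    if mirna_factor is not None:
        if mirna_factor <= 0:
            raise ValueError("miRNA factor must be positive")
        counts = counts / mirna_factor
    series = pd.Series(counts, index=np.arange(1, kmax + 1), dtype=float)
    return PingPongProfile(overlap_counts=series, focus=config.pingpong_focus)


def pingpong_zscore(profile: PingPongProfile, config: AnalysisConfig) -> PingPongProfile:
    """z-score of the focus overlap against all other overlap lengths.

    Background = counts at every overlap except the focus;
    ``z = (counts[focus] - mean(background)) / population_sd(background)``.
    A zero-variance background leaves ``zscore`` as None (undefined, not
    an error).
    """
    counts = profile.overlap_counts
    focus = config.pingpong_focus
    if focus not in counts.index:
        raise ValueError(f"profile lacks overlap {focus}")
    background = counts.drop(index=focus).to_numpy()
    mean = float(background.mean())
    sd = float(background.std(ddof=0))
    profile.focus = focus
    profile.background_mean = mean
    profile.background_sd = sd
    profile.zscore = None if sd == 0 else float((counts.loc[focus] - mean) / sd)
    return profile


def length_histogram(
    reads, mirna_factor: float, min_len: int = 18, max_len: int = 30
) -> LengthHistogram:
    """Per-length, per-strand read counts divided by the miRNA factor."""
    if mirna_factor <= 0:
        raise ValueError("miRNA factor must be positive")
    frame = reads_to_frame(reads)
    frame = frame[(frame["length"] >= min_len) & (frame["length"] <= max_len)]
    rows = []
    for strand in ("+", "-"):
        sub = frame[frame["strand"] == strand]
        tally = sub.groupby("length").size()
        for length in range(min_len, max_len + 1):
            rows.append(
                {
                    "length": length,
                    "strand": strand,
                    "value": float(tally.get(length, 0)) / mirna_factor,
                }
            )
    return LengthHistogram(counts=pd.DataFrame(rows), mirna_factor=mirna_factor)


def antisense_abundance_by_family(
    reads,
    family_intervals: Sequence[tuple[str, str, int, int, str]],
    mirna_factor: float,
) -> pd.Series:
    """Antisense piRNA abundance per transposon family, miRNA-normalised.

    ``family_intervals`` rows are ``(family_id, chrom, start, end,
    sense_strand)``; a family may own several insertion intervals.  A
    read counts as antisense when its 5' end lies in one of the family's
    intervals on the strand opposite to that interval's sense
    orientation.  Families lacking an orientation raise.
    """
    if mirna_factor <= 0:
        raise ValueError("miRNA factor must be positive")
    frame = reads_to_frame(reads)
    chroms = frame["chrom"].to_numpy()
    pos = frame["five_prime"].to_numpy()
    strands = frame["strand"].to_numpy()
    totals: dict[str, float] = {}
    for family, chrom, start, end, sense in family_intervals:
        if sense not in ("+", "-"):
            raise ValueError(f"family {family} has no annotated orientation")
        anti = "-" if sense == "+" else "+"
        mask = (chroms == chrom) & (pos >= start) & (pos < end) & (strands == anti)
        totals[family] = totals.get(family, 0.0) + float(mask.sum())
    return pd.Series({f: v / mirna_factor for f, v in totals.items()}, dtype=float)
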