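"""Binned ChIP occupancy and condition fold-change track arithmetic.

Occupancy follows the same normalisation chain as the small-RNA signal
(reads-per-million per replicate, pooled, divided by mappability; no
miRNA step).  The condition-comparison track combines the IP and input
knockdown/control ratios:

    A = log2((IP_kd + 0.1) / (IP_ctrl + 0.1))
    B = log2((IN_kd + 0.1) / (IN_ctrl + 0.1))
    track = A - B

The second-stage subtraction pseudocount (0.01, added to both operands)
cancels algebraically; it is kept in the configuration for provenance
and documented as inert.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .model import GenomicBin, Library
from .quant import BinSignal, count_bins, pool_and_normalize

__all__ = [
    "OccupancySignal",
    "chip_bin_signal",
    "log2_fc_track",
    "replicate_correlation",
]

# Occupancy signals share the structure and exclusion bookkeeping of
# the small-RNA bin signal.
OccupancySignal = BinSignal


def chip_bin_signal(
    libraries: Sequence[Library],
    bins: Sequence[GenomicBin],
    config: AnalysisConfig,
    strand_selection: str = "both",
) -> OccupancySignal:
    """Pooled, depth- and mappability-normalised ChIP occupancy per bin.

    All replicate libraries must share condition and assay; only
    unique-mapper reads are counted.
    """
    if not libraries:
        raise ValueError("at least one library is required")
    assays = {lib.assay for lib in libraries}
    conditions = {lib.condition for lib in libraries}
    if len(assays) != 1 or len(conditions) != 1:
        raise ValueError("replicates must share assay and condition")
    counts = []
    depths = []
    for lib in libraries:
        unique = lib.reads[lib.reads["n_hits"] == 1]
        sub = Library(
            sample_id=lib.sample_id,
            condition=lib.condition,
            replicate=lib.replicate,
            assay=lib.assay,
            reads=unique,
            depth=lib.depth,
        )
        counts.append(count_bins(sub, bins, strand_selection))
        depths.append(lib.depth)
    return pool_and_normalize(
        counts,
        depths,
        bins,
        condition=conditions.pop(),
        strand_selection=strand_selection,
    )


def log2_fc_track(
    ip_kd: OccupancySignal,
    ip_ctrl: OccupancySignal,
    in_kd: OccupancySignal,
    in_ctrl: OccupancySignal,
    config: AnalysisConfig,
) -> pd.Series:
    """Input-corrected log2 knockdown/control occupancy change per bin.

    The four signals must cover the same bin universe.  Bins excluded
    for zero counts re-enter at zero signal — the ratio pseudocount, not
    exclusion, handles emptiness here — while zero-mappability bins stay
    out of the track.
    """
    signals = [ip_kd, ip_ctrl, in_kd, in_ctrl]
    universes = [s.universe() for s in signals]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("signals were built over different bin universes")
    dense = [s.dense_values() for s in signals]
    index = dense[0].index
    if any(not d.index.equals(index) for d in dense[1:]):
        # mappability exclusions must agree since mappability is shared
        raise ValueError("signals disagree on zero-mappability exclusions")
    pc = config.pseudocount_ratio
    a = np.log2((dense[0].to_numpy() + pc) / (dense[1].to_numpy() + pc))
    b = np.log2((dense[2].to_numpy() + pc) / (dense[3].to_numpy() + pc))
    # subtract-stage pseudocount: (a + c) - (b + c) == a - b, kept in
    # config (pseudocount_subtract) for provenance only
    return pd.Series(a - b, index=index, dtype=float)


def replicate_correlation(
    count_matrix: pd.DataFrame, skip_zeros: bool = True
) -> pd.DataFrame:
    """Pairwise Spearman correlation of samples over fixed-width bins.

    ``count_matrix`` is bins x samples.  Bins that are zero in every
    sample are skipped (the skip-zeros convention for sparse genomic
    grids).
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("at least two samples are required")
    mat = count_matrix.to_numpy(dtype=float)
    if skip_zeros:
        mat = mat[(mat != 0).any(axis=1)]
    n = mat.shape[1]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rho = stats.spearmanr(mat[:, i], mat[:, j]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=count_matrix.columns, columns=count_matrix.columns)
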