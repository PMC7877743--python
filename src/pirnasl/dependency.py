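"""Fold changes, source-locus dependency classification, group statistics.

A source-locus bin is called *dependent* when its log2 piRNA fold change
is strictly below -threshold in **both** mutants, *up* when strictly
above +threshold in both, and *independent* otherwise; bins excluded by
the zero-read rule (on either side of a comparison) or the zero-
mappability guard are *excluded*.  Group comparisons use the two-sided
Wilcoxon rank-sum test with continuity correction, reporting p-values
below 2.2e-16 as the floor string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .quant import BinSignal

__all__ = [
    "GroupComparison",
    "bin_fold_change",
    "classify_sources",
    "class_totals",
    "compare_groups",
    "boxplot_summary",
]

CALLS = ("dependent", "independent", "up", "excluded")


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_two_sided: float
    report_string: str
    method: str


def bin_fold_change(
    signal_mut: BinSignal, signal_ref: BinSignal
) -> tuple[pd.Series, dict[str, str]]:
    """Per-bin log2 fold change mutant/reference over the shared bin set.

    Both signals must be built over the same bin universe.  Bins excluded
    on either side are returned in the exclusion map with a reason rather
    than producing infinite fold changes.
    """
    if signal_mut.universe() != signal_ref.universe():
        raise ValueError("signals were built over different bin universes")
    common = signal_mut.values.index.intersection(signal_ref.values.index)
    fc = pd.Series(
        np.log2(signal_mut.values.loc[common].to_numpy() / signal_ref.values.loc[common].to_numpy()),
        index=common,
        dtype=float,
    )
    excluded: dict[str, str] = {}
    for bid, reason in signal_ref.excluded.items():
        excluded[bid] = f"reference:{reason}"
    for bid, reason in signal_mut.excluded.items():
        excluded.setdefault(bid, f"mutant:{reason}")
    return fc, excluded


def classify_sources(
    fc_map_1: pd.Series,
    fc_map_2: pd.Series,
    threshold: float,
    excluded_1: Optional[Mapping[str, str]] = None,
    excluded_2: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Classify each bin from its two mutant fold changes.

    Strict inequalities at the threshold: dependent iff both fold changes
    are < -threshold, up iff both are > +threshold, independent
    otherwise.  Bins excluded in either fold-change computation are
    called ``excluded`` with the recorded reason.  Returns a DataFrame
    indexed by bin id with columns ``fc1``, ``fc2``, ``call``, ``reason``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    excluded_1 = dict(excluded_1 or {})
    excluded_2 = dict(excluded_2 or {})
    universe_1 = set(fc_map_1.index) | set(excluded_1)
    universe_2 = set(fc_map_2.index) | set(excluded_2)
    if universe_1 != universe_2:
        raise ValueError("fold-change maps cover different bin universes")

    common = fc_map_1.index.intersection(fc_map_2.index)
    fc1 = fc_map_1.loc[common].to_numpy()
    fc2 = fc_map_2.loc[common].to_numpy()
    call = np.full(len(common), "independent", dtype=object)
    call[(fc1 < -threshold) & (fc2 < -threshold)] = "dependent"
    call[(fc1 > threshold) & (fc2 > threshold)] = "up"
    frame = pd.DataFrame(
        {"fc1": fc1, "fc2": fc2, "call": call, "reason": ""}, index=common
    )

    rows = []
    for bid in sorted(universe_1 - set(common)):
        reason = excluded_1.get(bid) or excluded_2.get(bid) or "excluded"
        rows.append({"fc1": np.nan, "fc2": np.nan, "call": "excluded", "reason": reason})
    if rows:
        frame = pd.concat([frame, pd.DataFrame(rows, index=sorted(universe_1 - set(common)))])
    return frame.sort_index()


def class_totals(calls: pd.DataFrame) -> dict[str, int]:
    totals = {c: 0 for c in CALLS}
    totals.update(calls["call"].value_counts().to_dict())
    return totals


def _format_p(p: float) -> str:
    return f"P = {p:.4g}"


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    config: AnalysisConfig,
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test between two bin-value groups.

    Small tie-free groups (both n <= 8) are tested by exact enumeration;
    otherwise the normal approximation with continuity correction is
    used.  p-values below the reporting floor are rendered as the floor
    string.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("group values must be finite")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= 8 and len(b) <= 8 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal_cc"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(min(res.pvalue, 1.0))
    report = "P < 2.2e-16" if p < config.p_floor else _format_p(p)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        statistic=float(res.statistic),
        p_two_sided=p,
        report_string=report,
        method=method,
    )


def boxplot_summary(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Five-number summary per group: median, quartiles, 5th/95th percentiles.

    Percentiles use linear interpolation between order statistics.
    Values beyond the 5th/95th whiskers are counted as outliers, not
    returned.
    """
    rows = []
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if len(arr) == 0:
            raise ValueError(f"group {name!r} is empty")
        p5, q1, med, q3, p95 = np.percentile(arr, [5, 25, 50, 75, 95])
        rows.append(
            {
                "group": name,
                "n": len(arr),
                "p5": p5,
                "q1": q1,
                "median": med,
                "q3": q3,
                "p95": p95,
                "n_outliers": int(((arr < p5) | (arr > p95)).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("group")
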