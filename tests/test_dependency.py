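"""Fold changes, dependency calls, Wilcoxon statistics and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pirnasl.config import AnalysisConfig
from pirnasl.dependency import (
    bin_fold_change,
    boxplot_summary,
    class_totals,
    classify_sources,
    compare_groups,
)
from pirnasl.model import GenomicBin
from pirnasl.quant import BinSignal, pool_and_normalize


def make_signal(values: dict, excluded: dict | None = None, condition="X"):
    return BinSignal(
        condition=condition,
        strand_selection="both",
        values=pd.Series(values, dtype=float),
        excluded=dict(excluded or {}),
    )


def exact_ranksum_p(a, b):
    """Enumerate all rank assignments: exact two-sided rank-sum p-value."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n_a].sum()
    mean = n_a * (len(pooled) + 1) / 2
    stats = [
        ranks[list(combo)].sum()
        for combo in itertools.combinations(range(len(pooled)), n_a)
    ]
    stats = np.asarray(stats)
    p = (np.abs(stats - mean) >= abs(observed - mean) - 1e-12).mean()
    return min(1.0, p)


class TestFoldChange:
    def test_equal_signals_give_zero(self):
        a = make_signal({"b1": 5.0, "b2": 2.0})
        fc, excluded = bin_fold_change(a, make_signal({"b1": 5.0, "b2": 2.0}))
        assert np.allclose(fc.to_numpy(), 0.0)
        assert excluded == {}

    def test_quarter_signal_gives_minus_two(self):
        fc, _ = bin_fold_change(make_signal({"b1": 2.0}), make_signal({"b1": 8.0}))
        assert fc["b1"] == pytest.approx(-2.0)

    def test_zero_reference_bin_excluded_not_infinite(self):
        mut = make_signal({"b1": 4.0, "b2": 3.0})
        ref = make_signal({"b1": 4.0}, {"b2": "zero_count"})
        fc, excluded = bin_fold_change(mut, ref)
        assert "b2" not in fc.index
        assert excluded["b2"] == "reference:zero_count"
        assert np.isfinite(fc.to_numpy()).all()

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            bin_fold_change(make_signal({"b1": 1.0}), make_signal({"b2": 1.0}))


class TestClassification:
    def _classify(self, pairs, threshold=1.5):
        fc1 = pd.Series({k: v[0] for k, v in pairs.items()})
        fc2 = pd.Series({k: v[1] for k, v in pairs.items()})
        return classify_sources(fc1, fc2, threshold)

    @pytest.mark.parametrize(
        "fc1,fc2,expected",
        [
            (-2.0, -2.0, "dependent"),
            (-2.0, -1.0, "independent"),  # fails "in both"
            (-1.5, -1.5, "independent"),  # strict inequality at the threshold
            (2.0, 2.0, "up"),
            (1.5, 1.5, "independent"),
            (0.0, 0.0, "independent"),
            (-2.0, 2.0, "independent"),
        ],
    )
    def test_threshold_rule(self, fc1, fc2, expected):
        calls = self._classify({"b": (fc1, fc2)})
        assert calls.loc["b", "call"] == expected

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            self._classify({"b": (0.0, 0.0)}, threshold=0.0)

    def test_excluded_bins_reported_with_reason(self):
        fc1 = pd.Series({"b1": -2.0})
        fc2 = pd.Series({"b1": -2.0})
        calls = classify_sources(
            fc1, fc2, 1.5,
            excluded_1={"b2": "reference:zero_count"},
            excluded_2={"b2": "reference:zero_count"},
        )
        assert calls.loc["b2", "call"] == "excluded"
        assert calls.loc["b2", "reason"] == "reference:zero_count"

    def test_partition_over_random_fold_changes(self):
        rng = np.random.default_rng(13)
        pairs = {f"b{i}": (rng.normal(0, 2), rng.normal(0, 2)) for i in range(500)}
        calls = self._classify(pairs)
        assert calls["call"].isin(["dependent", "independent", "up"]).all()
        totals = class_totals(calls)
        assert sum(totals.values()) == 500

    def test_antisymmetry_swapping_mutant_and_reference(self):
        rng = np.random.default_rng(19)
        pairs = {f"b{i}": (rng.normal(0, 2), rng.normal(0, 2)) for i in range(300)}
        fwd = class_totals(self._classify(pairs))
        rev = class_totals(self._classify({k: (-v[0], -v[1]) for k, v in pairs.items()}))
        assert fwd["dependent"] == rev["up"]
        assert fwd["up"] == rev["dependent"]
        assert fwd["independent"] == rev["independent"]


class TestCompareGroups:
    def test_exact_enumeration_small_groups(self, config):
        cmp = compare_groups([1, 2, 3], [4, 5, 6], config)
        assert cmp.method == "exact"
        assert cmp.p_two_sided == pytest.approx(0.1)
        assert cmp.p_two_sided == pytest.approx(exact_ranksum_p([1, 2, 3], [4, 5, 6]))

    def test_identical_groups_give_p_one(self, config):
        cmp = compare_groups([1, 2, 3], [1, 2, 3], config)
        assert cmp.p_two_sided == pytest.approx(1.0)

    def test_tiny_p_reported_as_floor_string(self, config):
        a = np.arange(1000, dtype=float)
        b = a + 5000
        cmp = compare_groups(a, b, config)
        assert cmp.p_two_sided < config.p_floor
        assert cmp.report_string == "P < 2.2e-16"

    def test_moderate_p_reported_numerically(self, config):
        cmp = compare_groups([1, 2, 3], [4, 5, 6], config)
        assert cmp.report_string.startswith("P = ")

    def test_empty_group_rejected(self, config):
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups([], [1.0], config)

    def test_approximation_close_to_exact_enumeration(self, config):
        """Continuity-corrected normal p within 0.02 of exact p on small groups."""
        rng = np.random.default_rng(29)
        worst = 0.0
        for _ in range(100):
            # groups of >= 5: the corrected normal approximation is within
            # 0.02 of exact enumeration uniformly over all statistics there
            n_a, n_b = rng.integers(5, 9, size=2)
            pool = rng.choice(10_000, size=n_a + n_b, replace=False).astype(float)
            a, b = pool[:n_a], pool[n_a:]
            exact = exact_ranksum_p(a, b)
            from scipy.stats import mannwhitneyu

            approx = mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            worst = max(worst, abs(approx - exact))
        assert worst < 0.02


class TestBoxplotSummary:
    def test_percentile_convention_on_1_to_100(self):
        summary = boxplot_summary({"g": np.arange(1, 101, dtype=float)})
        row = summary.loc["g"]
        assert row["median"] == pytest.approx(50.5)
        assert row["p5"] == pytest.approx(5.95)  # linear interpolation
        assert row["p95"] == pytest.approx(95.05)

    def test_single_value_collapses_all_five_numbers(self):
        row = boxplot_summary({"g": [7.0]}).loc["g"]
        assert (row[["p5", "q1", "median", "q3", "p95"]] == 7.0).all()

    def test_constant_group_has_zero_iqr(self):
        row = boxplot_summary({"g": [3.0] * 20}).loc["g"]
        assert row["q3"] - row["q1"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            boxplot_summary({"g": []})
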