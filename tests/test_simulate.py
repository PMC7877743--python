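"""Ground-truth generator: determinism, label consistency, count model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pirnasl.config import AnalysisConfig
from pirnasl.model import bin_id
from pirnasl.simulate import (
    make_truth,
    simulate_chip_library,
    simulate_smallrna_library,
)


class TestMakeTruth:
    def test_class_counts_by_construction(self, config):
        truth = make_truth(config, 100, 400, 20, 2.5, seed=1)
        labels = pd.Series(truth.bin_labels)
        assert (labels == "dependent").sum() == 100
        assert (labels == "independent").sum() == 400
        assert (labels == "up").sum() == 20

    def test_same_seed_gives_identical_truth(self, config):
        a = make_truth(config, 50, 100, 10, 2.5, seed=9)
        b = make_truth(config, 50, 100, 10, 2.5, seed=9)
        assert a.bin_labels == b.bin_labels
        assert a.bin_effects == b.bin_effects
        assert [x.mappability for x in a.annotation.bins] == [
            x.mappability for x in b.annotation.bins
        ]

    def test_effect_below_threshold_rejected(self, config):
        with pytest.raises(ValueError, match="threshold"):
            make_truth(config, 10, 10, 10, effect_size_log2=1.0, seed=1)

    def test_genome_too_small_rejected(self, config):
        with pytest.raises(ValueError, match="too small"):
            make_truth(config, 10, 10, 10, 2.5, seed=1, chrom_length=10_000)

    def test_mappability_mixture_within_stated_ranges(self, config):
        truth = make_truth(config, 200, 700, 100, 2.5, seed=2)
        mapp = np.array([b.mappability for b in truth.annotation.bins])
        assert ((mapp > 0) & (mapp <= 1)).all()
        low = mapp <= 0.3
        assert 0.04 < low.mean() < 0.18  # ~10% low-mappability tail
        assert (mapp[~low] >= 0.6).all()

    def test_labels_consistent_with_effects(self, small_truth, config):
        thr = config.dependency_threshold
        for bid, label in small_truth.bin_labels.items():
            fc1, fc2 = small_truth.bin_effects[bid]
            if label == "dependent":
                assert fc1 < -thr and fc2 < -thr
            elif label == "up":
                assert fc1 > thr and fc2 > thr
            else:
                assert fc1 == fc2 == 0.0


class TestSmallRnaLibrary:
    def test_total_count_within_poisson_envelope(self, config):
        # no pairing: the piRNA read total is exactly Poisson with known mean
        truth = make_truth(config, 0, 100, 0, 2.5, seed=3, base_rate=100.0,
                           pingpong_fraction=0.0, mirna_fraction=0.0)
        lib = simulate_smallrna_library(truth, "WT", 1, seed=3)
        mean = truth.base_rate * sum(b.mappability for b in truth.annotation.bins)
        lo, hi = stats.poisson.ppf([0.0005, 0.9995], mean)
        assert lo <= lib.n_reads() <= hi

    def test_dependent_bin_mean_scales_by_effect(self, config):
        # true log2 FC -2 at base rate 100 -> mutant mean ~ 25 per unit mappability
        truth = make_truth(config, 300, 0, 0, 2.0, seed=4, base_rate=100.0,
                           pingpong_fraction=0.0, mirna_fraction=0.0)
        lib = simulate_smallrna_library(truth, "mut1", 1, seed=4)
        total_mapp = sum(b.mappability for b in truth.annotation.bins)
        observed_rate = lib.n_reads() / total_mapp
        assert observed_rate == pytest.approx(25.0, rel=0.1)

    def test_full_pairing_gives_partner_for_every_read(self, config):
        truth = make_truth(config, 0, 40, 0, 2.5, seed=5, base_rate=50.0,
                           pingpong_fraction=1.0, mirna_fraction=0.0,
                           dual_strand_fraction=1.0)
        lib = simulate_smallrna_library(truth, "WT", 1, seed=5)
        reads = lib.reads[lib.reads["chrom"] == "chr_sim"]
        plus = np.sort(reads.loc[reads["strand"] == "+", "five_prime"].to_numpy())
        minus = np.sort(reads.loc[reads["strand"] == "-", "five_prime"].to_numpy())
        # every plus read pairs a minus read at exactly 10-nt 5' overlap
        assert len(plus) == len(minus)
        assert np.array_equal(plus + 9, minus)

    def test_read_lengths_in_pirna_window_with_mirna_component(self, config, small_truth):
        lib = simulate_smallrna_library(small_truth, "WT", 1, seed=11)
        sim = lib.reads[lib.reads["chrom"] == "chr_sim"]
        mir = lib.reads[lib.reads["chrom"] == "chr_mirna"]
        assert sim["length"].between(23, 29).all()
        assert (mir["length"] == 22).all()
        assert lib.mirna_count == len(mir)
        assert len(mir) / len(lib.reads) == pytest.approx(0.1, abs=0.03)

    def test_same_seed_identical_library(self, small_truth):
        a = simulate_smallrna_library(small_truth, "mut1", 2, seed=8)
        b = simulate_smallrna_library(small_truth, "mut1", 2, seed=8)
        assert a.reads.equals(b.reads)

    def test_unknown_condition_rejected(self, small_truth):
        with pytest.raises(ValueError, match="condition"):
            simulate_smallrna_library(small_truth, "mut3", 1, seed=1)

    def test_depth_grows_linearly_with_base_rate(self, config):
        depths = []
        rates = [50.0, 100.0, 200.0]
        for rate in rates:
            truth = make_truth(config, 0, 200, 0, 2.5, seed=6, base_rate=rate,
                               pingpong_fraction=0.0, mirna_fraction=0.0)
            lib = simulate_smallrna_library(truth, "WT", 1, seed=6)
            depths.append(lib.depth)
        slope1 = depths[1] / depths[0]
        slope2 = depths[2] / depths[1]
        assert slope1 == pytest.approx(2.0, rel=0.05)
        assert slope2 == pytest.approx(2.0, rel=0.05)

    def test_dual_strand_bins_emit_balanced_strands(self, config):
        truth = make_truth(config, 0, 20, 0, 2.5, seed=7, base_rate=1500.0,
                           pingpong_fraction=0.0, mirna_fraction=0.0,
                           dual_strand_fraction=1.0)
        lib = simulate_smallrna_library(truth, "WT", 1, seed=7)
        n = lib.n_reads()
        frac_plus = (lib.reads["strand"] == "+").mean()
        se = 0.5 / np.sqrt(n)
        assert abs(frac_plus - 0.5) <= 3 * se


class TestChipLibrary:
    def test_flat_enrichment_matches_input_in_expectation(self, config):
        truth = make_truth(config, 0, 150, 0, 2.5, seed=9, base_rate=100.0,
                           control_enrichment=1.0)
        ip = simulate_chip_library(truth, "control_KD", "chip_IP", 1, seed=9)
        inp = simulate_chip_library(truth, "control_KD", "chip_input", 1, seed=9)
        assert ip.depth == pytest.approx(inp.depth, rel=0.05)

    def test_knockdown_collapse_gives_expected_fold_change(self, config):
        truth = make_truth(config, 200, 0, 0, 2.5, seed=10, base_rate=100.0,
                           control_enrichment=8.0, kd_enrichment_dependent=1.0)
        ctrl = simulate_chip_library(truth, "control_KD", "chip_IP", 1, seed=10)
        kd = simulate_chip_library(truth, "enok_KD", "chip_IP", 1, seed=10)
        assert kd.depth / ctrl.depth == pytest.approx(1 / 8, rel=0.1)

    def test_same_seed_identical_library(self, small_truth):
        a = simulate_chip_library(small_truth, "enok_KD", "chip_input", 1, seed=4)
        b = simulate_chip_library(small_truth, "enok_KD", "chip_input", 1, seed=4)
        assert a.reads.equals(b.reads)

    def test_unknown_assay_rejected(self, small_truth):
        with pytest.raises(ValueError, match="assay"):
            simulate_chip_library(small_truth, "control_KD", "chip", 1, seed=1)
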