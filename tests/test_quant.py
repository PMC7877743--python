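"""Filtering, bin counting and the normalisation chain."""

import numpy as np
import pandas as pd
import pytest

from pirnasl.model import Cluster, GenomeAnnotation, GenomicBin, ReadAlignment
from pirnasl.quant import (
    cluster_abundance,
    count_bins,
    count_mirna_factor,
    filter_pirna_reads,
    pool_and_normalize,
    transposon_rpkm,
)

from conftest import make_library, random_reads


def brute_force_bin_counts(reads, bins, strand_selection="both"):
    """Independent per-read loop oracle for count_bins."""
    counts = np.zeros(len(bins), dtype=int)
    for row in reads.itertuples(index=False):
        for i, b in enumerate(bins):
            if row.chrom == b.chrom and b.start <= row.five_prime < b.end:
                sense = row.strand == b.feature_strand
                if (
                    strand_selection == "both"
                    or (strand_selection == "sense" and sense)
                    or (strand_selection == "antisense" and not sense)
                ):
                    counts[i] += 1
                break
    return counts


class TestFilter:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([22, 23, 29, 30], [23, 29]), ([], []), ([25, 26], [25, 26])],
    )
    def test_length_window_is_23_to_29_inclusive(self, config, lengths, expected):
        lib = make_library([ReadAlignment("c", 100, l, "+") for l in lengths])
        out, stats = filter_pirna_reads(lib, config)
        assert sorted(out.reads["length"]) == sorted(expected)
        assert stats.removed_length == len(lengths) - len(expected)

    def test_multimappers_removed(self, config):
        reads = [ReadAlignment("c", 100 + i, 25, "+", n_hits=2 if i < 4 else 1)
                 for i in range(10)]
        out, stats = filter_pirna_reads(lib := make_library(reads), config)
        assert len(out.reads) == 6
        assert stats.removed_multimapper == 4
        assert stats.n_retained == 6


class TestMirnaFactor:
    def _annotation(self):
        return GenomeAnnotation(
            chrom_sizes={"c": 100_000}, mirna_loci=[("c", 5000, 5100)]
        )

    def test_counts_reads_at_mirna_loci(self):
        reads = [ReadAlignment("c", 5000 + i, 22, "+") for i in range(5)]
        reads += [ReadAlignment("c", 100 + i, 25, "+") for i in range(15)]
        lib = make_library(reads)
        assert count_mirna_factor(lib, self._annotation()) == 5
        assert lib.mirna_count == 5

    def test_no_mirna_loci_rejected(self):
        lib = make_library([ReadAlignment("c", 100, 22, "+")])
        with pytest.raises(ValueError, match="miRNA loci"):
            count_mirna_factor(lib, GenomeAnnotation(chrom_sizes={"c": 1000}))

    def test_zero_factor_rejected(self):
        lib = make_library([ReadAlignment("c", 100, 25, "+")])
        with pytest.raises(ValueError, match="no miRNA reads"):
            count_mirna_factor(lib, self._annotation())

    def test_all_reads_at_loci_gives_full_count(self):
        lib = make_library([ReadAlignment("c", 5010 + i, 22, "+") for i in range(8)])
        assert count_mirna_factor(lib, self._annotation()) == 8


class TestCountBins:
    def test_half_open_boundary_assignment(self, tiling_bins):
        lib = make_library([ReadAlignment("chr2R", 1999, 25, "+")])
        counts = count_bins(lib, tiling_bins, "both")
        assert counts[1] == 1 and counts[2] == 0

    def test_read_outside_all_bins_ignored(self, tiling_bins):
        lib = make_library([ReadAlignment("chrX", 500, 25, "+"),
                            ReadAlignment("chr2R", 99_999, 25, "+")])
        assert count_bins(lib, tiling_bins, "both").sum() == 0

    def test_overlapping_bins_rejected(self):
        bins = [GenomicBin("c", 0, 1000), GenomicBin("c", 500, 1500)]
        lib = make_library([ReadAlignment("c", 100, 25, "+")])
        with pytest.raises(ValueError, match="ambiguous"):
            count_bins(lib, bins, "both")

    @pytest.mark.parametrize("selection", ["both", "sense", "antisense"])
    def test_matches_per_read_loop_oracle(self, tiling_bins, selection):
        rng = np.random.default_rng(17)
        reads = random_reads(rng, 10_000)
        lib = make_library(reads)
        fast = count_bins(lib, tiling_bins, selection)
        slow = brute_force_bin_counts(reads, tiling_bins, selection)
        assert np.array_equal(fast, slow)

    def test_conservation_over_tiling_bins(self, tiling_bins):
        # non-overlapping bins covering all read positions: totals conserved
        rng = np.random.default_rng(23)
        lib = make_library(random_reads(rng, 5000))
        assert count_bins(lib, tiling_bins, "both").sum() == 5000


class TestPoolAndNormalize:
    def test_worked_example_two_replicates(self):
        # per-million values 2.0 and 2.0, mappability 0.5 -> (2+2)/0.5 = 8
        bins = [GenomicBin("c", 0, 1000, mappability=0.5)]
        sig = pool_and_normalize(
            [np.array([2]), np.array([2])], [1_000_000, 1_000_000], bins
        )
        assert sig.values.iloc[0] == pytest.approx(8.0)

    def test_zero_count_bin_excluded(self):
        bins = [GenomicBin("c", 0, 1000, 0.8), GenomicBin("c", 1000, 2000, 0.8)]
        sig = pool_and_normalize([np.array([5, 0]), np.array([3, 0])], [100, 100], bins)
        assert "c:1000-2000" in sig.excluded
        assert sig.excluded["c:1000-2000"] == "zero_count"
        assert "c:0-1000" in sig.values.index

    def test_zero_mappability_bin_excluded_despite_counts(self):
        bins = [GenomicBin("c", 0, 1000, mappability=0.0)]
        sig = pool_and_normalize([np.array([50])], [100], bins)
        assert sig.excluded == {"c:0-1000": "zero_mappability"}
        assert len(sig.values) == 0

    def test_single_replicate_unit_mappability_reduces_to_rpm(self):
        bins = [GenomicBin("c", i * 1000, (i + 1) * 1000, 1.0) for i in range(4)]
        counts = np.array([10, 20, 0, 5])
        sig = pool_and_normalize([counts], [2_000_000], bins)
        expected = counts[counts > 0] * (1e6 / 2_000_000)
        assert np.allclose(sig.values.to_numpy(), expected)

    def test_scale_equivariance(self, tiling_bins):
        rng = np.random.default_rng(2)
        counts = [rng.integers(0, 50, 10) for _ in range(3)]
        depths = [10_000, 12_000, 9_000]
        a = pool_and_normalize(counts, depths, tiling_bins)
        b = pool_and_normalize([2 * c for c in counts], [2 * d for d in depths],
                               tiling_bins)
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())
        assert a.excluded == b.excluded

    def test_zero_depth_rejected(self, tiling_bins):
        with pytest.raises(ValueError, match="depth"):
            pool_and_normalize([np.zeros(10)], [0], tiling_bins)

    def test_universe_partition(self, tiling_bins):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 3, 10)
        sig = pool_and_normalize([counts], [1000], tiling_bins)
        assert len(sig.values) + len(sig.excluded) == 10
        assert not (set(sig.values.index) & set(sig.excluded))


class TestClusterAbundance:
    def _cluster(self):
        return [Cluster("cl0", "c", 0, 10_000, "dual_strand", "+")]

    def test_quotient_of_cluster_reads_over_factor(self):
        reads = [ReadAlignment("c", 100 + i, 25, "+") for i in range(50)]
        lib = make_library(reads, mirna_count=10)
        ab = cluster_abundance(lib, self._cluster(), "both")
        assert ab["cl0"] == pytest.approx(5.0)

    def test_zero_cluster_reads_give_zero(self):
        lib = make_library([ReadAlignment("other", 100, 25, "+")], mirna_count=10)
        assert cluster_abundance(lib, self._cluster(), "both")["cl0"] == 0.0

    def test_abundance_inverse_to_factor(self):
        reads = [ReadAlignment("c", 100 + i, 25, "+") for i in range(30)]
        a = cluster_abundance(make_library(reads, mirna_count=10), self._cluster())
        b = cluster_abundance(make_library(reads, mirna_count=20), self._cluster())
        assert a["cl0"] == pytest.approx(2 * b["cl0"])

    def test_missing_factor_rejected(self):
        lib = make_library([ReadAlignment("c", 100, 25, "+")])
        with pytest.raises(ValueError, match="miRNA factor"):
            cluster_abundance(lib, self._cluster())


class TestTransposonRpkm:
    def test_closed_form_example(self):
        rpkm = transposon_rpkm({"TE1": 10}, {"TE1": 1000}, depth=1_000_000)
        assert rpkm["TE1"] == pytest.approx(10.0)

    def test_zero_reads_give_zero(self):
        assert transposon_rpkm({"TE1": 0}, {"TE1": 5000}, 10_000)["TE1"] == 0.0

    def test_random_table_matches_formula(self):
        rng = np.random.default_rng(9)
        counts = {f"TE{i}": int(rng.integers(0, 500)) for i in range(20)}
        lengths = {f"TE{i}": int(rng.integers(500, 9000)) for i in range(20)}
        depth = 3_456_789
        rpkm = transposon_rpkm(counts, lengths, depth)
        for fam in counts:
            expected = counts[fam] * 1e9 / (lengths[fam] * depth)
            assert rpkm[fam] == pytest.approx(expected)

    def test_zero_depth_or_length_rejected(self):
        with pytest.raises(ValueError):
            transposon_rpkm({"TE1": 1}, {"TE1": 100}, 0)
        with pytest.raises(ValueError):
            transposon_rpkm({"TE1": 1}, {"TE1": 0}, 100)
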