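import numpy as np
import pytest

from pirnasl.config import AnalysisConfig
from pirnasl.model import GenomicBin, Library, ReadAlignment, reads_to_frame
from pirnasl.simulate import make_truth


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def small_truth(config):
    """Toy study: 150 labelled bins, strong effects, seeded."""
    return make_truth(
        config,
        n_dependent=30,
        n_independent=100,
        n_up=20,
        effect_size_log2=2.5,
        seed=11,
        base_rate=80.0,
        pingpong_fraction=0.2,
    )


def make_library(reads, assay="smallRNA", condition="WT", replicate=1, depth=None,
                 mirna_count=None, sample_id="test"):
    frame = reads_to_frame(reads)
    return Library(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        assay=assay,
        reads=frame,
        depth=len(frame) if depth is None else depth,
        mirna_count=mirna_count,
    )


@pytest.fixture
def tiling_bins():
    """Ten adjacent 1-kb bins on one chromosome, full mappability."""
    return [
        GenomicBin("chr2R", i * 1000, (i + 1) * 1000, mappability=1.0)
        for i in range(10)
    ]


def random_reads(rng, n, chrom="chr2R", span=10_000, min_len=23, max_len=29):
    """n random piRNA-like reads with 5' ends inside [60, span-60)."""
    return reads_to_frame(
        [
            ReadAlignment(
                chrom,
                int(rng.integers(60, span - 60)),
                int(rng.integers(min_len, max_len + 1)),
                "+" if rng.random() < 0.5 else "-",
            )
            for _ in range(n)
        ]
    )
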