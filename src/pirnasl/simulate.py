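"""Seeded synthetic genomes, small-RNA libraries and ChIP libraries.

The generator emulates the statistical structure of an ovary small-RNA /
ChIP experiment over 1-kb source-locus bins:

* a toy genome tiled into bins, each carrying a mappability fraction and
  a known per-condition log2 effect (dependent / independent /
  up-regulated with a margin so labels are unambiguous);
* small-RNA libraries whose per-bin read counts are Poisson with mean
  ``base_rate * mappability * 2**effect``, read lengths peaked at 25-26 nt
  within the 23-29 nt piRNA window, a 22-nt miRNA component at dedicated
  miRNA loci, and a tunable fraction of reads emitted together with a
  complementary partner whose 5' end overlaps by exactly 10 nt (the
  ping-pong signature);
* ChIP IP/input libraries with per-bin condition-specific enrichment.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .model import (
    Cluster,
    GenomeAnnotation,
    GenomicBin,
    Library,
    READ_COLUMNS,
    TransposonFamily,
    bin_id,
)

__all__ = [
    "SimulationTruth",
    "make_truth",
    "simulate_smallrna_library",
    "simulate_chip_library",
    "write_truth_json",
]

SMALLRNA_CONDITIONS = ("WT", "mut1", "mut2")
CHIP_CONDITIONS = ("control_KD", "enok_KD")

#: Read-length distribution inside the 23-29 nt piRNA window, peaked at 25-26.
PIRNA_LENGTHS = np.arange(23, 30)
PIRNA_LENGTH_PROBS = np.array([0.06, 0.12, 0.24, 0.28, 0.16, 0.09, 0.05])

#: Margin (log2) separating effect classes from the decision threshold so
#: true labels never sit on the classification boundary.
LABEL_MARGIN = 0.5

_EDGE_PAD = 40  # keep read 5' ends this far from bin edges so pairs fit


@dataclass
class SimulationTruth:
    """A simulated study design plus its ground truth.

    ``bin_effects`` maps bin id -> (true log2 FC in mut1, in mut2);
    ``bin_labels`` maps bin id -> dependent/independent/up;
    ``chip_enrichment`` maps bin id -> (IP/input ratio in control KD,
    ratio in enok KD).
    """

    annotation: GenomeAnnotation
    bin_effects: dict[str, tuple[float, float]]
    bin_labels: dict[str, str]
    pingpong_fraction: float
    base_rate: float
    chip_enrichment: dict[str, tuple[float, float]]
    mirna_fraction: float = 0.1
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pingpong_fraction <= 1.0:
            raise ValueError("pingpong_fraction must lie in [0, 1]")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        thr = self.config.dependency_threshold
        for bid, label in self.bin_labels.items():
            fc1, fc2 = self.bin_effects[bid]
            if label == "dependent":
                ok = fc1 <= -(thr + LABEL_MARGIN) and fc2 <= -(thr + LABEL_MARGIN)
            elif label == "up":
                ok = fc1 >= thr + LABEL_MARGIN and fc2 >= thr + LABEL_MARGIN
            elif label == "independent":
                ok = abs(fc1) <= LABEL_MARGIN and abs(fc2) <= LABEL_MARGIN
            else:
                raise ValueError(f"unknown label {label!r}")
            if not ok:
                raise ValueError(f"label {label!r} inconsistent with effects ({fc1}, {fc2})")


def make_truth(
    config: AnalysisConfig,
    n_dependent: int = 1000,
    n_independent: int = 4600,
    n_up: int = 400,
    effect_size_log2: float = 2.5,
    seed: int = 0,
    base_rate: float = 100.0,
    pingpong_fraction: float = 0.2,
    mirna_fraction: float = 0.1,
    control_enrichment: float = 8.0,
    kd_enrichment_dependent: float = 1.0,
    cluster_size_bins: int = 50,
    dual_strand_fraction: float = 0.8,
    chrom_length: Optional[int] = None,
) -> SimulationTruth:
    """Lay out a toy genome of labelled 1-kb bins with known effects.

    Class labels (dependent / independent / up) are assigned to bins in a
    seeded random order; mappability is drawn from a mixture with 90% of
    bins in [0.6, 1.0] and 10% in (0, 0.3].  ChIP enrichment defaults to
    the study conditions: IP/input 8 everywhere in the control knockdown,
    collapsing to 1 at dependent bins in the perturbed knockdown.
    """
    if min(n_dependent, n_independent, n_up) < 0:
        raise ValueError("class counts must be non-negative")
    if effect_size_log2 <= config.dependency_threshold:
        raise ValueError(
            "effect_size_log2 must exceed the dependency threshold "
            f"({config.dependency_threshold}) for labels to be recoverable"
        )
    n_bins = n_dependent + n_independent + n_up
    if n_bins == 0:
        raise ValueError("at least one bin is required")
    rng = np.random.default_rng(seed)
    width = config.bin_width
    needed = n_bins * width
    if chrom_length is None:
        chrom_length = needed
    if chrom_length < needed:
        raise ValueError(f"genome too small: need {needed} bp for {n_bins} bins")

    # mappability mixture: mostly well-mappable, a repeat-like low tail
    low = rng.random(n_bins) < 0.10
    mapp = np.where(low, rng.uniform(0.05, 0.3, n_bins), rng.uniform(0.6, 1.0, n_bins))

    labels = np.array(
        ["dependent"] * n_dependent + ["independent"] * n_independent + ["up"] * n_up
    )
    rng.shuffle(labels)

    # contiguous runs of bins form clusters; most are dual-strand
    n_clusters = max(1, int(np.ceil(n_bins / cluster_size_bins)))
    cluster_types = np.where(
        rng.random(n_clusters) < dual_strand_fraction, "dual_strand", "uni_strand"
    )

    bins: list[GenomicBin] = []
    clusters: list[Cluster] = []
    for ci in range(n_clusters):
        first = ci * cluster_size_bins
        last = min(n_bins, first + cluster_size_bins)
        if first >= last:
            break
        ctype = cluster_types[ci]
        clusters.append(
            Cluster(
                cluster_id=f"cl{ci}",
                chrom="chr_sim",
                start=first * width,
                end=last * width,
                cluster_type=ctype,
                strand="+",
            )
        )
        for i in range(first, last):
            bins.append(
                GenomicBin(
                    chrom="chr_sim",
                    start=i * width,
                    end=(i + 1) * width,
                    mappability=float(mapp[i]),
                    group="RD_SL",
                    feature_strand="+",
                )
            )

    mirna_loci = [("chr_mirna", 200 * i, 200 * i + 100) for i in range(20)]
    families = [TransposonFamily(f"TE{i}", int(rng.integers(1000, 8000))) for i in range(10)]

    annotation = GenomeAnnotation(
        chrom_sizes={"chr_sim": int(chrom_length), "chr_mirna": 4000},
        clusters=clusters,
        transposon_families=families,
        mirna_loci=mirna_loci,
        bins=bins,
    )

    effects: dict[str, tuple[float, float]] = {}
    lab: dict[str, str] = {}
    chip: dict[str, tuple[float, float]] = {}
    for b, label in zip(bins, labels):
        bid = bin_id(b)
        if label == "dependent":
            effects[bid] = (-effect_size_log2, -effect_size_log2)
            chip[bid] = (control_enrichment, kd_enrichment_dependent)
        elif label == "up":
            effects[bid] = (effect_size_log2, effect_size_log2)
            chip[bid] = (control_enrichment, control_enrichment)
        else:
            effects[bid] = (0.0, 0.0)
            chip[bid] = (control_enrichment, control_enrichment)
        lab[bid] = str(label)

    return SimulationTruth(
        annotation=annotation,
        bin_effects=effects,
        bin_labels=lab,
        pingpong_fraction=pingpong_fraction,
        base_rate=base_rate,
        chip_enrichment=chip,
        mirna_fraction=mirna_fraction,
        config=config,
        seed=seed,
    )


def _sample_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(PIRNA_LENGTHS, size=n, p=PIRNA_LENGTH_PROBS)


def _make_frame(chrom, five, length, strand) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "five_prime": five.astype(np.int64),
            "length": length.astype(np.int64),
            "strand": strand,
            "n_hits": np.ones(len(five), dtype=np.int64),
        },
        columns=list(READ_COLUMNS),
    )


def simulate_smallrna_library(
    truth: SimulationTruth,
    condition: str,
    replicate: int = 1,
    seed: Optional[int] = None,
) -> Library:
    """Draw one small-RNA library from the truth model.

    Per-bin primary read counts are Poisson with mean
    ``base_rate * mappability * 2**effect(condition)``; each primary read
    is accompanied, with probability ``pingpong_fraction``, by a
    complementary opposite-strand partner whose 5' end overlaps it by
    exactly 10 nt.  Dual-strand bins emit both strands 50/50; uni-strand
    bins emit the cluster's sense strand only.  A miRNA component of
    fixed 22-nt reads (default 10% of the library) is placed at the
    annotation's miRNA loci.
    """
    if condition not in SMALLRNA_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {SMALLRNA_CONDITIONS}")
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=seed, spawn_key=(zlib.crc32(condition.encode()), replicate)
        )
    )
    ann = truth.annotation
    bins = ann.bins
    n_bins = len(bins)
    starts = np.array([b.start for b in bins])
    ends = np.array([b.end for b in bins])
    mapp = np.array([b.mappability for b in bins])
    ids = [bin_id(b) for b in bins]
    cond_idx = {"WT": None, "mut1": 0, "mut2": 1}[condition]
    if cond_idx is None:
        fc = np.zeros(n_bins)
    else:
        fc = np.array([truth.bin_effects[i][cond_idx] for i in ids])

    # which bins sit in uni-strand clusters (sense-strand-only emission)
    uni = np.zeros(n_bins, dtype=bool)
    for cl in ann.clusters:
        if cl.cluster_type == "uni_strand":
            uni |= (starts >= cl.start) & (ends <= cl.end)

    mean = truth.base_rate * mapp * np.power(2.0, fc)
    counts = rng.poisson(mean)
    total = int(counts.sum())

    bin_of_read = np.repeat(np.arange(n_bins), counts)
    lo = starts[bin_of_read] + _EDGE_PAD
    hi = ends[bin_of_read] - _EDGE_PAD
    pos = lo + rng.integers(0, hi - lo, size=total) if total else np.empty(0, dtype=np.int64)
    # strand: 50/50 in dual-strand bins, '+' in uni-strand bins
    plus = np.where(uni[bin_of_read], True, rng.random(total) < 0.5)
    lengths = _sample_lengths(rng, total)

    # ping-pong partners: exact 10-nt 5' overlap on the opposite strand
    paired = rng.random(total) < truth.pingpong_fraction
    p_pos = pos[paired]
    p_plus = plus[paired]
    partner_pos = np.where(p_plus, p_pos + 9, p_pos - 9)
    partner_plus = ~p_plus
    partner_len = _sample_lengths(rng, int(paired.sum()))

    all_pos = np.concatenate([pos, partner_pos])
    all_plus = np.concatenate([plus, partner_plus])
    all_len = np.concatenate([lengths, partner_len])
    n_pi = len(all_pos)

    # miRNA component on the dedicated loci
    n_mi = 0
    mi_frames = []
    if ann.mirna_loci and truth.mirna_fraction > 0:
        frac = truth.mirna_fraction
        n_mi = int(rng.poisson(n_pi * frac / (1.0 - frac))) if frac < 1 else 0
        if n_mi:
            locus = rng.integers(0, len(ann.mirna_loci), size=n_mi)
            l_start = np.array([l[1] for l in ann.mirna_loci])
            l_end = np.array([l[2] for l in ann.mirna_loci])
            mi_pos = l_start[locus] + rng.integers(
                0, l_end[locus] - l_start[locus] - 22, size=n_mi
            )
            mi_frames.append(
                _make_frame(
                    np.repeat(np.array(["chr_mirna"], dtype=object), n_mi),
                    mi_pos,
                    np.full(n_mi, 22),
                    np.repeat(np.array(["+"], dtype=object), n_mi),
                )
            )

    pi_frame = _make_frame(
        np.repeat(np.array(["chr_sim"], dtype=object), n_pi),
        all_pos,
        all_len,
        np.where(all_plus, "+", "-").astype(object),
    )
    reads = pd.concat([pi_frame, *mi_frames], ignore_index=True)
    return Library(
        sample_id=f"smallRNA_{condition}_rep{replicate}",
        condition=condition,
        replicate=replicate,
        assay="smallRNA",
        reads=reads,
        depth=len(reads),
        mirna_count=n_mi,
    )


def simulate_chip_library(
    truth: SimulationTruth,
    condition: str,
    assay: str,
    replicate: int = 1,
    seed: Optional[int] = None,
    read_length: int = 100,
) -> Library:
    """Draw one ChIP library (IP or input) from the truth model.

    Input counts are Poisson with mean ``base_rate * mappability``; IP
    counts multiply that mean by the bin's enrichment ratio for the
    condition.
    """
    if assay not in ("chip_IP", "chip_input"):
        raise ValueError(f"unknown assay {assay!r}")
    if condition not in CHIP_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CHIP_CONDITIONS}")
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=seed,
            spawn_key=(zlib.crc32(f"{condition}/{assay}".encode()), replicate),
        )
    )
    ann = truth.annotation
    bins = ann.bins
    starts = np.array([b.start for b in bins])
    ends = np.array([b.end for b in bins])
    mapp = np.array([b.mappability for b in bins])
    ids = [bin_id(b) for b in bins]

    mean = truth.base_rate * mapp
    if assay == "chip_IP":
        cond_idx = 0 if condition == "control_KD" else 1
        ratio = np.array([truth.chip_enrichment[i][cond_idx] for i in ids])
        mean = mean * ratio
    counts = rng.poisson(mean)
    total = int(counts.sum())
    bin_of_read = np.repeat(np.arange(len(bins)), counts)
    pad = max(_EDGE_PAD, read_length)  # keep occupied intervals on-chromosome
    lo = starts[bin_of_read] + pad
    hi = ends[bin_of_read] - pad
    if total and (hi <= lo).any():
        raise ValueError("bins too narrow for the requested ChIP read length")
    pos = lo + rng.integers(0, hi - lo, size=total) if total else np.empty(0, dtype=np.int64)
    plus = rng.random(total) < 0.5
    reads = _make_frame(
        np.repeat(np.array(["chr_sim"], dtype=object), total),
        pos,
        np.full(total, read_length),
        np.where(plus, "+", "-").astype(object),
    )
    return Library(
        sample_id=f"{assay}_{condition}_rep{replicate}",
        condition=condition,
        replicate=replicate,
        assay=assay,
        reads=reads,
        depth=total,
    )


def write_truth_json(truth: SimulationTruth, path: str | Path) -> None:
    """Sidecar with labels, effects, enrichment, seed and config hash."""
    payload = {
        "seed": truth.seed,
        "config_digest": truth.config.digest(),
        "base_rate": truth.base_rate,
        "pingpong_fraction": truth.pingpong_fraction,
        "mirna_fraction": truth.mirna_fraction,
        "bin_labels": truth.bin_labels,
        "bin_effects": {k: list(v) for k, v in truth.bin_effects.items()},
        "chip_enrichment": {k: list(v) for k, v in truth.chip_enrichment.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
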