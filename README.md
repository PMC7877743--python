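# pirnasl — piRNA source-locus analysis on 1-kb genomic bins

`pirnasl` quantifies piRNA production and chromatin occupancy across a
genome tiled into 1-kb bins ("source loci"), and asks which loci depend
on a regulator by comparing two mutant conditions against a reference.
It is written for germline small-RNA biology in *Drosophila*-style
systems, where dual-strand piRNA clusters are transcribed
noncanonically and their output collapses when the licensing machinery
is perturbed — but nothing in the code is species-specific.

The package covers five connected analyses:

1. **Bin quantification.** Unique-mapper reads of 23–29 nt are counted
   by their 5'-end coordinate per 1-kb bin. Each replicate is scaled to
   reads per million of its uniquely-mapped depth, replicates are
   pooled, and the pooled value is divided by the bin's mappability
   fraction. Bins with zero mappability or zero pooled reads are
   excluded (and remembered, so comparisons can drop a bin that is
   empty on either side).
2. **Dependency classification.** For each bin,
   `FC_i = log2(signal_mut_i / signal_ref)` in two independent mutants.
   A bin is *dependent* if `FC_1 < -1.5` **and** `FC_2 < -1.5`, *up* if
   both exceed `+1.5`, *independent* otherwise (strict inequalities).
3. **Ping-pong signature.** For every complementary read pair on a
   locus, the 5'-overlap is `k = q − p + 1` (plus-read 5' at `p`,
   minus-read 5' at `q`); the z-score at `k = 10` against the mean and
   population SD of the other overlap lengths (1–30 by default)
   quantifies the ping-pong amplification signature. Pair counts,
   length histograms and per-family antisense abundances are normalised
   to each library's miRNA read count.
4. **ChIP tracks.** IP and input occupancy follow the same
   normalisation chain; conditions are compared as
   `log2((IP_kd+0.1)/(IP_ctrl+0.1)) − log2((IN_kd+0.1)/(IN_ctrl+0.1))`.
5. **Group statistics.** Locus groups are compared with the two-sided
   Wilcoxon rank-sum test (continuity-corrected normal approximation,
   exact enumeration for small tie-free groups); p-values below
   2.2e-16 are reported as the string `"P < 2.2e-16"`.

A seeded synthetic-data generator (`pirnasl.simulate`) builds toy
genomes with known per-bin effects, ping-pong pairing fractions and
ChIP enrichment changes, so every stage can be tested against ground
truth.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(seed 7: 1,200 bins — 200 dependent at log2 effect −2.5, 920
unaffected, 80 up at +2.5 — three replicates per condition):

```bash
python analysis/01_simulate_study.py
python analysis/02_quantify_bins.py
python analysis/03_classify_dependency.py
python analysis/04_pingpong_signature.py
python analysis/05_chip_occupancy.py
```

which prints, among other lines:

```
dependency calls: {'dependent': 199, 'excluded': 1, 'independent': 920, 'up': 80}
agreement with simulation truth: 99.75%
dependent_mut1 vs independent_mut1: W = 10, P < 2.2e-16
WT: ping-pong z(10) = 238.1
track median over dependent bins:   -2.77
track median over other bins:       +0.22
```

Reading: 199 of the 200 truly dependent bins are recovered (one bin was
excluded by the zero-read rule), piRNA levels at dependent loci
collapse in both mutants (rank-sum p below the reporting floor), the
simulated ping-pong pairing produces a very strong 10-nt overlap
z-score, and the input-corrected ChIP track drops by ~2.8 log2 units
exactly at the loci whose enrichment was ablated. All tables land under
`results/pipeline/`. The same pipeline is scriptable through the
`pirnasl` CLI (`simulate`, `quant`, `classify`, `pingpong`, `chip`,
`compare`, `all`).

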