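# Methods

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention) internally;
1-based SAM positions are converted on ingest. A read is located by its
5'-end coordinate — leftmost base on the plus strand, rightmost on the
minus strand — and a read belongs to the unique bin containing that
coordinate. Fractional-overlap assignment was deliberately rejected:
5'-end assignment is unambiguous, strand-symmetric, and matches how
small-RNA 5' ends are interpreted biologically (the 5' end is the
defined end of a mature piRNA). Bin sets used for counting must be
non-overlapping; overlap is an error rather than a silent double-count.
"Unique mapper" means alignment multiplicity `n_hits == 1`; the
multiplicity is taken from the score column of the tabular dialect or
the `NH` tag of SAM records (absent tag ⇒ 1).

## Normalisation chain

Per condition: each replicate's raw per-bin counts are scaled to reads
per million of that replicate's retained unique-mapper depth; scaled
values are summed over replicates; the sum is divided by the bin's
mappability fraction (a number in [0,1]: the fraction of positions in
the bin where a read aligns uniquely). Division by the fraction, rather
than a mappability-weighted effective length, is the package's choice
where the convention was open; it is exact when mappable positions are
uniformly usable.

**Zero rule.** Bins with zero mappability are always excluded. Bins
whose pooled raw count is zero are excluded per signal, and a fold
change is only computed for bins retained on *both* sides of a
comparison ("either-side" exclusion). This keeps every retained fold
change finite without pseudocounts. Whether the original exclusion was
per condition or per comparison was an open choice; either-side is the
most conservative reading and is what the exclusion bookkeeping
(`BinSignal.excluded`, reasons `zero_count` / `zero_mappability`)
implements.

The miRNA normalisation factor of a small-RNA library is the number of
unique-mapper reads whose 5' end lies in an annotated miRNA locus,
regardless of read length — locus membership, not the canonical 22-nt
length, is the criterion. Cluster abundances, ping-pong pair counts,
length histograms and family antisense abundances divide by this
factor; the per-bin signal chain uses depth and mappability instead.

Transposon-family expression uses the standard
`RPKM = count / (length_kb × depth_millions)` on unique-mapper counts;
multi-mapper rescue (EM assignment) is out of scope.

## Dependency classification

`FC_i = log2(pooled_mut_i / pooled_ref)` per bin, on pooled
mappability-normalised signals (not per-replicate fold changes
averaged — pooling precedes analysis throughout). Calls use strict
inequalities at the threshold `t = 1.5`: dependent iff both `FC_i < −t`,
up iff both `> +t`, independent otherwise. A bin sitting exactly at the
threshold is therefore independent. The three calls partition all
non-excluded bins; bins that clear the threshold in only one mutant are
deliberately folded into "independent" and visible in the raw fold
change columns of the calls table.

## Wilcoxon rank-sum and reporting floor

Group comparisons use the two-sided Wilcoxon rank-sum test. Small
tie-free groups (both n ≤ 8) are evaluated by exact enumeration; larger
or tied groups use the normal approximation with continuity correction
(scipy's `mannwhitneyu`). The continuity-corrected approximation is
within 0.02 of exact enumeration uniformly over all achievable
statistics once both groups have ≥ 5 members; below that the exact path
is used anyway. Any p-value below 2.2e-16 — the smallest value the
reference implementation of the test reports reliably — is rendered as
the string `"P < 2.2e-16"`; the numeric p is still stored. Box-plot
summaries report median, quartiles and the 5th/95th percentiles using
linear interpolation between order statistics (the default percentile
convention, pinned so summaries are bit-for-bit reproducible).

## Ping-pong signature

For a plus-strand read with 5' end `p` and a minus-strand read with 5'
end `q` on the same reference, the pair's 5'-overlap is
`k = q − p + 1`; the profile counts all read pairs (reads sharing a
position multiply) with `1 ≤ k ≤ 30`, each pair once, scaled by
1/miRNA-factor when a factor is supplied. The z-score at the 10-nt
focus uses all other overlap lengths (1–9, 11–30) as background:
`z = (c₁₀ − mean) / population_sd`. The background window is the whole
profile minus the focus — a symmetric-window convention — and is
configurable (`overlap_max`, `pingpong_focus`). A zero-variance
background yields an undefined z (None), not an exception, since flat
profiles legitimately occur on uni-strand loci. Scaling the profile by
a positive factor leaves z unchanged.

## ChIP track arithmetic

Pseudocounts are applied to normalised per-million signal values, not
raw counts, mirroring track-level arithmetic:
`A = log2((IP_kd+0.1)/(IP_ctrl+0.1))`, `B` likewise for input, track
`= A − B`. The subtraction-stage pseudocount 0.01 is mathematically
inert (`(A+c) − (B+c) = A − B`) and is retained in the configuration
purely so the parameter set matches the track-generation provenance.
Bins excluded for zero counts re-enter the track at signal 0 — the
ratio pseudocount handles emptiness there — whereas zero-mappability
bins stay excluded. Box-plot/group comparisons of occupancy reuse the
same rank-sum machinery as the piRNA signals; by default they operate
on the IP mappability-normalised signal, with the input-corrected track
available as an alternative value set.

Replicate QC uses Spearman correlation over a fixed-width bin grid,
skipping bins that are zero in all samples.

## Synthetic-data generator

The generator emulates the *statistical* structure of an ovary
small-RNA/ChIP study; it produces no nucleotide sequences and no
alignment ambiguity (all reads are unique mappers unless a fixture says
otherwise).

* **Genome.** One chromosome tiled into 1-kb bins grouped into
  contiguous clusters of 50 bins, 80% dual-strand (both strands
  emitted 50/50) and 20% uni-strand; a separate small chromosome holds
  20 miRNA loci. Mappability is a mixture: 90% of bins uniform on
  [0.6, 1.0], 10% on [0.05, 0.3], giving a realistic low-mappability
  repeat-like tail.
* **Effects.** Bins are labelled dependent / independent / up with true
  log2 effects −e / 0 / +e (default e = 2.5). Labels sit at least 0.5
  log2 units clear of the 1.5 decision threshold by construction, so
  truth labels are never boundary-ambiguous.
* **Counts.** Per-bin read counts are Poisson with mean
  `base_rate · mappability · 2^effect` (default base_rate 100 reads per
  unit-mappability bin per replicate — deep enough that a −2.5 effect
  leaves tens of pooled reads, as in a well-sequenced ovary library).
  Poisson is the minimal noise model and keeps recovery rates
  analysable; biological overdispersion is not modelled, so recovery
  rates here are upper bounds on what identical settings would achieve
  on real libraries.
* **Reads.** Lengths are drawn from a discrete distribution peaked at
  25–26 nt within 23–29; a 22-nt miRNA component (default 10% of the
  library) lands on the miRNA loci. With probability
  `pingpong_fraction` a read is emitted together with a complementary
  opposite-strand partner at exactly 10-nt 5'-overlap; background pairs
  arise only by position coincidence.
* **ChIP.** Input counts are Poisson at `base_rate · mappability`; IP
  multiplies the mean by a per-bin enrichment ratio — default 8 in the
  control knockdown everywhere, collapsing to 1 at dependent bins in
  the perturbed knockdown.

Everything derives from `numpy.random.default_rng` seeded by
(seed, condition, assay, replicate) via CRC-keyed `SeedSequence` spawn
keys, so libraries are reproducible per seed across processes.

## Problem sizes

The recovery experiments run 20 seeds of a 6,000-bin study
(1,000/4,600/400 bins per class, three replicates of three small-RNA
conditions, ≈4.5 M reads per seed) for classification, 5,000-read
libraries for the ping-pong signal/null contrast, and a 1,200-bin study
(same class proportions) with three IP/input replicates per condition
for the ChIP track; these sizes give stable medians and rates while a
full run of the test suite plus the acceptance script stays in the
low minutes on a single CPU.

A note on the depth-normalisation shift visible in the ChIP track and
fold changes: when a sixth of the genome loses signal in the knockdown,
per-million scaling inflates the remaining bins by
`log2(Σctrl/Σkd) ≈ +0.23`; medians over unaffected bins therefore sit
slightly above 0 rather than at 0. This is a property of depth
normalisation itself, not an artifact of the generator, and the same
shift arises in real data when a large signal compartment collapses.

## Known limitations

* No overdispersion in the default noise model (an NB option would
  drop in at the Poisson draw; not currently exposed).
* No sequence-level simulation: mappability is an abstract fraction,
  multi-mapping structure cannot be emulated beyond the `n_hits` field.
* The ping-pong profile counts pairs within a single reference
  coordinate system; heterotypic partitioning by PIWI protein and
  phasing signatures are out of scope.
* Group labels (RD_SL / RI_SL / SO_SL / HET_NON_SL) are carried and
  serialised but the synthetic generator populates only one source
  class; real-data group files are supplied as labelled BED.
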