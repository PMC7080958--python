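# Methods

This note documents the models, parameter choices and numerical
conventions behind `cnascape`, and what the synthetic-data tests do and
do not establish about real data.

## Coordinate frame

All internal coordinates are 0-based half-open; SEG files on disk use
the common 1-based inclusive dialect and are converted on read.
Chromosome names are normalized by stripping a leading `chr`
(case-insensitive).  X and Y are excluded from the default analysis set
to avoid gender bias in cohort frequencies.

Arms are derived from `acen`-stained cytoband rows: the p arm runs from
0 to the first acen start, the q arm from the last acen end to the
chromosome end.  Chromosomes without acen bands are kept for binning and
breakpoint work but skipped by arm-level calls (with a warning).
Telomeres are not annotated in most inputs, so a fixed margin of 10 kb
per chromosome end (the UCSC gap-track convention) is treated as
telomeric; it is configurable per build.  The packaged hg19 file is a
condensed cytoband table carrying only the arm/centromere boundaries
(four bands per autosome built from the standard hg19 centromere
coordinates), which is all the pipeline consumes.

The genome-wide bin grid tiles each chromosome with fixed-width bins
(default 1 Mb).  The final partial bin of each chromosome is retained,
not dropped or merged: the permutation null sees the same grid, so bin
length enters the null correctly.

## CNA calling

States are assigned per segment with strict thresholds: gain iff
log2 > 0.2, loss iff log2 < −0.2, neutral otherwise (boundary values are
neutral).  An *event* for burden purposes is one non-neutral called
segment; mean event size is undefined (reported missing) for all-neutral
samples; the altered-genome fraction uses the build's total autosome
length as denominator.

**Bin-state rule.** Frequency profiles and the clustering matrix need
one state per sample per bin.  A bin takes the state (gain or loss)
whose segments cover the largest fraction of the bin, provided that
state covers strictly more than half the bin; ties and ≤ 50% coverage
give neutral.  This guarantees gain_freq + loss_freq ≤ 1 per bin.  The
rule is a design choice of this package — any rule mapping segment calls
to bins would do — and is verified against a literal per-bp majority
oracle in the tests.

**Arm-level events.** An arm event is a maximal run of *adjacent*
same-state segments whose summed overlap with an arm exceeds 50% of the
arm length (strictly).  Merging adjacent same-state segments reflects
that segmentation splits single biological events; a
`merge_adjacent=False` flag restores the literal single-segment reading.
Per sample and arm at most one gain and one loss event are reported (the
largest run of each state).  Arm frequencies are event occurrence over
cohort size; the gain/loss correlation is the Pearson r across arms with
a two-sided t-distribution p, undefined (missing, with a warning) when
either vector has zero variance.

## Breakpoints and hotspots

The filter order is fixed and tested against a brute-force oracle:
(1) drop segments shorter than 10 kb; (2) evaluate boundaries between
*consecutive retained* segments; (3) keep |Δlog2| strictly greater than
0.4; (4) drop boundaries inside telomere/centromere exclusion zones.
The boundary position is the left segment's end; when retained segments
do not abut (a gap left by the size filter or missing data), the
midpoint of the gap is used.

**Permutation null.** Each of n_perm permutations relocates every
breakpoint to a uniform random integer position on its own chromosome,
drawn from the complement of the exclusion zones.  This preserves
per-sample and per-chromosome breakpoint totals exactly and needs no
segment-level bookkeeping.  (An alternative would relocate whole CNA
segments; breakpoint-level shuffling is the simpler model of "random
breakage position" and is what the statistics consume.)

**Enrichment p-values.** The per-bin p-value is the upper tail
P(X ≥ observed) of a Poisson law with mean equal to the bin's
permutation-estimated null mean, Bonferroni-corrected by the number of
bins; a bin is a hotspot iff corrected p < 0.01.  A parametric tail is
used because an empirical tail over n_perm shuffles is floored at
1/n_perm, which can never clear a Bonferroni bar of 0.01 over thousands
of bins regardless of how extreme the observation is.  `method` can be
set to `normal` (z against the permutation sd) or `empirical` (needs the
full permutation matrix).  Bins with null mean 0 and a positive
observation use a floor mean of 1/n_perm.  Region-set overlap (CFS/NFR)
counts a hotspot bin as overlapping at ≥ 1 bp intersection.

## Chromothripsis-like patterns

A switch is a pair of consecutive retained (≥ 10 kb) segments whose
call states differ AND whose |Δlog2| ≥ 0.4.  Requiring both conditions
jointly (their conjunction is not forced by either condition alone)
guards against sub-threshold flicker near a call boundary and against
large within-state jumps; relaxing either threshold can only add
switches, which the tests assert as a monotonicity property.

**Clustering likelihood ratio.** For k of the chromosome's N switches
falling in a candidate region of length L on a chromosome of length G,
the clustered model places rate λ1 = k/L inside the region and
λ2 = (N−k)/(G−L) outside; the homogeneous model has λ0 = N/G
everywhere.  The statistic is the log10 likelihood-ratio of these two
Poisson models, defined as 0 when k = 0 or λ1 = λ0.  When all switches
cluster in the region it reduces to N·ln(G/L)/ln 10.  It is 0 under
homogeneity and strictly increasing in the degree of clustering, and is
verified to 1e-9 against a direct `poisson.logpmf` evaluation of the two
log-likelihoods.  The LR lives behind one function so an alternative
clustering statistic can be swapped in.

**Scan.** Candidate windows are multi-scale: widths grow from 30 Mb
(the smallest affected-region size worth reporting) by factors of 1.5 up
to the chromosome length, sliding by 5 Mb.  A window's LR is evaluated
on the *span of the switches it contains*, not the window width — a
window is merely a device for choosing which switches are considered
together, and using its raw width would penalize a tight cluster sitting
in a loose window.  Windows passing both thresholds (≥ 20 switches,
log10 LR ≥ 10) have their switch spans merged, and each merged region is
re-evaluated once on its own span.  With 0.5–3 Mb oscillation segments,
~20 switches span ≈ 35–45 Mb, so single fixed-width 30-Mb windows would
systematically truncate real clusters; the multi-scale span-based scan
avoids that without changing the thresholds.

A sample is a chromothripsis case if ≥ 1 chromosome qualifies;
per-chromosome shares use CTLP-positive samples as denominator, counting
one per qualifying sample chromosome.

Note a threshold interplay: the maximum attainable LR for a fully
clustered pattern is N·ln(G/L)/ln 10, so a ~40 Mb, 24-switch cluster
reaches log10 LR 10 only on chromosomes of ≳ 105 Mb.  The detection
benchmarks therefore plant chromothripsis on hg19 chromosome 8
(146 Mb) — also the chromosome most frequently affected in head-and-neck
cohorts — where detection is comfortably above threshold.

## Cohort clustering

Samples are columns of a bins × samples matrix, state-encoded
(−1/0/+1) by default — robust to signal-scale differences across array
platforms — with a length-weighted mean-log2 mode available.  Ward
linkage on Euclidean distances (scipy), cut to k = 2 flat clusters by
default; labels are renumbered in order of first appearance over the
lexicographically sorted sample list, making the assignment deterministic
and invariant to input order up to renaming.  Clinical enrichment drops
unknown values from denominators and tests each cluster against the rest
with a two-sided Fisher exact test.

## Synthetic cohorts

The generator works at the segment level: per chromosome, a baseline
partition (Poisson-many uniform cuts, mean segment ≈ 5 Mb) with
segment-mean jitter N(0, 0.05²), on which planted events shift the mean:

- **Arm events**: per-arm *exclusive* gain-or-loss propensities (each
  arm is gain-prone or loss-prone, never both), amplitude ±0.5, covering
  a uniform 60–95% of the arm anchored at one end.  Exclusivity is what
  induces the negative arm gain/loss frequency correlation.
- **Focal events**: Poisson(2) per sample, log-uniform 0.2–5 Mb,
  amplitude ±0.6, positions uniform with chromosomes weighted by length.
- **Chromothripsis**: in 5% of samples, one chromosome (chr8 on hg19,
  the largest chromosome otherwise) carries an oscillating block of
  alternating baseline/baseline+0.6 segments, sizes uniform 0.5–3 Mb,
  with an exact planted switch count (24 by default; odd counts run the
  block to the chromosome end because a closed oscillation has even
  parity).
- **Hotspots**: optional bins receive short (20 kb) ±0.6 spike segments
  until the bin's expected breakpoint count is `multiplier` times the
  cohort's genome-wide per-bin background (each spike contributes two
  qualifying boundaries).
- **Subgroup**: 30% of samples by default form an HPV-positive,
  nasopharynx-labelled subgroup with a forced 3q gain and a vetoed 3p
  loss; a flag can instead suppress all arm events in the subgroup to
  build high-burden vs quiet two-group cohorts.

Event amplitudes (0.5–0.6) sit at ≥ 2.5× the call threshold with noise
sd 0.05, so planted events are recoverable essentially deterministically;
this is by design — the tests probe the analysis logic, not the calling
of marginal events.  All coordinates are integers and every draw flows
through one seeded generator, so identical config + seed reproduces SEG
output byte-for-byte.

**What the simulation does not model:** tumor purity and subclonality,
allele-specific copy number, probe-level noise and re-segmentation
artifacts, platform batch effects, correlated event co-occurrence beyond
the planted subgroup, and realistic size/amplitude joint distributions.
Passing recovery tests therefore demonstrates correctness of the
statistics under their stated models, not calling performance on noisy
real arrays.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use desk-scale problem sizes
chosen to keep runs at minutes on one CPU: toy-build cohorts of 60–200
samples, 1,000 permutations, 100 seeded replicates for type-I and
recovery rates (30 in the acceptance script), 20 (10) seeds for
clustering agreement, and 1,000 random cases per brute-force oracle
comparison.  Oracle agreement is exact for integer outputs and 1e-9 for
the likelihood ratio; stochastic benchmarks assert the documented
bounds (type-I < 0.05 flags/run, recovery ≥ 95%, false flags ≤ 1%,
ARI ≥ 0.8 in ≥ 90% of seeds, correlation negative in ≥ 95% of cohorts).
Cohort-scale headline numbers that depend on a specific 1,395-sample
meta-cohort (total events per sample, hotspot counts, CTLP incidence)
are exercised as arithmetic on their printed marginals, not reproduced
from raw data.

## Known limitations

- The hotspot null shuffles breakpoints, not segments; long-range
  dependence between the two ends of one CNA is ignored.
- The CTLP likelihood ratio is this package's concrete statistic; other
  scanners use different likelihood definitions, so absolute LR values
  are not comparable across tools (thresholds are, qualitatively).
- Arm-event detection reports coverage of the *arm*, so events spanning
  the centromere contribute to both arms independently.
- `ctlp_scan` assumes segmented input already smoothed by CBS-like
  segmentation; raw probe-level data would need segmentation upstream.
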