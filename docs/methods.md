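# Methods

## The target model

The analysis assumes dormancy entry produces a genome-wide,
TET-independent methylation gain, on top of which a subset of
TET1/TET2-bound elements is held lowly methylated by continued TET
activity. A candidate region is any TET1- or TET2-bound interval (the
union of both flattened peak collections, exact duplicates collapsed;
overlapping but non-identical peaks from the two factors remain separate
candidates so that each candidate has a well-defined binding class).
Candidates partition into `both` / `tet1_only` / `tet2_only` by ≥ 1 bp
overlap with each factor's peaks.

The call itself uses two inequalities on region methylation rates at the
dormancy timepoint *t* = 72 h:

- protection: `m(WT, t) − m(WT, 0) ≤ wt_protection_max_delta` (default
  0.10). The protection criterion has no published numeric threshold;
  the same 10% magnitude as the knockout criterion is used symmetrically
  and is configurable.
- TET dependence: `m(DKO, t) − m(WT, t) ≥ dko_min_delta` (default 0.10,
  read inclusively — "at a minimum of 10%").

Methylation is evaluated over the bound region itself, not a containing
tile: the criterion is about the bound site. Regions with fewer than
`min_cpgs = 3` covered CpGs in any required sample are flagged
undetermined and excluded from target counts rather than silently
classified.

## Methylation rates

Per-CpG calls are filtered to autosomes and coverage 10–150× (both
bounds inclusive); the lower bound suppresses sampling noise, the upper
bound removes collapsed-repeat pileups. Replicates of one condition are
pooled by summing read counts before filtering, which roughly doubles
effective coverage and halves region-rate variance. Region and tile
rates are **unweighted** means of per-CpG rates — matching the output
convention of per-CpG callers and keeping a single deep CpG from
dominating a 1 kb tile; tiles are consecutive, non-overlapping, and
reported only where they contain a covered CpG. Deltas live on the
[0, 1] rate scale (10% = 0.10) and are missing whenever either side is.

## Proximity and feature rules

All coordinates are 0-based half-open (BED). "Within 1 kb" is
implemented as expansion of the query by the slack on both sides
followed by a ≥ 1 bp intersection test: overlap, adjacency and edge gaps
strictly smaller than 1000 bp count. Chromosome names match by exact
string comparison — no "chr" harmonization, so mismatched inputs fail
visibly instead of returning empty overlaps.

Active enhancers are p300 regions with H3K27ac within 1 kb and no
H3K27me3 within 1 kb; primed enhancers are H3K4me1 regions with neither
mark within 1 kb. Each target receives a single feature label by
priority (promoter > active_enhancer > primed_enhancer > L1Md > other);
the priority resolves multi-annotation overlaps deterministically and is
configurable. Control regions are 1 kb tiles (uniform length, comparable
to targets) sampled uniformly without replacement from tiles with a
positive WT methylation delta, n = 2,000 by default, seeded.

## Footprint statistic

The footprint score is a bespoke flank-vs-core depletion ratio, a
deliberately simple stand-in with the same directionality as
state-of-the-art footprinters ("footprint up" = deeper core depletion).
Cut counts of all occurrences of a motif (strand-oriented) are summed
into one aggregate profile of length L + 2·flank (flank = 50 bp);

```
score = (mean_flank − mean_core) / (mean_flank + 0.5)
```

A uniform profile scores exactly 0; 50% core protection scores ≈ 0.5.
The 0.5 pseudocount guards against empty flanks at sparse coverage and
perturbs the ratio by < pc/mean_flank, negligible at aggregate counts in
the hundreds. Differential footprints between two conditions compare the
observed score difference against the same statistic recomputed at
`n_shuffles = 100` random same-length window sets placed uniformly
within the same regions (shrunk by the flank so windows stay covered);
z = (Δ − null mean)/null sd. Tn5 +4/−5 offset correction is assumed done
upstream of the cut tracks. Motif scanning reports every position on
either strand with log-odds score ≥ threshold (default 80% of the
maximum achievable score) against a uniform background.

Motif enrichment is region-level (a region either contains ≥ 1
occurrence or not), upper-tail hypergeometric over the
targets-plus-background universe, Benjamini–Hochberg-corrected across
motifs. Sequence-shuffled backgrounds of dedicated motif tools are out
of scope.

## Spike-in normalization

Size factors are DESeq-style median-of-ratios restricted to spike-in
rows. Because per-sample TPM forces every sample to the same total, it
is blind to global repression; the order of operations therefore
matters. For TPM-scale output, counts are first transformed to
reads-per-kilobase rescaled so *endogenous* rows sum to 10⁶ per sample,
spike-in rows carried through on the same scale; factors are then
measured on the TPM-scale spike-in rows and divide the whole matrix.
This equalizes spike-ins across samples (their cross-sample median
ratio becomes 1) and makes a globally repressed sample show a
proportionally lower endogenous mean — computing factors on raw counts
and applying them to TPM would cancel library depth twice and hide the
repression. An exact equivariance note: scaling one sample's counts by
c moves the per-row geometric means by c^(1/S), so individual factors
are equivariant only in ratio form (f_s/f_t gains the full factor c);
tests assert the ratio form.

Repeat-family expression sums spike-normalized, length-normalized
member-consensus values per family, ordered by repeat class. Pathway
values are unweighted mean TPM over de-duplicated member genes, with
pathways below 10 present genes dropped. Contact-based gene assignment
keeps ABC scores inclusively at the recommended 0.02 cutoff and Hi-C
contact probabilities strictly above 15, mirroring how each cutoff is
stated for its source data.

## Accessibility grouping

Peak-level accessibility matrices are grouped by k-means (k = 3 by
default) on log1p-transformed signal, 10 restarts, fixed seed; clusters
are then rank-ordered by mean so label 1 is always the
highest-accessibility group. Clusters with coinciding centroids
(degenerate inputs) collapse into one label. This is the simplest
scheme consistent with a high/medium/low reading; the input matrix is
clustered as supplied, without replicate merging.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not real sequence biology. Defaults are the study conditions used
throughout the tests: 2 chromosomes × 2 Mb, CpGs at ~100 bp mean
spacing, 2,000 candidate regions (1,400 TET1 peaks, 1,000 TET2 peaks,
400 co-bound and emitted identically in both files), 200 planted
targets, planted DKO-only gain 0.25 with WT drift sd 0.02, global gain
0.15 by 72 h applied to both genotypes (so only planted targets separate
them), Poisson(30) coverage, beta-binomial per-CpG rates with
overdispersion ρ = 0.05 (beta concentration (1−ρ)/ρ), two replicates,
timepoints 0/24/72/144 h. Methylation gain ramps linearly to 72 h and
stays flat after. Every candidate carries at least 8 CpGs (planted
evenly if the background spacing yields fewer) and one exact embedded
motif instance at its center.

Feature layout is block-wise with 2 kb guard gaps so the 1 kb proximity
rules cannot leak across classes: active-enhancer sites carry p300 plus
an H3K27ac partner 300 bp away; decoy p300 sites carry overlapping
H3K27me3; primed sites carry isolated H3K4me1. Candidate feature
composition (promoter 12%, active 10%, primed 13%, L1Md 33%, other the
rest) mirrors the composition scale reported for real targets. Cut
tracks cover the first 300 candidate peaks ± 60 bp at Poisson rate
5/base with a multiplicative (1 − 0.5) dip over motif cores in bound
conditions only. Counts are Poisson around lognormal baselines with
per-sample lognormal library factors (sd 0.15), global repression
1.0/0.6/0.4/0.3 across timepoints, constant spike-in expectations
(92 spike-ins, the standard ERCC mix size), and one L1Md family boosted
3× at 24 h in WT — the transient-upregulation signature. All randomness
derives from one master seed through named substreams, making every
output byte-reproducible.

What the simulation does **not** model: realistic sequence composition
and GC/mappability bias, read-level errors, peak-calling noise,
correlated CpG structure, DKO divergence in expression, or multi-mapping
of repeat reads. Passing recovery tests therefore demonstrates the
correctness and calibration of the downstream integration, not the
behavior of upstream callers on real libraries.

## Problem sizes and numerics

The default synthetic dataset (≈ 56,000 CpGs × 16 samples, 2,000
candidates, 600 motif occurrences over 300 covered peaks, 609 count
features) generates in ~2 s and runs through the full pipeline in ~4 s
on one CPU, so the whole validation suite stays interactive. Unit tests
use a further-scaled configuration (120 peaks on 2 × 400 kb). Numeric
choices: k-means is seeded with 10 restarts; the footprint null uses
≥ 10 shuffles (100 by default); hypergeometric p-values come from
scipy's survival function and are exact; report JSON is written with
sorted keys and fixed rounding so reruns are byte-identical.

## Known limitations

- The WT-protection threshold is a design choice (no published value);
  sensitivity to it should be checked on real data via `TargetParams`.
- The footprint score is not bias-corrected (no enzyme sequence-bias
  model) and produces aggregate, not per-site, calls.
- One peak set per factor is accepted as-is; replicate union/intersection
  policy is the caller's responsibility.
- Feature annotation is single-label by priority; multi-label
  composition counting would give different percentages on elements that
  overlap several annotation classes.
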