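# Methods

This note records the statistical models, numerical conventions and design
choices behind `longvar`, and what the synthetic-data tests do and do not
establish about real sequencing data.

## Genotype model

Genotype likelihoods are binomial in the ALT/REF supporting read counts
with a symmetric per-read miscall probability *e* (see README for the
equations). *e* is not identifiable from a single locus and is exposed as a
parameter, default 0.1, restricted to (0, 0.5); the default matches
long-read SV-signature miscall rates and keeps the SQ ≥ 20 filter
meaningful at low depth (two clean ALT reads already reach SQ ≈ 20.3,
three reach ≈ 29.3). All likelihood arithmetic is in log space with a
log-gamma binomial coefficient, so counts in the thousands cannot
underflow; an oracle test checks agreement with arbitrary-precision
rational arithmetic to 1e-9 for all depths ≤ 12. Posterior ties (including
the empty-data case, where the posterior is uniform) call 0/0,
conservative toward reference. GQ and SQ are capped at 99, the usual VCF
convention, when the complementary posterior underflows. The quantity
1 − max posterior is computed from the complementary likelihoods rather
than by subtraction, so GQ stays accurate when the top posterior is close
to 1.

Phased genotypes use a strict majority of ALT-supporting reads across
haplotags — not a per-haplotype posterior — because the simplest
deterministic rule is transparent and the evidence counts are small; ties
and fully unphased support yield no phased call.

The trio de novo filter is deliberately literal: proband ALT depth ≥ 3,
zero parental ALT reads, and ≥ 1 REF-supporting read on *each* parental
haplotype, so that absence in a parent is backed by coverage of both
chromosomes rather than by a coverage gap.

## Evidence extraction

A read supports a DEL/INS candidate when a CIGAR run of the right type
falls within ±100 bp (`window`) of the breakpoints and within ±50%
(`size_tolerance`) of the candidate length; split-read deletions and
DUP/INV supplementary-alignment pairs with the type-appropriate
orientation are also accepted, while lone clipped alignments are
uninformative — conservative, since a singleton clip is compatible with
many rearrangements. Both thresholds are configuration-exposed; no
published values exist for them, and the defaults mirror common long-read
genotyper practice. All alignments of one read are considered together and
count once. Reads with mapq < 1 are ignored, consistent with the TR
genotyping settings. Coordinates are 0-based half-open internally; VCF I/O
converts to 1-based with the padding-base convention for SV records.

TR length deviations are inserted-minus-deleted bases within the region
per spanning read; a haplotype's repeat count is the reference count plus
its mean deviation divided by the motif length. Soft clips outside the
region cannot affect the deviation.

## Call-set merging

Reciprocal overlap requires the overlap to cover ≥ 50% of *each* record's
span (a config switch relaxes this to the smaller span only, since the
convention is not universal). Insertions are compared through
pseudo-intervals extending the anchor by half the insertion length each
way (floor left / ceil right, clamped at 0, guaranteeing nonzero width).
Matching is greedy in coordinate order so transitive chains resolve
deterministically and the result is independent of input order; breakpoints
come from the priority set (the Sniffles2-like caller over the LUMPY-like
one; long-read over short-read). TR exclusion tests each SV against each
single TR region (not the union) at strictly > 50% reciprocal overlap.
Cross-platform rescue relabels a platform-specific record as shared when
re-genotyping on the other platform's evidence returns a non-reference
call, with an optional SQ floor.

## Tandem repeats

Regions within 100 bp merge before 30 bp flanks are added. Z-scores use
the cohort sample SD (ddof = 1); monomorphic regions get Z = 0 everywhere,
so they can never host outliers, rather than dividing by zero.
Missingness filtering is region-first (regions missing in > 25% of
subjects, then subjects missing > 50% of remaining regions); the order
changes the result and is fixed and documented here. A subject is missing
at a region when either haplotype lacks a call. Z-scores are computed on
the filtered table. Burden scores count outlier *regions* per subject, not
haplotypes, and exclude homopolymer motifs, whose genotyping error rates
are elevated. The rarity-based outlier preset uses the fraction of
parental haplotypes with a ≥ 50 bp deviation at the region as the parent
allele frequency.

## Methylation

Long reads near the FMR1 5′ UTR are observed to be essentially fully
methylated or fully unmethylated, so a read is classified by its mean CpG
likelihood with a strict > 0.5 cutoff (configurable; the boundary case is
unmethylated). The skew test is the exact binomial two-sided p-value by
the minimum-likelihood convention (sum of outcomes no more probable than
observed), computed on phased reads only; fully skewed loci give
p = 2^(1−n). Gene-level fractions enter the chromosome-X average only with
≥ 3 reads per haplotype, generalizing the FMR1 inclusion rule, and the
chromosome average is unweighted across genes — weighting by read count is
defensible but couples the profile to coverage. XCI skewness is oriented by
the FMR1 CGG alleles (long-allele haplotype minus short-allele haplotype).
CGG classes: ≤ 25 short, 26–34 intermediate, 35–54 gray-zone, > 54 carried
as above-gray-zone and included in the ≥ 35 grouping. The FMR1 association
models are ordinary statsmodels fits: OLS of haplotype methylation
fraction on XCI and repeat length (with drop-one partial R²) and logistic
regression of case status on repeat length and methylation fraction;
rank-deficient designs raise an error naming the collinear columns.

## Copy number

GC correction divides by a tricube local-regression (lowess) fit of depth
on GC, span 0.3 by default, rescaled to preserve the overall mean; tracks
with < 20 windows or degenerate GC fall back to identity with a warning.
Flanks default to regions of equal total width on each side of the target
separated by a one-window buffer. Per-window CN is 2 × depth / flank mean;
the point estimate and 95% CI are the region-window mean and t interval.
The significance test against diploid is Welch's two-sample t between
region and flank depths rather than a one-sample t of window CNs against
2.0: the flank mean is itself estimated, and its error shifts every window
CN coherently, which makes the one-sample test reject a true null ~11% of
the time at α = 0.05 in simulation, while the two-sample form is
calibrated (5% ± 2% over 1,000 nulls). The mosaic cell fraction of a
one-copy gain or loss is |CN − 2|, clamped to [0, 1].

## Junctions

Microhomology is breakpoint-anchored: the longest k such that the k-mer
anchored at one flank's breakpoint occurs within k + 2 bp of the other
flank's breakpoint, evaluated in both directions of the join appropriate
to the SV type (deletions join left-upstream to right-downstream; tandem
duplications join right-upstream back to left-downstream; inverted joins
reverse-complement the re-entering side). The 2 bp positional slack
absorbs breakpoint placement ambiguity, which in real calls is often a
base or two; without it, one published worked example's 4 bp homology is
missed, and with it no clean join in the packaged examples is overcalled.
Junction reads are decomposed by a scored alignment (+1 match, −3
mismatch, ≥ 15 matched bases per side, ≤ 10 bp anchor offset because a
consumed microhomology copy shifts the junction's re-entry point); the
residual between the matched segments is the inserted sequence, and
insertions ≥ 4 bp found within ±100 bp of either breakpoint (either
strand) are flagged templated. Mechanism classes, in order: NAHR-like
(homology ≥ 20 bp, the upper end of the published 10–20 bp range, or
breakpoints inside segmental duplications), MMEJ-like (2–20 bp homology,
no insertion), NHEJ-templated (templated insertion ≥ 4 bp; exactly 4 bp is
flagged low-confidence since so short a match recurs by chance), NHEJ-clean
(blunt), else unclassified. The packaged worked-example sequences from
three characterized DUP-DEL rearrangements reproduce their published
signatures (2 bp GC, 7 bp templated CTTACAC, 4 bp ATTT + CCCC).

## Burden association

Conditional logistic regression is fitted with statsmodels'
`ConditionalLogit` (exact within-stratum conditional likelihood);
phenotype-concordant families contribute nothing and are dropped, and the
covariate-free null log-likelihood has the closed form Σ −log C(nᵢ, kᵢ)
over informative strata. On 1:1 matched pairs the fit equals the
closed-form discordant-pair odds-ratio estimator, which the tests use as
an independent oracle. The burden term's p-value is a likelihood-ratio
chi-square; pseudo-R² follows the Cox–Snell and Nagelkerke formulas
exactly. Bootstrap CIs resample whole families with replacement
(relabelled so repeats stay distinct strata) and take percentile bounds;
resamples with degenerate outcome patterns are skipped. Platform
meta-analysis defaults to fixed-effect inverse-variance weighting, with a
sample-size-weighted z alternative. Burden scores count rare
(parental AF < 0.05), high-quality (SQ > 20) SVs intersecting a category's
intervals, excluding calls whose two breakpoints fall inside the two
halves of a paired segmental duplication (likely mapping artifacts);
designated karyotype events can be added per subject and category.

## Synthetic data

The generators emulate the *structure* of the real inputs — phased read
support, toy trio alignments with planted CIGAR signatures, cohort TR
deviation tables, near-saturated per-read CpG likelihoods, windowed
coverage, matched family cohorts — under a single master seed fanned out
into counter-based streams, so every fixture is bitwise-reproducible.
Two modelling choices matter:

* Read support splits coverage evenly across haplotypes (depth//2 each,
  odd read randomized) with per-read ALT probability e or 1 − e per
  haplotype. Homozygous genotypes remain exactly Binomial(depth, q); the
  heterozygous ALT count is the sum of two binomials concentrated at ½,
  which is what balanced phased coverage produces. Had haplotypes been
  resampled per read (marginal Binomial(depth, ½)), ~11% of depth-10 het
  draws would cross the hom-alt decision boundary and genotype recovery
  would cap near 96%; with balanced coverage it is ≈ 99.2%.
* Window depth is Poisson-distributed *aggregate* coverage —
  Poisson(depth × width)/width, the mean-per-bp quantity a depth profiler
  reports — not a single Poisson(depth) draw per window, so 500-bp windows
  at 30× have the small variance real window means have (ignoring
  read-length autocorrelation, which widens it somewhat).

What the generators do not model: sequencing-error profiles, mapping
ambiguity, reference bias, GC-coverage interactions beyond a linear bias,
read-length autocorrelation of coverage, TR genotyping error structure, or
population structure in the cohort tables. Passing tests therefore
establish correctness of the statistical machinery and of signature
parsing under clean inputs, not robustness to alignment artifacts.

## Problem sizes and determinism

Simulation-based tests use desk-scale sizes chosen to make Monte-Carlo
error small relative to the tested tolerance: 10,000 variants for genotype
recovery, 100 replicate tracks (55 region windows each) for mosaic CN,
1,000 null replicates of 200 families for LRT calibration, 1,000 random
interval pairs for the merge oracle. All randomness flows from fixed seeds
or the acceptance script's `--seed`; property-based tests (hypothesis) are
derandomized by the fixed seeds in their strategies' ranges.

## Known limitations

* The genotype model is biallelic with a symmetric error rate; somatic
  fractions are handled descriptively through copy number, not in the
  genotype posterior.
* INV/DUP evidence requires supplementary-alignment pairs; singleton
  clipped reads never count, which loses sensitivity at low depth.
* The junction aligner assumes a single switch point (one insertion); more
  complex multi-segment junctions come back unclassified or unalignable.
* The lowess GC correction span and the flank widths are heuristics; on
  real tracks they should be tuned against a diploid baseline.
* Conditional-logistic separation (common with sparse burdens) is flagged
  with a warning rather than penalized; use the bootstrap CI, not the Wald
  SE, in that regime.
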