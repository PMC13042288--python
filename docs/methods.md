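# Methods

This note documents the models, conventions and design choices behind
`malines`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and record contracts

Internal coordinates are 0-based half-open everywhere except
`VariantRecord.position`, which stays 1-based to mirror VCF; the only
crossing point is `records.point_to_interval` / `interval_to_point`.
Mixed-convention bugs are the dominant failure mode in this kind of
pipeline, so the conversion is a single audited function.

Multiallelic VCF rows are split into one record per ALT; per-allele support
comes from that allele's AD entry and site-level annotations are copied to
every child, because filtering is per variant, not per site. A missing
annotation is kept absent (never imputed as zero): it fails closed in
variant mode, and in non-variant (callable-site) mode its handling is the
`strict_callable` flag (default true = fail closed), since how
missing-annotation sites enter callable-site counts is genuinely
under-determined for GATK-style inputs.

The VCF writer formats floats at six significant digits and the reader
canonicalizes to the same precision, so write→read→write is byte-stable.

## Filter stack

All thresholds are inclusive as written: alt reads ≥ 10 (variant mode only),
MQ ≥ 50, QD ≥ 2, FS ≤ 60, SOR ≤ 3, |MQRankSum| ≤ 8, |ReadPosRankSum| ≤ 4,
and depth within [0.5, 2] × the line's chromosome-wide median depth. The
depth window applies in both variant and non-variant modes, making variant
mode strictly stricter (a property test asserts this). Rejection logs
always record the *first* failed rule in a fixed canonical order, which is
what makes artifact bookkeeping auditable.

Median chromosome-wide depth is defined per (line, contig) over sites with
nonzero depth, lower median on ties.

## Callable-site accounting

A site is callable iff it is outside the repeat mask and no line fails the
non-variant stack there. Accounting partitions the genome exactly:
`total = repeat_masked + filter_failed + callable`, with `filter_failed`
counting only non-masked sites. Per-line failures enter as sparse interval
tracks (all unlisted sites pass); a helper converts explicit per-site
statistic tables into such tracks so the same rules drive both forms.
Callable G/C counts use the reference base, not line consensus.

Coverage-based aneuploidy screening flags a contig when its mean depth is
≥ 1.4× the line's autosomal median — between disomy (1.0) and the 1.5
expected for a trisomy; the threshold is configurable because it is a
screening heuristic, not an estimator.

## Event definitions and clustering

Line-unique candidates are clustered per (line, contig) by single-linkage on
consecutive gaps ≤ 1 kb (inclusive). Chains of one variant are SNV/INDEL
events; larger chains are MNV (all SNVs) or COMPLEX (≥ 1 indel), one event
per chain. Single linkage is the only order-independent,
partition-consistent reading of "two or more variants within 1 kb", but a
chain can then span more than 1 kb end-to-end; a `linkage="span"` variant
that also caps the end-to-end span is provided for sensitivity analyses.
The SV/TE proximity exclusion is likewise inclusive at exactly 1,000 bp and
uses TE insertions only by default (excisions via a flag).

SV calls survive when unique to one line, genotyped across their block
(block partition configurable; default treats the panel as one block, since
blocking in practice is operational rather than methodological), supported
by ≥ 10 spanning **or** ≥ 10 split reads, and at the dialect's maximum
quality score.

Zygosity: homozygous iff every member is hom-alt, heterozygous iff every
member is het, otherwise mixed.

## Rates and comparison statistics

Rates are ratios of pooled counts to pooled opportunity. Per-site
opportunity is callable sites × *adjusted* generations per line; the
generation adjustment (accounting for extra transmitted genome copies under
sib-mating) is an input per line, defaulting to the nominal count — it
scales absolute rates but cancels in group contrasts. TE rates use nominal
generations (per-genome scope).

CIs are percentile bootstraps over lines (10,000 replicates, seeded), the
design's natural resampling unit; a Poisson-exact alternative is available,
and a zero count yields a one-sided Poisson upper bound. In very small
panels a percentile interval can exclude the pooled point estimate, so the
interval is clamped to bracket it.

The rate table's "absolute group difference" is `100·|r₊ − r₋| / mean(r₊,
r₋)`: this is the unique simple formula consistent with all seven published
rows, verified to two decimals in the tests. The repair-tract fold-excess
model assumes the whole group rate gap is confined to `n_DSB × L` bp of
repair synthesis per genome per generation:

    fold = 1 + (r₊ − r₋) · G / (n_DSB · L · r₋)

with defaults n_DSB = 24, L = 5,000 bp, G = callable-site total. On rounded
published rates this yields 8.12; the published 6.7 came from unrounded
estimates, so the implementation reports the formula and its inputs rather
than asserting a value.

The CV comparison is a label-permutation test on |CV₁ − CV₂| (add-one
corrected); Levene uses median centring; the goodness-of-fit chi-square
takes expectation weights (callable sites per arm, or raw contig lengths for
the TE X-enrichment binomial).

## TE reconciliation

Merging is single-linkage over sorted breakpoints per (family, contig,
type), inclusive at 50 bp, order-invariant and idempotent; the
representative breakpoint is the lower median of members. De novo = exactly
one carrier; multi-carrier events are logged as segregating-or-recurrent.
Apparent excisions are indistinguishable from deletions spanning the TE, and
events carry that caveat. The family-independence test compares the
per-line count of active families to Poisson via a binned chi-square whose
p-value is a parametric bootstrap (counts redrawn at the sample mean, the
statistic recomputed with each simulated sample's own mean, add-one
corrected).

## Window regressions

Continuous covariates are projected by overlap-weighted averaging (missing
when a window has no overlap); windows missing recombination or timing, or
with zero callable sites, are excluded and logged. G/C content and
recombination are scaled by their means (the scaling is recorded in the fit
metadata); chromatin state enters as indicators against BK, the largest
class. Power (callable sites × lines) is a log offset by default — the
exposure interpretation — with a linear-predictor variant by flag; outputs
name which was used.

Fixed-effect fits are nbinom2 maximum likelihood (statsmodels, BFGS from a
Poisson start, gtol 1e-7); θ is estimated jointly, or can be fixed (the fit
then reduces to a negative-binomial GLM, and with θ → ∞ reproduces Poisson
coefficients, both asserted in tests). The treatment-interaction model
stacks two rows per window (one per group, power apportioned by group size),
adds treatment main and interaction terms and a per-window Gaussian random
intercept, and maximizes the exact marginal likelihood by Gauss–Hermite
quadrature (15 nodes by default; 1 node = Laplace-at-zero) with an analytic
gradient and observed-information standard errors. With two observations
per group the integral factorizes per window, so quadrature is exact enough
that no Laplace approximation error enters at the variances involved.
Likelihood-ratio tests drop all interactions jointly or one at a time.

## The synthetic generator

Defaults are the study conditions: 16 + 19 lines, 30 generations, five 1 Mb
contigs (a ~40× miniature of the real genome, keeping runtimes in seconds),
per-site rates at the published point estimates (SNV 5.85e-9, INDEL
1.71e-9, MNV 5e-10, COMPLEX 6e-10, SV 2.2e-10 per site per generation),
group-specific TE rates (insertion 0.482 / 0.681, excision 0.119 / 0.136
per genome per generation), homozygous fractions 0.55 (autosomes) / 0.70
(X), mean depth 99, ~15% repeat-masked and ~11% filter-failed genome
(≈74% callable), and G/C fraction 0.43 drifting in 10 kb blocks (sd 0.07)
so window composition varies as in real genomes.

Event counts are Poisson with mean rate × callable sites × generations per
line (TE: rate × generations). Planted features reserve spaced positions
(3 kb margin; 1.2 kb for TE events) so clustering and proximity exclusion
act only where truth says they should; artifacts deliberately violate
exactly one rule each (e.g. QD 1.5, MQ 45, depth 2.5× median, alt reads 5,
a shared call, a missing genotype, a variant 200–900 bp from an SV or TE).
TE breakpoints jitter uniformly within ±20 bp across carriers — inside the
50 bp merge window — and a configurable fraction jitters 60–150 bp to
create deliberate merge failures. Depths are negative binomial around the
line median (clipped into the passing window), AD binomial given zygosity.
Per-window counts are drawn from the nbinom2 model (θ = 2) at known
coefficients, optionally with a per-window random intercept and treatment
interactions for the mixed-model tests. Everything derives from one seed;
two runs are byte-identical.

What the generator does **not** emulate: reads or alignments, reference
sequence (G/C identity is a seeded mask; no FASTA), caller-specific output
quirks, mapping artifacts correlated across nearby sites, selection during
MA, or linkage between planted events. Passing oracle tests therefore
demonstrates the correctness of the filtering/accounting/estimation
machinery under its stated assumptions — not the error profile of any
particular upstream caller on real reads.

## Numerical choices and degenerate inputs

Ties in medians resolve to the lower median. Bootstraps and Monte-Carlo
p-values are seeded and reported with their replicate counts; Monte-Carlo
p-values are add-one corrected, never zero. `group_difference_percent` is
undefined (reported missing) when both rates are zero;
`relative_increase_percent` requires a positive reference; the tract model
refuses an inverted rate ordering. Non-converged regression fits are
returned flagged, never silently replaced. Likelihood-ratio statistics are
floored at zero and a zero-df comparison returns p = 1.

## Known limitations

- Non-variant-site filter evaluations are consumed as sparse failure tracks
  (or per-site tables), not recomputed from alignments (gVCF support is out
  of scope).
- The nonsynonymous null (0.744) and consequence labels are inputs, not
  computed; no codon-level annotation is performed.
- The windowed analysis assigns multi-variant events by their start
  position, and window definitions are inputs (or synthetic) — the package
  does not rebuild published window sets from external chromatin datasets.
- The mixed model supports a single Gaussian random intercept (window
  identity); crossed or nested random effects are not implemented.
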