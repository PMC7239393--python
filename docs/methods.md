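# Methods

## The locus and the data model

The *St* locus sits on a Z-linked scaffold (ScoHet5_227).  Birds are
ZW (female) / ZZ (male), so the baseline copy number of any Z-linked
sequence is 1 in females and 2 in males; every copy-number statement in the
package is explicit about this baseline.  The canonical Almond allele is a
nested tandem expansion: an outer 77,790 bp segment
(ScoHet5_227:5,181,467–5,259,256) present in 7 copies per affected
chromosome, containing an inner 25,545 bp segment
(5,201,091–5,226,635) present in 14.  Kilobase labels are reported as
floor(length/1000), which reproduces the conventional "77-kb"/"25-kb"
labels from the printed coordinates.  All coordinates are 1-based
inclusive; BED is converted at the boundary.

## Differentiation scan

Per site the package compares cohort alternate-allele counts (a₁, n₁) and
(a₂, n₂) with a two-binomial likelihood-ratio test: G is twice the
difference between the log-likelihood at the per-cohort MLEs and at the
pooled MLE, with 0·log 0 ≡ 0, and p is the upper χ²₁ tail.  Published
scans of this design use genotype likelihoods; this implementation uses
hard allele counts (rounding ploidy × AD/DP per sample) because that makes
the statistic fully specified and oracle-checkable.  The genome-wide
threshold is Bonferroni over tested sites.  Multiallelic sites reduce to
reference vs the read-richest alternate; a site with an all-missing cohort
is dropped with a log message.

**Calibration caveat.**  χ²₁ p-values from counts are asymptotic.  With
very few case alleles (e.g., 12 hemizygous females) the statistic's support
is so discrete that null p-values are visibly non-uniform; this is a
property of any count-based LRT at that sample size, not of the
implementation.  The calibration test therefore draws a null cohort in the
asymptotic regime (151 case / 200 control alleles, coprime totals so that
exact frequency ties — which put an atom at p = 1 — are negligible) and
checks Kolmogorov–Smirnov uniformity over 10,000 sites.  Scans of
study-sized cohorts remain valid for ranking and localization, which is
how they are used.

## Read-depth copy number

Depth tracks are per-window means over tiling windows (default 100 bp;
the windowing granularity is a package choice).  Tracks are normalized by
the median depth over a control interval with no coverage gain (default:
scaffold start up to well before the CNV, mirroring the 1–5 Mb convention
on the real scaffold); normalization is idempotent and leaves the control
median exactly 1.  Integer copy number over an interval is
round(median normalized depth × sex baseline); the median is robust to the
repeat-element depth spike inside the region, and windows overlapping an
explicit exclusion mask can additionally be dropped.  For a heterozygous
male the per-chromosome assignment of the total is not identifiable from
depth alone; the package reports the total plus the even per-chromosome
split, and call assembly attributes the expansion to a single affected
chromosome (total − baseline + 1), which is the configuration of every
carrier the allelic series describes.

Segmentation is greedy binary changepoint splitting: the candidate split
minimizes the within-side sum of squares (least-squares binary
segmentation, which pins step edges exactly on noiseless tracks) and is
accepted when the medians of up to 50 windows flanking it differ by at
least 0.5 copies; both sides must keep ≥ 10 windows, and adjacent segments
closer than the threshold are merged back.  A pure median-based split
criterion was rejected during design: when the CNV occupies a minority of
the scaffold, the two halves of any split have identical medians and the
recursion cannot start.

Breakpoints are positions where ≥ 3 reads clip (the original analysis used
manual inspection of split reads; the threshold and the 5 bp merge radius
make it automatic), clusters keeping their max-count position.  Call
assembly pairs elevated depth segments with breakpoints: segment edges snap
to a breakpoint within 2 windows, and an edge with no breakpoint within 10
windows flags the call `depth-only`.  Inner/outer levels are length-weighted
medians of segment levels with a two-pass regrouping (re-cut at the midpoint
of the inner and outer levels) so spurious sub-splits inside the inner
region cannot bias its extent or copy number.  A single elevated level
yields an `inner-only` call with outer CN 1 — the configuration seen in
rare non-carrier birds with only the inner duplication.

## Tandem structure and gene effects

With outer multiplicity o and inner count i, the structure model is the
uniform arrangement [S1 (S2 × r) S3] × o with r = i/o; i not divisible by
o is rejected with the nearest divisible alternatives suggested, because
the inferred structure implies uniform repeat units and guessing a
non-uniform arrangement from depth alone is not defensible.  Junction
counts are obtained by enumerating adjacencies of the arrangement string —
1/2 = o, 2/2 = o(r−1), 2/3 = o, 3/1 = o−1 — and tests verify the
enumeration against these closed forms for all o ≤ 10, r ≤ 4.  Gene
effects follow from placement: inside S2 → amplified to i copies; inside
S1/S3 → amplified to o; spanning an inner boundary → one full copy per 2/3
junction plus one truncated copy per 2/2 junction; spanning an outer edge →
fusion partner with one fused copy per 3/1 junction (o−1 of them).  Note
the uniform arrangement yields o full copies of an inner-boundary-spanning
gene (seven at o = 7); the package reports the enumeration result.

## Paralog-aware variant scan

Retention keeps any (site, alternate allele, sample) with AD/DP strictly
greater than 4% — the threshold that admits a variant on 1 of 14 copies
(≈7.1%) while excluding sequencing errors — evaluated for every alternate
allele (the filter is stated over the first alternate in the original
command line but over any allele in prose; the package follows the prose).
Retained sites are routed by allele count: biallelic sites return alleles
with nonzero retained frequency in cases and zero in controls; multiallelic
sites are scored by presence (≥ 1 read, no fraction threshold — an
intentional asymmetry with the retention filter) summed across case birds,
with ≥ 3 carriers making a candidate.  Presence coding operates on the
retained allele set, i.e. on the filtered file, which is what makes the
error-only null come back empty.  Finally every candidate is checked in the
controls, where a single supporting read disqualifies it.  Missing samples
count as absent.

## Dosage statistics

Copy-number plates: per sample ΔCt = mean Ct(target) − mean Ct(reference);
ΔΔCt vs a designated calibrator with known copies c₀ (a wild-type bird: 1
copy for females, 2 for males, with the reference probe at 2 autosomal
copies); continuous CN = c₀·2^(−ΔΔCt), integer by rounding.  Association
uses the two-sided Wilcoxon rank-sum on all phenotype pairs.  The exact
path computes the permutation distribution of the rank sum by subset-sum
dynamic programming over doubled midranks — exact under ties, feasible
where direct enumeration (C(50,25) ≈ 10¹⁴) is not — and is used when both
groups have ≤ 25 samples; larger groups use the normal approximation with
tie and continuity corrections.  Bonferroni is applied two ways, over all
pairs and over baseline-vs-other pairs only, since either denominator is a
defensible reading of "pairwise with correction"; both columns are
reported.  Expression: ΔCt per sample and gene, fold change
2^(−(ΔCt − mean ΔCt of the baseline group)), one-way ANOVA and Tukey HSD
computed on ΔCt (log₂ scale, where variance is closest to homogeneous),
and a compact letter display assigned by insert–absorb so groups share a
letter iff not significantly different at 0.05.  Groups with fewer than
two samples are excluded from the ANOVA with a warning (a single
homozygote group is handled this way).

## Synthetic cohort generator

The generator defines the study conditions every test runs under.  One
400 kb Z-linked scaffold hosts the CNV at the published coordinates shifted
left by 5 Mb, preserving printed segment lengths and breakpoint spacing.
Defaults: 30× haploid-baseline coverage with Poisson window counts
(λ = coverage × local copies / sex baseline; a noiseless mode returns the
expectation for closed-form tests), per-base error rate 0.5%, cohort of 12
Almond females vs 109 non-Almond birds, TaqMan plates in quadruplicate
(sd 0.15 Ct), qRT-PCR in duplicate (sd 0.25 Ct) normalized to a β-actin-like
reference, and a 40-fold expression effect template for the carrier groups.
Coverage and error rate are configuration, not claims — no sequencing
summary statistics for the original panel are published.  Per-chromosome
(outer, inner) copies for non-Almond series members (Qualmond/Faded/Frosty
(2,4), Chalky (3,6), Sandy (5,10), White Out (6,12)) are generator settings
chosen to reproduce the qualitative allelic-series gradation; only Almond's
(7,14) is an established value.  Clip piles appear at the four junction
coordinates with Poisson counts proportional to coverage × junction copies
(o−1 outer, i−o inner junctions per chromosome) plus sporadic 1-read
background clips.  Copy-private SNVs are shared across carriers — the
scenario the scan hunts for — at expected fraction
(expanded chromosomes)/(total inner copies), with DP scaling with local
copy number; at planted sites, control-sample error reads avoid the planted
base so "absent from controls" is true by construction, while carrier and
background-site errors land on any non-reference base.  Genotypes for the
scan draw background sites from a shared Uniform(0.05, 0.95) frequency and
causal-region sites from divergent cohort frequencies (default 1.0 vs 0.0).
All randomness flows through one explicitly passed numpy Generator; a fixed
seed gives bit-identical output.

What the generator does **not** emulate: alignment artifacts, GC and
mappability bias, overdispersed coverage (an optional factor exists but the
default is pure Poisson), linkage disequilibrium between sites, W-chromosome
repeat pileups, systematic (non-uniform) sequencing error, and plate or
batch effects in Ct measurements.  Passing tests therefore demonstrate the
statistical machinery under the assumed noise models, not robustness to
real-data artifacts.

## Problem sizes and numerical notes

Tests and the acceptance script run the depth pipeline on 4,000 windows
(400 kb at 100 bp), 100 seeded replicates for recovery rates, 10,000 sites
for the null-calibration check, and 100 replicates of the paralog scan on a
24-bird cohort with 55 sites — sizes chosen so the full suite completes in
well under a minute while keeping every Monte-Carlo tolerance at ≥ 3
standard errors.  Ties in scan ranking break by scaffold order then
position; G is clamped at 0 (identical sample frequencies return exactly
G = 0, p = 1); p-values are floored at the smallest positive double;
rank-sum two-sided p is twice the smaller tail, capped at 1.

## Known limitations

- Hard-call allele counting discards genotype uncertainty; the scan is a
  count-based approximation to likelihood-based differentiation statistics.
- Heterozygous-male copy numbers are attributed to one affected chromosome;
  a homozygous male's depth is indistinguishable from a heterozygote with
  double the expansion without assay or pedigree information.
- Structure inference assumes uniform repeat units; real alleles with
  non-uniform arrangements are rejected rather than guessed.
- The paralog scan cannot assign a variant to a specific repeat unit, and
  phasing of copies is out of scope.
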