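# Methods notes

This note records the statistical model, the numerical conventions, and the
design decisions behind `snpmeta`, in the spirit of the methods sections of
the classical meta-analysis packages.

## Data model and assumptions

A *study* contributes genotype counts (GG, GA, AA) for a case arm and a
control arm of one biallelic SNP, with G the minor allele, plus the
stratification metadata used in subgroup analysis: ethnicity (closed
vocabulary: European, Asian, African, SouthAmerican), control source
(hospital- vs population-based), Newcastle–Ottawa quality score (0–9 stars;
≥ 7 counts as *high* quality), and genotyping method. A study is *large*
when cases + controls ≥ 1000. Both cutoffs are the conventional ones for
this literature and are fixed constants in `snpmeta.studies`.

The analysis assumes studies are independent case–control samples of the
same underlying association, possibly with between-study variation in the
true log odds ratio (random-effects view). No covariate adjustment is
attempted: the inputs are marginal genotype counts, so every estimate is an
unadjusted odds ratio.

## Genetic-model contrasts

Each contrast maps the genotype counts of both arms to one 2×2 table with
the G-bearing category as exposure. The allelic contrast counts *alleles*
(each individual contributes two, treated as independent observations — the
convention of the source literature; no within-individual correlation
adjustment). Homozygote and heterozygote contrasts drop the excluded
genotype from both arms, shrinking the totals. Zero cells are handled by
the Haldane–Anscombe correction: +0.5 to all four cells, applied *only*
when some cell is zero (never "always-add"), so datasets without empty
cells — including the bundled one — are untouched. A table with an empty
exposure margin has no odds ratio and is rejected.

## Hardy–Weinberg screening

Default: Pearson chi-square with 1 df, expected counts n·q², 2n·q(1−q),
n·(1−q)² at the observed minor-allele frequency q, no continuity
correction. This choice reproduces the per-arm p-values printed with the
bundled dataset (e.g. Qu controls 0.993, Ebrahimi cases 0.276, Marchal
cases 0.391). A conditional exact test (Wigginton-style enumeration of
heterozygote counts given the allele margin) is provided for sparse arms
but is not the default. Monomorphic arms are flagged degenerate (χ² = 0,
p = 1) rather than errored. The asymptotic caveat: at moderate n the
chi-square p-distribution under the null is only approximately uniform; the
test suite verifies approximate uniformity at n = 500 by Kolmogorov–Smirnov.

## Pooling

Per-study effects are Woolf: ln(OR) = ln(ad/bc), var = 1/a+1/b+1/c+1/d.
The 95% normal critical value is fixed at 1.959964 everywhere.

**Heterogeneity.** Cochran's Q uses inverse-variance weights. In the
2×2-table pipeline Q is centred on the *Mantel–Haenszel* pooled log-OR
rather than the inverse-variance mean. The two agree to several decimals on
realistic data, but the MH-centred version is what the classical
count-data meta-analysis software reports, and it is the variant that
reproduces the published heterogeneity cells of the bundled dataset to
their printed rounding. `cochran_q` keeps the IV-centred textbook default
for effect-only input; callers can pass any centre.
I² = max(0, 100·(Q−(k−1))/Q).

**Gate.** Fixed-effect Mantel–Haenszel when the Q-test p-value is strictly
greater than 0.05 (configurable `het_alpha`); otherwise DerSimonian–Laird.
A p-value exactly at the gate routes to random effects. The gate is
re-evaluated inside every stratum and every leave-one-out subset, because
heterogeneity is a property of the subset being pooled. One published cell
of the bundled dataset sits numerically at the boundary (heterogeneity
p = 0.0501, printed 0.050): the strict gate pools it fixed, while the
source's own table shows the random-effects branch; the replication test
accepts either branch for that cell and the discrepancy is documented, not
forced.

**Mantel–Haenszel.** OR_MH = Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) with the
Robins–Breslow–Greenland variance for ln(OR_MH) — consistent under both
sparse-strata and large-stratum asymptotics, and collapsing exactly to the
Woolf variance at k = 1, so a single-study "pool" is the study's own
estimate. Verified against R's `metafor::rma.mh` to 9+ significant digits.

**DerSimonian–Laird.** τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)); re-weighted
mean with SE (Σw*)^(−1/2). When Q ≤ k−1 the estimator truncates to zero
and DL coincides with inverse-variance fixed pooling (asserted as a test
invariant; also cross-checked against `statsmodels.stats.meta_analysis`).
REML/Paule–Mandel estimators and the Hartung–Knapp adjustment are out of
scope; the normal (not t) reference is used for the pooled Z-test,
matching 2009-era practice of the field's standard software.

**Rounding** happens only at the reporting layer (OR/CI 2 dp, p 3 dp,
I² 1 dp); all internal arithmetic and the JSON manifest are full precision.

## Publication bias

Egger: OLS of the standardized effect ln(OR)/SE on precision 1/SE;
t = intercept/SE(intercept) with k−2 df, two-sided t-tail p. Per-model
effects come from the (continuity-corrected, where needed) tables of the
model being tested. Begg: effects centred on the fixed IV mean and
standardized by sqrt(vᵢ − 1/Σ(1/vⱼ)); tie-corrected Kendall τ_b against
the variances, normal approximation z = τ/sqrt(2(2k+5)/(9k(k−1))) without
continuity correction — conventional defaults, scale-invariant in the
variances. Small-k caveat: Egger's test is known to be slightly liberal at
k ≈ 15; the suite checks its null rejection rate stays within [0.02, 0.10].
Funnel plots use pseudo-95% bounds around the fixed IV centre. No
trim-and-fill.

## The bundled dataset and its known print defects

The 15-study rs1805087/prostate-cancer table ships as a package CSV with
transcription notes. Resolution rule for ambiguous digit runs in the
source: genotypes must sum to the published per-arm n *and* the published
per-arm Hardy–Weinberg p must reproduce (this fixes the Marchal case row
to 9/54/118). Verified totals: 10,666 cases / 40,750 controls; all
published stratum denominators reproduce exactly. The source prints "9
large studies" in its text but its own table lists 6 (which the
denominators confirm); the fixture follows the table.

Defects found during replication and left visible (see
`tests/_published.py`):

- one control-arm HWE p (Eeles) prints 0.079 but computes 0.213
  (Pearson) / 0.217 (exact) from the printed counts — no test reproduces
  it;
- two stratified-grid cells print the Z-test p and heterogeneity p in each
  other's columns (both digit pairs reproduce, swapped);
- of the five published Egger t statistics, only the heterozygote-model
  value (t = 2.03, p = 0.064) follows from the printed data; the other
  four (all in a narrow 1.92–2.06 band) could not be reproduced by the
  standard Egger test or by any common variant examined (always-corrected
  tables, Harbord, Peters, weighted forms, OR-scale regression,
  leave-one-out subsets). The package reports its computed values.

## Synthetic-data generator

`simulate_meta` draws control genotypes multinomially from exact
Hardy–Weinberg proportions at frequency q, and case genotypes from the
genotype-tilted multinomial with weights proportional to the HWE
probabilities times OR^g for g minor-allele copies — the retrospective
sampling law under a log-additive per-allele effect. This keeps controls
exactly in equilibrium (in expectation) while letting case arms deviate,
as real case–control data do. Study-level true log-ORs are
Normal(ln OR, τ²). Optional small-study bias: a drawn study with total n
below the median of the configured sizes and allelic Z < 1 is redrawn with
probability `bias_strength` — a simple censoring mechanism that hollows
out the lower-left of the funnel.

Defaults (chosen once as field-realistic and fixed): k = 15 studies and
per-study sizes resampled from the bundled dataset's observed sizes
(mirroring the replication's scale), q = 0.2 (the European/global minor
allele frequency of rs1805087 is ≈ 0.20–0.21), per-allele OR 1.2 (a
typical detectable SNP effect), τ = 0 and no bias unless requested. One
seeded `numpy` Generator stream per `simulate_meta` call; the seed fully
determines the dataset.

What the generator does *not* emulate: covariates, population
stratification or admixture, genotyping error, and any real-data
correlation between study size and design quality. Passing calibration
tests therefore validate the estimators under the model's own assumptions,
not robustness to those violations.

Calibration checks in the suite (sizes chosen to keep the default run
fast while leaving Monte-Carlo error well below the asserted margins):
control arms reject the HWE screen at the nominal 5% (1000 replicates,
±3.3 SD binomial band); pooled log-OR recovery bias < 0.02 at k = 20,
n = 2000/arm, OR ∈ {1.0, 1.2, 1.5} (2000 replicates each); type-I error
of the gated pooled Z-test within [0.035, 0.065] (1000 replicates of
k = 15 at the bundled size distribution); I² increasing in τ over
{0, 0.1, 0.3}; and Egger rejecting more often under injected funnel bias
than without (200 paired replicates).

## Degenerate inputs and tie-breaks

- Monomorphic arm → degenerate HWE result, not an exception.
- Zero cell → continuity correction; empty exposure margin → error.
- k = 1 → study-level estimate; heterogeneity fields are `None` and render
  as "–".
- Q = 0 → I² = 0 (not NaN); τ² truncation at 0.
- Heterogeneity p exactly equal to the gate → random effects.
- Empty stratum → omitted from the grid, not an error.

## Known limitations

No meta-regression, cumulative meta-analysis, Peto or exact conditional MH
methods, trim-and-fill, or X-linked/multi-allelic HWE. The allelic model's
independent-alleles assumption slightly understates variance when
genotypes deviate from HWE. The Begg z uses the large-k normal
approximation, optimistic below k ≈ 10.
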