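# Methods

This note records the statistical conventions the package implements, the
choices made where more than one convention is defensible, and what the
synthetic-data generator does and does not emulate.

## Data model

A study is a pair of genotype-count triples (CC, CT, TT) for cases and
controls at one biallelic SNP, with stratification metadata.  The mutant
allele (C for both embedded SNPs) is always listed first, which orients
every odds ratio: OR < 1 means the mutant allele or genotype is
protective.  Study ids must be unique within an analysis set; where one
publication contributes several case subsets against a shared control
group (disease-subtype strata), each subset is its own record and the id
carries the stratum.  The embedded collection keeps the total-AMD pool
(12 studies) and the disease-subtype pool (11 strata) as separate tables
because they reuse the same control groups with different case subsets.

## Effect estimation

Per-study effects are Woolf log odds ratios with
SE = sqrt(1/a + 1/b + 1/c + 1/d).  The Haldane–Anscombe correction adds
0.5 to all four cells, and only when at least one cell is zero — an
unconditional correction would perturb studies that need none (the
embedded tables contain no zero cells, so their effects are exact).  A
table with an empty row or column has no finite effect and is rejected
rather than patched.

The heterozygote and homozygote models are conditional contrasts: the
excluded genotype is dropped from the table entirely, which is what the
pairwise labels "CT vs. TT" and "CC vs. TT" mean in the field's standard
tables.

## Heterogeneity and pooling

Cochran's Q uses fixed inverse-variance weights; its p-value comes from
χ²(k−1).  τ² is the DerSimonian–Laird moment estimator truncated at zero,
so τ² = 0 whenever Q ≤ df, and the random-effects estimate then collapses
to inverse-variance fixed pooling by construction.

Fixed-effect pooling is Mantel–Haenszel on the raw count tables (not
inverse-variance on log ORs): MH is the canonical fixed estimator for
sparse-to-moderate 2×2 strata and is robust to small cells without
continuity correction.  Its log-OR variance is the
Robins–Breslow–Greenland estimator.  Random-effects pooling is
DerSimonian–Laird inverse-variance on log ORs.  Significance of the pooled
effect is the two-sided Z test on the log scale, with 95% Wald intervals.

The effect-model choice follows the conventional screen: fixed effects
when the Q-test p-value exceeds 0.10, random effects otherwise.  The rule
is applied independently to every stratum × genetic-model cell using that
cell's own Q test, because subgroup heterogeneity routinely differs from
the whole-set heterogeneity.  The threshold is a plan parameter
(`q_threshold`, default 0.10).

## Publication-bias tests

Egger's test is the unweighted OLS regression of the standard normal
deviate (log OR/SE) on precision (1/SE); the intercept estimates
small-study asymmetry and is referred to t with k−2 df, with a t-based 95%
CI.  This is the convention of Stata's `metabias`, and it exactly
reproduces the internally consistent rows of the embedded collection's
published bias table (the 3-study set's intercept 1.247, SE 1.837,
t = 0.68 with its df = 1 CI, and the 12-study recessive row −0.577,
SE 1.243, t = −0.46).  The test requires k ≥ 3 and distinct precisions.

Begg's test standardizes deviations from the inverse-variance pooled mean
with v_i* = SE_i² − (Σ 1/SE_j²)⁻¹, computes the Kendall score S against
the variances over all pairs, and refers z = (|S| − adj)/sqrt(k(k−1)(2k+5)/18)
to the standard normal.  The package reports the uncorrected statistic
(adj = 0) by default — the variant that reproduces the published 3-study
value z = 0.52 (S = 1, k = 3) exactly — and exposes the ±1 continuity
adjustment through a flag.

The published bias table for the 12-study set could not be reproduced for
the allele, heterozygote, dominant or homozygote rows under any standard
convention (fixed or τ²-inflated standard errors, OR- or log-scale inputs,
either continuity setting); its allele row is internally inconsistent
(coefficient/SE ≠ printed t, and the printed CI implies a different SE).
The package reports what the data give.

## Sensitivity analysis

Leave-one-out re-pools every (k−1)-subset under the same selection rule.
A study is flagged *influential* when the estimate is unstable in either
direction: the re-pooled OR falls outside the all-study CI, or the
all-study OR falls outside the re-pooled CI.  Significance flips of the
Z test are deliberately not part of the flag: with a full-set p-value near
0.05, omitting almost any study nudges p across the line, which says the
evidence is borderline, not that any single study is influential.  On the
embedded 12-study allele set no study is flagged, matching the published
conclusion.

## Hardy–Weinberg screen

Control-group HWE uses the Pearson χ² goodness-of-fit statistic against
p², 2pq, q² at the observed allele frequency, df = 1, no continuity
correction and no exact test — the only variant that reproduces the
published per-study HWE column (e.g. 0.764, 0.063, 0.998) to three
decimals.  Monomorphic groups are rejected as undefined.  The screen is
reported, not enforced: the one HWE-violating control group in the
embedded collection (rs2285714, p < 0.001) stays in its 3-study pool
because the published analysis retained it; callers who want to exclude
violators can filter on `hwe_test` before pooling.

## Synthetic data

The generator emulates the structure of the embedded collection: k studies
with uniform group sizes in a configurable range, control genotypes
multinomial under HWE at a control mutant-allele frequency, per-study log
odds ratios Normal(log(true OR), τ²), and case genotypes multinomial under
HWE at the case frequency implied by the allelic odds.  Defaults follow
the embedded set: k = 12, control frequency 0.45 (the collection's pooled
control C-allele frequency is ≈0.47, with ethnic strata at ≈0.33 and ≈0.51), allelic OR 0.87 and τ² = 0.03 (the
pooled estimate and between-study variance of its allele contrast), and
group sizes spanning the fixture's range (cases 100–1100, controls
55–1260).  An optional fraction of studies receives an inbreeding-style
distortion (F = 0.3) of the control genotype probabilities to exercise
the HWE screen.  One integer seed drives a single `numpy` generator.

The multiplicative allelic model makes every genotype-model OR an analytic
function of the allelic OR (e.g. the homozygote OR is its square under
HWE), which the tests exploit as an oracle.  The generator does not
emulate: genotyping error, covariate confounding, linkage disequilibrium
between SNPs, selective publication, or non-HWE case ascertainment
effects.  Passing calibration tests therefore shows the estimators are
correct under the stated sampling model, not that real collections are
free of those complications.

## Numerical notes and test scale

Wald intervals use the exact normal 97.5% quantile (1.959963…), not 1.96,
so round-trips through the log scale are consistent to machine precision.
Q, τ², MH sums and the bias tests are direct summations in float64 — the
study counts involved (k ≤ 50 in tests, cells < 10⁶) are far from any
conditioning trouble.  Monte-Carlo calibration tests use 200 replicates
(Q-test type-I error at the 0.10 threshold within ±3 points; DL coverage
of a true OR 0.8 at k = 50 at least 90%, mean pooled OR within ±0.03),
sizes at which the suite completes in well under a minute.  Reports round
ORs and CI bounds to 2 decimals and p-values to 3, printing sub-0.0005
p-values as "0.000", following the field's table style.
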