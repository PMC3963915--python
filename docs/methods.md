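# Methods

This note documents the statistical procedures implemented in `cordmediate`,
the generative model behind the synthetic cohorts, the defaults and why they
were chosen, and what the passing test suite does and does not establish.

## Exposure model and classification

Whole-blood arsenic is treated as lognormal. All summaries are computed on
the natural-log scale: geometric mean `exp(mean(ln v))`, geometric SD
`exp(sd(ln v))` with the n−1 denominator. Extreme groups are bounded by the
geometric mean ×/÷ the geometric SD, read strictly: a value exactly on a
boundary is `median`. The multiplicative reading is forced by internal
consistency — with a geometric mean of 0.56 µg/L and printed boundaries of
0.17 and 1.81 µg/L, an additive mean ± SD would require SD ≈ 1.25 µg/L and a
negative lower bound, whereas 0.56/3.25 ≈ 0.17 and 0.56 × 3.25 ≈ 1.82 are
consistent with one multiplicative SD of ≈ 3.25. Under lognormality each
extreme group captures Φ(−1) ≈ 15.9 % of subjects.

Values censored below the limit of detection (default 0.028 µg/L) are
replaced by LOD/2 before any log transform; the substitution is idempotent.
The IQR used to scale regression effects is computed with the
linear-interpolation (type-7) quantile convention, the numpy default, so the
reported "per IQR" effects are exactly reproducible. Whether the emulated
analysis used n or n−1 in the log-scale SD is unknowable from the printed
values; we use n−1, which moves the thresholds by well under 0.01 µg/L at
n ≈ 180.

## Birth-weight adjustment and SGA

SGA is a strict inequality against a per-(sex, completed week) P10 lookup
with no interpolation; a missing curve entry is an error rather than a
guess. The growth-adjusted outcome for the screen is ln(observed/expected)
where the expected weight comes from a per-sex OLS fit of weight on GA and
GA² (solved on centred GA for conditioning, coefficients mapped back).
Extreme groups are mean ± SD of the log ratio computed **within sex**; the
per-sex group counts this yields match the sex-specific counts the design
reports, which is why stratified thresholding was chosen over pooling (the
pooled alternative differs only marginally because the sex effect is largely
absorbed by the per-sex fits). Subjects with missing weight or GA — and any
non-positive ratio, which can only arise from invalid data — are excluded
from fitting and labelled `missing`. A log-ratio spread at floating-point
noise level (SD < 1e−10) is treated as a perfect fit: no extremes.

## Association models

Exposure enters continuously; the reported effect is coefficient × IQR
(linear) or exp(coefficient × IQR) (logistic odds ratio), with Wald CIs
scaled identically — the scaling is an exact identity, not a refit.
Covariate selection keeps the a-priori confounders unconditionally and runs
a deterministic backward elimination on the candidates: fit the full model,
drop the least significant candidate above p = 0.05 (multi-level categorical
candidates tested jointly by Wald blocks), refit, repeat. The emulated
analysis states only the 0.05 retention rule, not the search direction;
single-pass backward elimination was chosen because it is order-independent
given the largest-p-first drop rule.

Interaction checks add a cross-product and flag it at the liberal p < 0.20,
returning stratified fits when flagged. Diagnostics on linear fits:
Kolmogorov–Smirnov of standardized residuals against N(0,1) (the estimated
scale is treated as known — slightly conservative, noted in the record);
White's general heteroskedasticity test (LM p-value); and the classical
pure-error lack-of-fit F-test, which requires replicated design rows and is
reported "not applicable" otherwise. Influence screening flags leverage
> 2p/n or |externally studentized residual| > 3 — the named statistics with
conventional cutoffs, since no cutoffs are printed in the emulated design —
and the model is refitted without the flagged subjects; removing zero
subjects returns the original fit object, hence bit-identical numbers.
Logistic fits detect perfect separation (statsmodels' warning is escalated
plus a convergence/magnitude check) and raise rather than report nonsense.

## Quadrant screen

Within one sex, each surviving feature is Welch-tested (two-sided, unequal
variances, Satterthwaite df) for high-vs-low arsenic and low-vs-high
adjusted birth weight. Differences are oriented (high − low As) and
(low − high BW), so quadrant 1 is "up with exposure and up with growth
restriction" and quadrant 3 its mirror. `candidate` requires a concordant
quadrant **and** both p < 0.05; `labelled` reproduces the looser
plot-annotation rule (either p < 0.05). Under the null with disjoint
contrast groups the candidate rate is 0.05 × 0.05 × ½ = 0.125 %, which the
acceptance suite verifies at the design's girls-stratum group sizes
(17 vs 19 and 10 vs 14). Reliability filtering is conservative: a feature
enters a screen only if all five quality criteria pass in **every** sample
of the union of the four contrast groups, and replicate probes of a sequence
are averaged with flags AND-combined before screening. No multiple-testing
correction is applied to the primary candidate call, mirroring the targeted
panel design; BH q-values are emitted as an advisory column. Zero-variance
contrasts yield p = 1 (equal means) with a warning instead of NaN, and
−log10 p plot coordinates floor p at machine tiny.

Ties in quantile normalization receive the mean of the reference quantiles
at their tied ranks (the standard "mean" rule); the operation is exactly
idempotent on tie-free data and permutation-equivariant over samples.

## Mediation cascade

Exposure is dichotomized high vs median-or-low. Model 1 (BW ~ As) and models
3–4 adjust for sex, GA, smoking and parity (two dummies against the 2+
reference); model 2 (expression ~ As) adjusts for sex and GA only, matching
the emulated design's model footnotes. Each model tests a focal×sex
cross-product at p < 0.20; when included, sex-specific focal effects come
from linear contrasts of the fitted coefficients. The mediator enters
continuously on the log2 scale, so its coefficient is exactly "grams per
doubling of expression". Requirement 3/4 ("mediator predicts birth weight")
is met if the mediator is significant overall or in at least one sex stratum
when the interaction is included — a cascade can legitimately rest on a
single-sex effect. "Full" mediation is operationalized as a non-significant
model-4 exposure coefficient at α = 0.05, since a literal "drops to zero" is
unattainable in finite samples; "partial" additionally requires
|β_As(m4)| < |β_As(m1)|. The per-requirement trace is always returned so a
failed cascade (e.g. a candidate that does not survive the high vs
median-or-low recoding in model 2) shows exactly where it stopped.
Sensitivity analyses refit all four models with maternal BMI added, with the
pregnancy-complications flag added, or with complicated pregnancies
excluded, and report whether every significance conclusion is preserved.

Bootstrap/Sobel indirect-effect intervals and counterfactual mediation
estimands are deliberately out of scope — the implemented procedure is the
classical stepwise cascade — and are natural extensions.

## qPCR confirmation

Relative quantities are efficiency-corrected, `E^(Cq_ref − Cq)` with a
per-target efficiency defaulting to 2.0 (no printed efficiencies to emulate;
overridable per target), normalized by the geometric mean of the
reference-gene quantities of the same sample, and expressed as log2 fold
change versus an explicit reference sample (default: lexicographically first
id). Per-sample loading shifts cancel exactly in this normalization. The
geNorm M statistic is implemented at the definition level — the mean, over
partner references, of the SD across samples of the pairwise log2 ratio —
plus the iterative worst-gene exclusion ranking; the pairwise-variation
V < 0.15 inclusion cutoff is advisory only. Platform concordance is the
Pearson r of paired array/qPCR log2 fold changes, with the high-vs-low
exposure Welch contrast re-run on each platform.

## The synthetic generator

One draw produces a coherent study: lognormal cord arsenic (geometric mean
0.56 µg/L, geometric SD 3.25, LOD 0.028 µg/L), maternal arsenic correlated
at r = 0.82 on the ln scale, gestational age on completed weeks 34–42 from a
pmf peaked at 40 (median 40), and birth weight

```
BW = 3650 + 216·(GA − 40) + 161·boy − 111·smoking − 184·[parity 0] − 30·[parity 1]
     − 47·(As / IQR_theoretical) + δ_sex·(mediator − baseline) + ε,   ε ~ N(0, 400²) g
```

with δ_girls = −182 g per doubling and δ_boys = 0 by default. The
arsenic effect is injected through the latent continuous exposure scaled by
the theoretical lognormal IQR (≈ 0.99 µg/L), so the planted −47 g reads
exactly as a per-IQR effect. The planted mediator gene ("SFLT1", transcript
NM_001159920) is shifted +0.30 log2 units in the high-arsenic group, where
"high" is the **empirical** extreme-group classification of the drawn
cohort — the same classification the analysis will compute — so planted
contrasts are exact in the zero-noise limit. A single per-subject expression
value drives both the array row and the birth-weight path; replicate probes
add technical noise (SD 0.1 log2) on top.

Defaults the emulated design does not pin down are deliberate choices, not
population estimates: smoking prevalence 0.12, parity mix 0.45/0.38/0.17,
boys 0.5, complications 8/183, six missing birth weights and six missing
maternal arsenic values (reproducing the 183→177 attrition of the model Ns),
subject-level expression noise 0.5 log2 units, and residual birth-weight SD
400 g — the last back-derived from the width of the per-IQR CI the design
reports (±31 g at n = 177 implies a residual SD near 400 g). The geometric
SD 3.25 is itself derived from the printed class boundaries
(1.81/0.56 ≈ 0.56/0.17 ≈ 3.2–3.3).

Reference growth curves are self-derived: for each (sex, week) cell the P10
of the generator's own marginal birth-weight distribution is estimated from
20 000 simulated subjects (documented in the config as `curve_sim_size`) and
forced monotone by a running maximum. By construction ≈ 10 % of a fresh
cohort is SGA against these curves. The real external reference curves are
not shipped; users supply their own CSV for real data.

qPCR Cq values track −1 × log2 expression plus a per-sample loading shift
(SD 0.3 cycles, cancelled by normalization) and measurement noise (SD 0.15
cycles); a second mediator transcript is the first plus 0.25 log2 units of
independent noise, giving transcript–transcript correlations in the observed
range. The confirmation subset picks the 15 highest- and 15 lowest-exposure
samples by default.

**What the generator does not emulate:** probe-level spatial or dye
artifacts, batch effects, array background correction, non-Gaussian
expression noise, exposure measurement error beyond censoring, gestational
age recorded in days, or any real covariate joint distribution. Passing
tests therefore demonstrate that the *procedures* are correct and calibrated
under the assumed data-generating process, not that the scientific findings
would replicate in any real population.

## Problem sizes and numerical choices in the verification suite

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the asserted tolerances while keeping the default test run in
the low minutes: 10⁵ replicates for Welch null calibration, 10⁵ draws for
the extreme-group fractions, 10⁴ null genes for screen calibration (bands
are ±3 Monte-Carlo SEs), 500 cohorts for CI coverage, and 100–500 cascade
replicates for the mediation verdicts. Planted-recovery checks that are
power-limited at realistic noise (quadrant-screen recovery, the
partial-mediation verdict rate) run under documented high-power conditions
— a larger planted fold change with stronger mediator→weight coupling for
the screen, and residual SD 100 g with expression noise 0.25 log2 for the
cascade — because at the realistic defaults each individual requirement has
only 60–85 % power and the four-way conjunction would be met in well under
half of the replicates; the "full mediation at large n" check uses n = 2000
and expects the asymptotic 95 % rate (the model-4 exposure p-value is
uniform under its null). Degenerate inputs are handled explicitly
throughout: constant exposure or expression raises, zero-variance Welch
contrasts return p = 1 with a warning, perfect logistic separation raises,
and seeds make every generator output byte-identical across runs.
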