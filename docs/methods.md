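# Methods

This note documents the models, procedures and numerical choices behind
`epiclock`, the assumptions they make, and what the synthetic-cohort tests
do and do not demonstrate about real data.

## The clock model

A methylation clock is a sparse linear predictor of chronological age from
CpG beta values,

    ŷ_i = b₀ + Σ_j w_j m_ij ,

fitted by elastic-net regression: the penalized least-squares objective
mixes an L1 and an L2 penalty with mixing parameter α (here 0.5, an equal
mix) and overall strength λ. Age is regressed untransformed, in years —
log-linear age transforms belong to multi-species clocks and are out of
scope here. Covariates are standardized internally during fitting and the
coefficients are reported back on the original beta scale, so a stored
clock can be applied to any matrix containing its CpGs.

λ is chosen by tenfold cross-validation over a log-spaced path of 50
values (path span `eps = 1e-3` relative to the largest useful penalty),
taking the CV-mean-squared-error minimizer. The one-standard-error rule is
available (`lambda_rule="1se"`) but is not the default: the minimizer is
the conventional choice and the less biased predictor at these sample
sizes. Fold assignment is seeded and stratified by age quantile —
consecutive age-ordered blocks receive a random permutation of fold
labels — which stabilizes the CV curve at n ≈ 90. That assignment is the
only randomness in training; identical seed means identical clock.
Coordinate-descent convergence tolerance is 1e-3 on the CV path (the
selected λ is insensitive to tightening it tenfold; the loose setting
keeps the ~100 clock fits of a leave-one-out run affordable) and 1e-6 for
single fixed-λ fits.

Repeat samples from the same animal are deliberately *not* grouped in CV
folds; the main analysis treats samples as exchangeable and mixed-model
sensitivity analyses are out of scope.

Degenerate case: a training set whose ages are all equal yields the
constant clock (intercept = that age, no weights), which is the exact
penalized solution for any positive λ.

### Leave-one-out estimation

In-sample predictions of a cross-validated elastic net are optimistic. For
every downstream analysis the pipeline therefore uses leave-one-out (LOO)
DNAm ages: for each sample a clock is trained from scratch on the other
n−1 samples — *including its own tenfold λ search* — and applied to the
held-out sample. Nothing about a sample (neither its methylation nor its
recorded age) influences its own prediction; the test suite verifies this
by perturbing a held-out sample's age and checking its prediction is
unchanged, and by comparing `loo_predict` against an explicit
train/predict loop.

### Sex-specific clocks

`train_sex_specific` fits the same model on one sex only; applying a
female clock to males (or vice versa) uses the ordinary prediction path.
When male ageing slopes exceed female slopes at some CpGs, the female
clock systematically over-ages old males — the direction the synthetic
generator plants and the tests check.

## Age trend and parsimony rule

DNAm age is regressed on chronological age under three nested OLS models:
constant, linear, quadratic. Each fit stores the Gaussian maximum
likelihood (σ² = RSS/n) and AIC = −2ℓ + 2k with k counting the regression
coefficients plus the variance parameter; the additive constants cancel in
ΔAIC, so selection is insensitive to the convention, but stored AIC values
are defined exactly by it. Akaike weights are w_m = exp(−Δ_m/2) / Σ
exp(−Δ/2).

Selection retains the model with the lowest AIC unless a simpler model
lies within 2 AIC units of it, in which case the simplest such model is
retained. The rule is applied over the complexity order constant < linear
< quadratic (and, for the acceleration models below, ascending parameter
count with lexicographic tie-break). A perfect fit (RSS = 0) has formally
infinite likelihood; the implementation then selects the simplest
perfectly fitting model.

## Epigenetic age acceleration

Acceleration is the signed residual of DNAm age from the *selected* trend,
computed once on the pooled sample and then analysed within life stages:
juvenile (< 1 y), prime-age (1–8 y, boundaries inclusive), senescent
(> 8 y). By OLS algebra the residuals sum to zero and are orthogonal to
every polynomial term of the selected trend; both properties are asserted
in tests and used as a guard against mismatched inputs.

Within each adult stage, 14 candidate OLS models of acceleration on sex,
population and body mass are compared: the constant model, three single
main effects, three additive pairs, those pairs plus their interaction,
the additive triple, and the triple plus each one of the three two-way
interactions — every marginality-respecting combination with at most one
two-way interaction and no three-way term. Juveniles, being few in a real
campaign, get only four candidates: constant, or a single linear effect of
mass, sex or population. Specs with more parameters than samples (or
requiring an absent mass column) are dropped with a logged warning rather
than aborting the comparison. Selection reuses the AIC + parsimony
machinery; under the null the 14-model comparison retains the constant
model in roughly 80% of replicates (the familywise chance of some
covariate model gaining > 2 AIC is ~20% — a property of the candidate
set, verified by Monte Carlo, not a defect of the rule).

## EWAS statistics

The age screen computes, per CpG, the Pearson correlation r with age and
reports the Student t statistic z = r√(n−2)/√(1−r²) with a two-sided
p-value on n−2 degrees of freedom. This is algebraically identical to the
t test of the OLS slope of beta on age; the suite checks the two routes
agree to 1e-8. Missing betas are removed pairwise per CpG and `n_used`
recorded. Zero-variance CpGs get an explicit flag (never a silent 0), and
|r| = 1 gets `perfect` sentinels (z = ±∞, p = 0) rather than floating
overflow.

The sex screen fits beta ~ age + sex per CpG and tests the sex
coefficient; the interaction screen fits beta ~ age + sex + age×sex and
tests the interaction. Female is the reference level throughout: positive
coefficients mean higher methylation, or faster ageing, in males. The
stratified screen runs the age EWAS within each sex and reports the
Pearson correlation of the two z vectors over CpGs defined in both.

Multiple testing uses the single fixed threshold p < 10⁻⁸ (a
Bonferroni-style correction for five million tests); no FDR machinery is
layered on top. Top-CpG selection filters at the threshold, splits by the
sign of z, ranks each side by |z| and truncates at 500 per direction, with
ties broken by CpG id so the selection is order-invariant.

For the synthetic interaction-recovery check the genome-wide 10⁻⁸ cutoff
would be miscalibrated — it corresponds to a five-million-test array, not
a 4,000-CpG simulation — so that test uses Bonferroni at the simulated
array scale, 0.05/n_cpgs.

## Enrichment

For each annotation category (region class relative to the closest TSS,
or CpG-island status) and each direction of change, a 2×2 table of
selected vs background CpGs is tested with the two-sided Fisher exact
test, defined exactly: the sum of hypergeometric probabilities of all
tables with the observed margins no more probable than the observed one
(mid-p and doubling variants differ; this is the standard convention).
The sample odds ratio ad/bc gets the Haldane 0.5 correction if and only
if a cell is zero, and is flagged. Stars follow the usual figure
convention (* p<.05 to **** p<10⁻⁴). The test suite checks the p-value
against full enumeration for every 2×2 table with N ≤ 40.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for every planted effect:

- **Design**: 83 animals by default, a fraction (11/83) recaptured one
  year later, giving ~94 samples; two sexes, two populations; juveniles
  all sampled at the winter capture age of 8 months (0.67 y), adults
  uniform to 13.5 y; juvenile share ≈ 8/94 of samples.
- **Methylation model**: on the logit scale,
  `logit m_ij = μ_j + s_j (f(a_i+δ_i) − f̄) + β_j^sex·male_i +
  β_j^int·male_i·(f(a_i+δ_i) − f̄) + ε_ij`, mapped through the logistic
  function so betas are strictly inside (0, 1). Null CpGs draw μ from a
  bimodal mixture near logit 0.05 and logit 0.95, matching the
  U-shaped beta distribution of real arrays; planted CpGs draw μ
  mid-range. The age effect is centered at the cohort-mean effective age
  f̄ so planted sites stay mid-range across the cohort — the μ-at-birth
  parameterization would drive every planted site into saturation by old
  age and distort the age trend with artificial curvature.
- **Tick rate**: effective age f(a) rises with slope λ = 3 per year up to
  the maturity age and slope 1 after it. The two knobs are calibrated, not
  measured quantities: λ = 3 makes the juvenile steepening clearly
  detectable at n ≈ 94, and maturity is set at 1.5 y so the knee of f lies
  strictly below the adult (≥ 2 y) range — a linear-in-beta clock can only
  represent the knee smoothly, and a knee at the adult boundary leaks
  curvature into the adult subset that the real analysis does not show.
- **Effects**: age CpGs carry slope ±0.15 logit per effective year; sex
  CpGs a basal offset ±1.0; interaction CpGs age in both sexes with a
  same-signed male surplus of 0.10 (males are the faster-ageing sex at
  those sites). Sex-linked CpGs land on two designated gonosomal scaffolds
  with probability 0.8. Hypermethylating age CpGs are placed into
  promoters/5'UTRs and islands at 3× the background rate so the
  enrichment stage has a planted, directional signal.
- **Mass coupling**: juveniles get a biological-age offset δ = γ(mass −
  stage mean), γ = 0.1 y/kg, making early growth allocation recoverable by
  the acceleration stage. Adult mass is noise by construction.
- **Noise**: i.i.d. Gaussian on the logit scale, σ = 0.3 — chosen so that
  per-CpG age correlations and genome-wide EWAS hit counts sit in the
  plausible range for a blood methylation study of this size.
- **Reproducibility**: everything derives from one seed; an optional
  `site_seed` fixes the per-CpG biology (classes, baselines, slopes,
  annotation) independently of the cohort draw, so replicate cohorts can
  share an "array" — used by the leakage-free calibration oracle in the
  acceptance tests.

What the generator does *not* emulate: probe chemistry and measurement
batch effects, cell-composition heterogeneity, spatial correlation along
the genome, realistic minor-allele or cross-hybridization artefacts, and
any nonlinearity of ageing beyond the single tick-rate knee. Passing the
recovery tests therefore demonstrates that the estimators are correct and
well-calibrated under the assumed generative model at realistic sizes — it
does not certify performance on real arrays.

## Problem sizes in the tests

The test suite trades breadth for runtime deliberately: unit tests run on
hand-sized fixtures; the parameter-recovery suite uses one 150-animal ×
2,000-CpG cohort (with its leave-one-out predictions computed once per
session and shared across tests, and the juvenile share raised to 0.15 so
the curvature contrast is well powered at that n), a 120-animal cohort
with 60 juveniles for the mass-coupling check, a 94 × 5,000-null-CpG
cohort for type-I error, and the default 94 × 4,000 design for the EWAS
power and sex-clock checks. The acceptance script runs the default study
design end to end, dominated by the 94 leave-one-out clock trainings.

## Known limitations

- The Fisher enrichment tests are array-internal; gene-set enrichment
  against external genome annotation is out of scope.
- Clock training assumes complete betas (error on missing, with optional
  training-mean imputation at prediction time); no EM-style handling.
- The LOO protocol is O(n) full CV fits; it is affordable at field-study
  sizes but not engineered for thousands of samples.
- The acceleration models are ordinary least squares; animal identity is
  not modelled as a random effect, so repeat captures contribute as
  independent samples exactly as in the main analysis they mirror.
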