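# Methods

## Design being modelled

A single-group crossover: every subject is measured at each of four visits
(V1–V4), each visit corresponding to an inhaled-treatment condition
(maintenance ICS/LABA, new-combination run-in, LABA alone after steroid
withdrawal, combination re-treatment). All models are pairwise between two
visits; with two visits per subject the paired structure is exact and the
analysis below applies. More than two visits per model is out of scope.

## Multilevel variation splitting

For visit pair (a, b), subject i contributes rows x_ia and x_ib. The matrix
decomposes exactly as X = 1 mᵀ + X_between + X_within, where m is the grand
mean, X_between holds subject-mean deviations, and the within rows of subject
i are ∓(x_ib − x_ia)/2. The split is an identity, not an estimate; tests
assert reconstruction to 1e−10 and the ± antisymmetry. All discriminant
modelling uses X_within only, which removes the between-subject variance that
otherwise dominates omics blocks.

Held-out subjects' within parts are computed from *their own* pair mean. This
uses no class labels and no training rows, which is what makes per-individual
validation leakage-free: the test transformation is purely local to the test
subject.

## Scaling and block fusion

Features are centered and autoscaled to unit variance using training rows only
(sample SD, ddof = 1); features constant in training are dropped and the same
drop is applied at projection. For multi-block fusion every feature is further
divided by √p_block (retained features in its block) so each block contributes
equal total variance a priori — without this the 32-sensor array would swamp
single-feature blocks. The source study does not state its scaling;
autoscaling is the metabolomics default and both autoscaling and block
weighting are config switches (`PipelineConfig`). Within matrices are exactly
column-centered by construction, so the learned centers are ≈ 0 there; the
scaling model is still fitted generically.

## PLS-DA

Single-response NIPALS: per component, w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt,
q = yᵀt/tᵀt, then deflation of X and y. Scores are mutually orthogonal and
weights unit-norm by construction; the first weight equals the dominant left
singular vector of the Xᵀy cross-covariance (asserted against an SVD oracle at
1e−8, and against scikit-learn's PLS as an independent implementation).
Extraction stops early when the deflated cross-covariance or score norm
underflows the numerical rank, and the achieved component count is recorded.
Default A = 2 components: the smallest dimensionality that supports a
non-trivial KNN geometry; configurable. Projection uses the standard rotation
t = x W(PᵀW)⁻¹.

For two-visit data, PLS on the ± within rows is equivalent to PLS on the
per-subject difference vectors: a subject's row scores are ± half the score of
its scaled difference vector (asserted in tests), so subject-level decision
orderings agree with a difference-matrix formulation.

## KNN and Monte Carlo cross-validation

KNN (default k = 3, odd k enforced) on the PLS scores, Euclidean distance,
distance ties broken deterministically toward the smallest training-row index.
The vote fraction — the share of the k neighbours labelled +1 — is the
continuous score for ROC analysis; it is the only continuous quantity this
classifier family produces.

MCCV: default 500 iterations, each holding out ⌈20%⌉ of subjects (both rows
together, minimum 1 subject, at least 2 training subjects required). The whole
pipeline (splitting → scaling → PLS → KNN) is refitted inside every training
fold. Predictions pool across iterations into one confusion matrix. Because
the training score cloud is mirror-symmetric and each test subject contributes
mirrored ±d/2 rows, an odd-k KNN classifies the two rows oppositely: the
pooled matrix is exactly symmetric (TP = TN, FP = FN) and sensitivity =
specificity = accuracy. The accuracy CI is the Monte-Carlo standard-error
interval of per-iteration accuracies (mean ± 1.96·SD/√n_iter, clipped to
[0, 100]%) — it quantifies resampling noise of the MCCV estimate, not
subject-level binomial uncertainty.

## Permutation significance

The only exchangeable relabelling under the paired design is swapping the two
visit labels within a subject, i.e. a sign flip of that subject's difference
vector. Each of the (default 100) permutations draws independent ±1 signs per
subject and re-runs the *full* MCCV; p = (1 + #{AUC_perm ≥ AUC_obs})/(n_perm + 1)
(add-one convention, so p is never 0 and min p = 1/(n_perm+1) ≈ 0.0099 at 100
permutations). `permutation_iterations` optionally reduces the per-permutation
MCCV iteration count for speed; in that case the observed AUC entering the
comparison is recomputed at the same reduced count so observed and permuted
statistics stay exchangeable under the null (the full-run AUC is still the one
reported). A classification is significant when accuracy > 70% (strict) and
p < 0.01 (strict); both thresholds are configurable.

The diagnostic odds ratio is (sens·spec)/((1−sens)(1−spec)), reported to 3
significant figures; boundary sensitivities/specificities yield ±inf/NaN
rather than exceptions. Youden's J is the ROC-maximal sens + spec − 1 over
thresholds of the pooled vote fractions; note that for a symmetric confusion
matrix J at the ROC optimum can legitimately exceed 2·accuracy − 1, because
the optimum threshold need not coincide with the majority-vote cut.

## Univariate cascade and correlations

Per feature across the four visits (complete-case subjects, ≥ 3 required):
D'Agostino–Pearson omnibus normality on two-way residuals (value − subject
mean − visit mean + grand mean; a `pooled` option exists) at α = 0.05 routes
to one-way repeated-measures ANOVA (no sphericity correction) or the Friedman
test. Only a significant overall p (< 0.05) triggers the six pairwise paired
t or Wilcoxon signed-rank tests. No multiple-testing adjustment is applied
anywhere — an explicit exploratory-study choice; the type-I error of the
cascade is verified to sit at the nominal 5% per test on null data. Summaries
are mean ± SEM on the normal route, median with IQR and MAD otherwise.

Correlations are pairwise-complete Pearson r with two-sided p over all pooled
samples, treating a subject's four visits as independent observations. That is
statistically naive by design — it reproduces the pooled-sample heatmap
convention — and the docstring flags it. Zero-variance features are flagged
and their pairs left NaN.

## Synthetic cohort generator

Latent model per block: value = baseline + visit effect δ + subject effect +
residual, with subject effect ~ σ_s·(√ρ·h_s + √(1−ρ)·η) and residual ~
σ_e·(√ρ·g + √(1−ρ)·ε), where h_s (per subject) and g (per sample) are shared
across the block's features. Any two features of a block then have latent
correlation exactly ρ — one parameter reproducing e-nose sensor redundancy.
Lognormal-family blocks exponentiate the latent value: effects are
multiplicative and values strictly positive. Missingness is completely at
random per block (no mechanism is claimed by the emulated study). Generation
and missingness use separate child streams of one seed; identical configs are
bit-reproducible.

Default configuration (the simulated study conditions): 14 subjects × 4
visits; blocks carbon_polymer (32 sensors, lognormal, ρ = 0.90), quartz (8
sensors, ρ = 0.85), nmr (13 EBC metabolites, ρ = 0.20), eicosanoids (4
features), feno, spirometry (9 gaussian indices), sputum (5 gaussian
differential counts). Baselines are typical published magnitudes (sensor
response levels, metabolite integrals, spirometric values); σ_s values are
back-computed from published between-subject dispersions (SEM·√14) and σ_e
set to plausible visit-to-visit repeatability (~5–10% of baseline). Because
the emulated study reports only group-level summaries, per-subject variance
components cannot be calibrated exactly: σ_s/σ_e are loosely matched to
published dispersion tables and are simulator choices, not claims. The
spirometry block accepts per-feature σ because litres (~1) and %-predicted
(~80) scales cannot share one SD.

The default effect template (latent/log scale, relative to V1) encodes the
qualitative ICS-response pattern: all e-nose sensors drift upward after the
inhaler switch (+0.12/+0.15/+0.25 at V2/V3/V4 for carbon; +0.30/+0.25/+0.35
for quartz), sputum PGE2 rises under LABA-alone withdrawal (+0.55 at V3), EBC
formate falls at V3/V4 and acetate falls at V4, and spirometry shifts by the
published between-visit mean differences. Magnitudes are free parameters.
Default missingness: 3% per cell on the eicosanoid and sputum blocks, which
reproduces ≈ 7 missing eicosanoid cells per 56-sample cohort and ≈ 8/14
subjects with complete sputum sets at block level.

What the generator does *not* emulate: raw NMR spectra and peak overlap,
sensor drift/time-series structure, informative missingness, non-lognormal
skew, inhaler pharmacokinetics, and %-predicted values derived from reference
equations (they are generated directly as features). Passing tests therefore
demonstrate correctness and calibration of the *pipeline* under a plausible
generative model, not clinical validity on real breathomics data.

## Numerical and test-design choices

* Seeds: every stochastic component (generator, missingness, MCCV draws,
  permutations) derives from named `SeedSequence` child streams; identical
  seeds give identical results to the bit.
* Tolerances: decomposition identity 1e−10 (relative to input magnitude), PLS
  oracle agreement and score orthogonality 1e−8, constant-feature detection
  via zero sample SD.
* Degenerate inputs raise typed errors (`DegenerateDataError`,
  `InsufficientDataError`, `FeatureMismatchError`) rather than silently
  producing numbers; DOR boundaries return inf/NaN by contract.
* Monte Carlo test sizes: calibration suites use 30–100 replicate cohorts,
  100–500 MCCV iterations, and 19–100 permutations — sizes chosen so binomial
  / Monte-Carlo standard errors support 3–4 SE assertions; single-cohort null
  accuracy is itself ~±15% noisy at n = 14 subjects (finite-subject noise), so
  calibration is asserted on replicate-averaged accuracies.
* The full-pipeline CLI is deterministic: reports and manifests are
  byte-identical across reruns of the same config and seed.

## Known limitations

* Complete-case assembly only; no imputation (the emulated study's n varies
  per outcome, and any imputation policy would be a stronger claim than the
  data support).
* The permutation test at 100 permutations cannot produce p below 0.0099;
  finer significance claims need more permutations.
* Pooled correlations ignore within-subject dependence (by design, see above).
* RM-ANOVA applies no sphericity correction; with 4 visits and n = 14 this is
  anti-conservative under non-sphericity.
* KNN and PLS component count are fixed defaults (k = 3, A = 2), not tuned;
  an inner-CV chooser for A was considered and deliberately left out to keep
  the validation loop simple and leakage-free.
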