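# breathpair

Multilevel PLS-DA breathomics for paired inhaled-treatment crossover studies.

## The problem

Small crossover studies in respiratory pharmacology measure the same subjects
under several treatment conditions (visits) across heterogeneous feature
blocks: electronic-nose sensor arrays (32 carbon-polymer + 8 quartz-crystal
sensors), NMR metabolite integrals from exhaled breath condensate (EBC),
eicosanoid concentrations, FeNO, spirometry, and sputum differential counts.
Between-subject baseline differences dwarf the within-subject treatment
effects, sample sizes are tiny (n ≈ 14), and the question is whether the
*multidimensional* breathprint distinguishes treatment conditions better than
spirometry alone.

`breathpair` implements the full analysis pipeline for this design, plus a
synthetic cohort generator with known ground truth so every stage is testable
without patient data.

## The method

For a visit pair (a, b), each subject contributes two rows and the data matrix
splits exactly into

```
X = 1 mᵀ + X_between + X_within,     within part of subject i: ±(x_b − x_a)/2
```

Discrimination runs on the within-subject part only (multilevel PLS):
features are autoscaled and block-weighted by 1/√p_block (fitted on training
rows only), a NIPALS PLS-DA extracts A latent components (default A = 2)
against y = ∓1, and a k-nearest-neighbour classifier (default k = 3) labels
held-out subjects by their projected scores.

Validation is a subject-level Monte Carlo cross-validation (default 500
iterations, 20% of subjects per draw): *both* rows of a test subject are held
out together, the entire variation splitting / scaling / PLS fit is redone on
the training subjects, and the test subject's within part is computed from its
own pair mean — no labels or training statistics leak. The ± geometry makes
the pooled confusion matrix exactly symmetric (TP = TN, FP = FN), so
sensitivity = specificity = accuracy.

Reported per model and visit pair: pooled accuracy (%) with a Monte-Carlo SE
confidence interval, AUC of the pooled KNN vote fractions, Youden's J,
diagnostic odds ratio `(sens·spec)/((1−sens)(1−spec))`, and a permutation
p-value in which the visit labels are swapped within subjects (a sign flip of
each dᵢ) and the full MCCV pipeline is re-run per permutation (default 100);
`p = (1 + #{AUC_perm ≥ AUC_obs})/(n_perm + 1)`. A classification is
*significant* when accuracy > 70% and p < 0.01.

A univariate module provides the companion within-group cascade
(D'Agostino–Pearson normality → RM-ANOVA or Friedman → all pairwise paired
t / Wilcoxon tests, deliberately without multiplicity adjustment) and pooled
pairwise-complete Pearson correlations.

## Worked example

```
$ breathpair simulate --out cohort/ --seed 7
wrote 56 samples x 7 blocks to cohort

$ breathpair analyze --cohort cohort/ --pair V1,V4 \
    --blocks carbon_polymer,quartz,nmr,eicosanoids,feno,spirometry,sputum \
    --iterations 500 --permutations 100 --permutation-iterations 100 --seed 7
comparison: V1 vs V4
n_subjects: 11
accuracy_pct: 86.3
ci95_low_pct: 84.3
ci95_high_pct: 88.3
auc: 0.948
youden_j: 0.782
odds_ratio: 39.7
sensitivity: 0.863
specificity: 0.863
permutation_p: 0.009900990099009901
significant: True
excluded_subjects: S02;S06;S12
```

The simulated cohort is 14 subjects × 4 visits; the default effect template
shifts e-nose responses, EBC formate/acetate, and sputum PGE2 between visits.
Three subjects have missing eicosanoid or sputum cells (the generator mimics
realistic missingness) and are excluded by the complete-case rule, leaving 11.
The V1-vs-V4 model separates the two treatment conditions well: 86.3% pooled
accuracy (sensitivity = specificity, by the symmetry above), AUC 0.948, and no
permutation beat the observed AUC (p = 1/101 < 0.01), so the model clears the
significance rule. `breathpair report --out out/` runs the full 2-model ×
6-visit-pair grid and writes `models_report.csv`, `univariate_report.csv`,
`correlations.csv`, and a reproducibility manifest.

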