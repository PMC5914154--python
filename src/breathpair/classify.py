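"""KNN on multilevel PLS scores under subject-level Monte Carlo CV.

Each MCCV iteration holds out complete subjects (both visits together), runs
variation splitting, scaling, and the PLS fit on training subjects only,
projects the held-out subjects' within-parts (computed from their own pair
means — no labels, no training rows) and classifies their scores with KNN.
Predictions are pooled over iterations into a single confusion matrix.

Because each test subject contributes two mirrored within-rows (+-d/2) and the
training score cloud is itself mirror-symmetric, an odd-k KNN classifies a
subject's two rows in opposite ways: if one row is wrong the other is wrong in
the opposite direction, forcing a fully symmetric pooled confusion matrix
(TP = TN, FP = FN) and hence sensitivity = specificity = accuracy.

Significance follows the permutation logic of the paired design: the only
exchangeable relabelling is swapping the two visit labels within a subject
(a sign flip of that subject's difference vector); the full MCCV pipeline is
re-run per permutation and the AUCs compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ConfigError, InsufficientDataError
from .multilevel import (
    PairedMatrix,
    PipelineConfig,
    apply_scaling,
    fit_pls_da,
    fit_scaling,
    project,
    split_variation,
    within_parts,
)

__all__ = [
    "CVConfig",
    "ConfusionMatrix",
    "CVResult",
    "knn_predict",
    "mccv_classify",
    "permutation_test",
    "confusion_stats",
    "diagnostic_odds_ratio",
    "roc_auc",
    "youden_j",
    "accuracy_ci",
    "classify_significance",
]


@dataclass(frozen=True)
class CVConfig:
    """Monte Carlo cross-validation and significance settings.

    ``permutation_iterations=None`` re-runs permutations at the full
    ``n_iterations``; a smaller value trades permutation precision for speed,
    in which case the observed AUC entering the p-value comparison is
    recomputed at the same reduced count so the comparison stays exchangeable.
    """

    k: int = 3
    n_iterations: int = 500
    test_fraction: float = 0.2
    n_permutations: int = 100
    permutation_iterations: int | None = None
    accuracy_threshold: float = 70.0   # percent
    alpha: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ConfigError(f"k must be an odd integer >= 1, got {self.k}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.n_iterations < 1:
            raise ConfigError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.n_permutations < 1:
            raise ConfigError(f"n_permutations must be >= 1, got {self.n_permutations}")
        if self.permutation_iterations is not None and self.permutation_iterations < 1:
            raise ConfigError("permutation_iterations must be >= 1 or None")


@dataclass
class ConfusionMatrix:
    """Pooled counts; class +1 = second visit of the pair."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def add(self, y_true: np.ndarray, y_pred: np.ndarray) -> None:
        pos, predpos = y_true > 0, y_pred > 0
        self.tp += int(np.sum(pos & predpos))
        self.fn += int(np.sum(pos & ~predpos))
        self.tn += int(np.sum(~pos & ~predpos))
        self.fp += int(np.sum(~pos & predpos))


@dataclass
class CVResult:
    """Everything the study reports per model and visit pair."""

    confusion: ConfusionMatrix
    per_iteration_accuracy: np.ndarray   # fractions in [0, 1]
    accuracy: float                      # pooled, percent
    accuracy_ci: tuple[float, float]     # percent
    sensitivity: float
    specificity: float
    auc: float
    youden_j: float
    odds_ratio: float
    permutation_p: float | None
    significant: bool | None
    visit_pair: tuple[str, str] = ("a", "b")
    n_subjects: int = 0
    excluded_subjects: list[str] = field(default_factory=list)
    permutation_aucs: np.ndarray | None = None


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------


def knn_predict(
    train_scores: np.ndarray,
    train_labels: np.ndarray,
    test_scores: np.ndarray,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean KNN with majority vote and a continuous vote fraction.

    Distance ties are broken deterministically toward the smallest
    training-row index (stable sort on distances). ``vote_fraction`` is the
    fraction of the k nearest neighbours labelled +1, the continuous score the
    ROC analysis consumes.
    """
    train_scores = np.atleast_2d(np.asarray(train_scores, dtype=float))
    test_scores = np.atleast_2d(np.asarray(test_scores, dtype=float))
    train_labels = np.asarray(train_labels)
    if train_scores.shape[0] == 0:
        raise InsufficientDataError("empty training set")
    if k > train_scores.shape[0]:
        raise InsufficientDataError(
            f"k={k} exceeds the {train_scores.shape[0]} training rows"
        )
    if train_scores.shape[1] != test_scores.shape[1]:
        raise ValueError("train and test scores have different dimensionality")
    d2 = (
        np.sum(test_scores**2, axis=1)[:, None]
        - 2.0 * test_scores @ train_scores.T
        + np.sum(train_scores**2, axis=1)[None, :]
    )
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    neighbour_labels = train_labels[order] > 0
    vote_fraction = neighbour_labels.mean(axis=1)
    labels = np.where(vote_fraction > 0.5, 1.0, -1.0)
    return labels, vote_fraction


# ---------------------------------------------------------------------------
# MCCV engine
# ---------------------------------------------------------------------------


def _n_test_subjects(n_subjects: int, cv: CVConfig) -> int:
    n_test = max(1, int(round(cv.test_fraction * n_subjects)))
    if n_subjects - n_test < 2:
        raise InsufficientDataError(
            f"test_fraction={cv.test_fraction} leaves "
            f"{n_subjects - n_test} training subject(s); need >= 2"
        )
    return n_test


def _run_mccv(
    paired: PairedMatrix,
    pipeline: PipelineConfig,
    cv: CVConfig,
    n_iterations: int,
    rng: np.random.Generator,
    subject_signs: np.ndarray | None = None,
):
    """Pooled MCCV pass; ``subject_signs`` (+-1 per subject) implements the
    within-subject label-swap null."""
    n = paired.n_subjects
    if n < 4:
        raise InsufficientDataError(f"MCCV needs >= 4 subjects, got {n}")
    n_test = _n_test_subjects(n, cv)
    y_base = paired.y.copy()
    if subject_signs is not None:
        y_base = y_base * np.repeat(subject_signs, 2)

    cm = ConfusionMatrix()
    votes: list[np.ndarray] = []
    truths: list[np.ndarray] = []
    accs = np.empty(n_iterations)
    all_idx = np.arange(n)
    for it in range(n_iterations):
        test_idx = rng.choice(n, size=n_test, replace=False)
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]

        train_rows = np.ravel([[2 * i, 2 * i + 1] for i in train_idx])
        test_rows = np.ravel([[2 * i, 2 * i + 1] for i in test_idx])

        X_train, y_train = paired.X[train_rows], y_base[train_rows]
        train_sub = PairedMatrix(
            subjects=[paired.subjects[i] for i in train_idx],
            visit_pair=paired.visit_pair,
            X=X_train,
            y=y_train,
            feature_names=paired.feature_names,
            block_index=paired.block_index,
        )
        dec = split_variation(train_sub)
        scaling = fit_scaling(
            dec.X_within,
            paired.block_index,
            autoscale=pipeline.autoscale,
            block_weight=pipeline.block_weight,
            feature_names=paired.feature_names,
        )
        Z_train = apply_scaling(scaling, dec.X_within)
        model = fit_pls_da(Z_train, y_train, pipeline.n_components, scaling=scaling)

        W_test = within_parts(paired.X[test_rows])
        Z_test = apply_scaling(scaling, W_test)
        T_test = project(model, Z_test)
        y_test = y_base[test_rows]
        labels, vote_fraction = knn_predict(model.T, y_train, T_test, cv.k)

        cm.add(y_test, labels)
        votes.append(vote_fraction)
        truths.append(y_test)
        accs[it] = float(np.mean(labels == y_test))

    pooled_votes = np.concatenate(votes)
    pooled_truth = np.concatenate(truths)
    auc = roc_auc(pooled_votes, pooled_truth)
    return cm, accs, pooled_votes, pooled_truth, auc


def mccv_classify(
    paired: PairedMatrix,
    pipeline: PipelineConfig | None = None,
    cv: CVConfig | None = None,
    run_permutations: bool = True,
) -> CVResult:
    """Full subject-level MCCV evaluation of one pairwise model.

    Seeded and reproducible: the observed run and the permutation null draw
    from separate child streams of ``cv.seed``.
    """
    pipeline = pipeline or PipelineConfig()
    cv = cv or CVConfig()
    cv.validate()
    ss = np.random.SeedSequence(cv.seed)
    obs_ss, perm_ss = ss.spawn(2)

    cm, accs, votes, truths, auc = _run_mccv(
        paired, pipeline, cv, cv.n_iterations, np.random.default_rng(obs_ss)
    )
    acc_frac, sens, spec = confusion_stats(cm)
    accuracy = 100.0 * acc_frac
    ci = accuracy_ci(100.0 * accs)
    j = youden_j(votes, truths)
    dor = diagnostic_odds_ratio(sens, spec)

    p = None
    perm_aucs = None
    significant = None
    if run_permutations:
        p, perm_aucs = permutation_test(
            paired, pipeline, cv, auc_obs=auc, seed_sequence=perm_ss
        )
        significant = classify_significance(accuracy, p, cv)

    return CVResult(
        confusion=cm,
        per_iteration_accuracy=accs,
        accuracy=accuracy,
        accuracy_ci=ci,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_j=j,
        odds_ratio=dor,
        permutation_p=p,
        significant=significant,
        visit_pair=paired.visit_pair,
        n_subjects=paired.n_subjects,
        excluded_subjects=list(paired.excluded_subjects),
    )


def permutation_test(
    paired: PairedMatrix,
    pipeline: PipelineConfig | None = None,
    cv: CVConfig | None = None,
    auc_obs: float | None = None,
    seed_sequence: np.random.SeedSequence | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the classifier AUC under the paired null.

    The null swaps the two visit labels independently within each subject
    (a sign flip of d_i), preserving the paired structure, and re-runs the
    entire MCCV pipeline per permutation. p uses the add-one convention,
    ``(1 + #{AUC_perm >= AUC_obs}) / (n_permutations + 1)``, so it is never 0.

    When ``cv.permutation_iterations`` reduces the per-permutation iteration
    count, the observed AUC is recomputed at that same count (``auc_obs`` is
    ignored) to keep observed and permuted statistics exchangeable.
    """
    pipeline = pipeline or PipelineConfig()
    cv = cv or CVConfig()
    cv.validate()
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(cv.seed, spawn_key=(1,))
    n_iter = cv.permutation_iterations or cv.n_iterations
    children = seed_sequence.spawn(cv.n_permutations + 1)

    if auc_obs is None or n_iter != cv.n_iterations:
        *_, auc_obs = _run_mccv(
            paired, pipeline, cv, n_iter, np.random.default_rng(children[0])
        )

    n = paired.n_subjects
    perm_aucs = np.empty(cv.n_permutations)
    for b in range(cv.n_permutations):
        rng = np.random.default_rng(children[b + 1])
        signs = rng.integers(0, 2, size=n) * 2 - 1
        *_, auc_b = _run_mccv(paired, pipeline, cv, n_iter, rng, subject_signs=signs)
        perm_aucs[b] = auc_b

    p = (1.0 + float(np.sum(perm_aucs >= auc_obs))) / (cv.n_permutations + 1.0)
    return p, perm_aucs


# ---------------------------------------------------------------------------
# Reporting statistics
# ---------------------------------------------------------------------------


def confusion_stats(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as fractions."""
    if cm.total == 0:
        raise InsufficientDataError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else float("nan")
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else float("nan")
    return accuracy, sens, spec


def diagnostic_odds_ratio(sensitivity: float, specificity: float) -> float:
    """DOR = (sens * spec) / ((1 - sens)(1 - spec)); boundaries give inf/0."""
    num = sensitivity * specificity
    den = (1.0 - sensitivity) * (1.0 - specificity)
    if den == 0.0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC (ties get half credit) of scores for class +1."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InsufficientDataError("AUC undefined: only one class present")
    return float(roc_auc_score(labels > 0, np.asarray(scores, dtype=float)))


def youden_j(scores: np.ndarray, labels: np.ndarray) -> float:
    """Max over ROC thresholds of sensitivity + specificity - 1."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InsufficientDataError("Youden's J undefined: only one class present")
    fpr, tpr, _ = roc_curve(labels > 0, np.asarray(scores, dtype=float))
    return float(np.max(tpr - fpr))


def accuracy_ci(per_iteration_accuracies: np.ndarray) -> tuple[float, float]:
    """Monte-Carlo standard-error interval of the MCCV mean accuracy.

    mean +- 1.96 * SD / sqrt(n_iterations), clipped to [0, 100]. Pass
    percentages for a percent-scale interval.
    """
    accs = np.asarray(per_iteration_accuracies, dtype=float)
    if accs.size < 2:
        raise InsufficientDataError("accuracy CI needs >= 2 iterations")
    mean = accs.mean()
    half = 1.96 * accs.std(ddof=1) / np.sqrt(accs.size)
    return (float(np.clip(mean - half, 0.0, 100.0)), float(np.clip(mean + half, 0.0, 100.0)))


def classify_significance(accuracy_percent: float, p: float, cv: CVConfig | None = None) -> bool:
    """Significant classification: accuracy strictly above the threshold
    (default 70%) AND permutation p strictly below alpha (default 0.01)."""
    cv = cv or CVConfig()
    return bool(accuracy_percent > cv.accuracy_threshold and p < cv.alpha)
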