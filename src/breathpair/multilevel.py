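"""Multilevel variation splitting and PLS-DA for paired two-visit data.

For a paired (two-visit) design every subject contributes two rows, and the
data matrix decomposes exactly as

    X = 1 m' + X_between + X_within

with ``m`` the grand mean, ``X_between`` the subject-mean deviations (repeated
over a subject's rows) and ``X_within`` each row's deviation from its own
subject mean. For two visits the within part of subject i is +-(x_b - x_a)/2:
the between-subject baseline differences — which dominate omics data — are
removed before the discriminant model ever sees the matrix, and the
classification problem becomes fully paired. PLS-DA is fitted on the scaled
within part against y = -1 (first visit) / +1 (second visit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import DegenerateDataError, FeatureMismatchError, InsufficientDataError

__all__ = [
    "PairedMatrix",
    "MultilevelDecomposition",
    "ScalingModel",
    "PLSModel",
    "PipelineConfig",
    "assemble_paired",
    "split_variation",
    "within_parts",
    "fit_scaling",
    "apply_scaling",
    "fit_pls_da",
    "project",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the multilevel PLS stage.

    ``autoscale=False`` falls back to centering without unit-variance scaling
    (e.g. to feed raw NMR integrals); ``block_weight=False`` disables the
    1/sqrt(p_block) fusion weights.
    """

    n_components: int = 2
    autoscale: bool = True
    block_weight: bool = True


@dataclass
class PairedMatrix:
    """Complete-case two-visit matrix: 2 rows per subject, [visit_a, visit_b]."""

    subjects: list[str]
    visit_pair: tuple[str, str]
    X: np.ndarray                 # (2n, p)
    y: np.ndarray                 # (2n,) -1 for visit_a rows, +1 for visit_b rows
    feature_names: list[str]
    block_index: np.ndarray       # (p,) owning block name per feature
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_rows(self, i: int) -> tuple[int, int]:
        """Row indices (visit_a, visit_b) of subject number ``i``."""
        return 2 * i, 2 * i + 1

    def take_subjects(self, idx: np.ndarray) -> "PairedMatrix":
        rows = np.ravel([[2 * i, 2 * i + 1] for i in idx]).astype(int)
        return PairedMatrix(
            subjects=[self.subjects[i] for i in idx],
            visit_pair=self.visit_pair,
            X=self.X[rows],
            y=self.y[rows],
            feature_names=self.feature_names,
            block_index=self.block_index,
            excluded_subjects=list(self.excluded_subjects),
        )


def assemble_paired(
    cohort: Cohort,
    blocks: list[str] | tuple[str, ...],
    visit_a: str,
    visit_b: str,
) -> PairedMatrix:
    """Build the complete-case paired matrix for one visit pair.

    Subjects are retained only if every requested feature is observed at both
    visits; excluded subjects are recorded on the result. y is -1 for
    ``visit_a`` rows and +1 for ``visit_b`` rows.
    """
    for v in (visit_a, visit_b):
        if v not in cohort.visits:
            raise KeyError(f"visit {v!r} not present in cohort (has {cohort.visits})")
    for b in blocks:
        if b not in cohort.blocks:
            raise KeyError(f"block {b!r} not present in cohort (has {cohort.block_names})")

    feature_names: list[str] = []
    block_index: list[str] = []
    for b in blocks:
        for col in cohort.blocks[b].columns:
            feature_names.append(col)
            block_index.append(b)

    kept: list[str] = []
    excluded: list[str] = []
    rows: list[np.ndarray] = []
    for subject in cohort.subjects:
        ok = True
        pair_rows = []
        for visit in (visit_a, visit_b):
            key = (subject, visit)
            vals = []
            for b in blocks:
                if key not in cohort.blocks[b].index:
                    ok = False
                    break
                if not bool(cohort.masks[b].loc[key].all()):
                    ok = False
                    break
                vals.append(cohort.blocks[b].loc[key].to_numpy(dtype=float))
            if not ok:
                break
            pair_rows.append(np.concatenate(vals))
        if ok:
            kept.append(subject)
            rows.extend(pair_rows)
        else:
            excluded.append(subject)

    if len(kept) < 2:
        raise InsufficientDataError(
            f"only {len(kept)} subject(s) complete for blocks {list(blocks)} at "
            f"({visit_a}, {visit_b}); need at least 2"
        )
    n = len(kept)
    return PairedMatrix(
        subjects=kept,
        visit_pair=(visit_a, visit_b),
        X=np.vstack(rows),
        y=np.tile([-1.0, 1.0], n),
        feature_names=feature_names,
        block_index=np.asarray(block_index, dtype=object),
        excluded_subjects=excluded,
    )


# ---------------------------------------------------------------------------
# Variation splitting
# ---------------------------------------------------------------------------


@dataclass
class MultilevelDecomposition:
    m: np.ndarray          # (p,) grand mean
    X_between: np.ndarray  # (2n, p) subject-mean deviations
    X_within: np.ndarray   # (2n, p) deviations from own subject mean


def split_variation(paired: PairedMatrix) -> MultilevelDecomposition:
    """Exact additive split X = 1 m' + X_between + X_within.

    With two visits the two within rows of a subject are negatives of each
    other: -(x_b - x_a)/2 and +(x_b - x_a)/2.
    """
    X = paired.X
    m = X.mean(axis=0)
    pair_means = _pair_means(X)
    X_between = pair_means - m[None, :]
    X_within = X - pair_means
    return MultilevelDecomposition(m=m, X_between=X_between, X_within=X_within)


def _pair_means(X: np.ndarray) -> np.ndarray:
    """Per-subject mean repeated over each subject's two consecutive rows."""
    if X.shape[0] % 2:
        raise ValueError("paired matrix must have an even number of rows")
    means = X.reshape(-1, 2, X.shape[1]).mean(axis=1)
    return np.repeat(means, 2, axis=0)


def within_parts(X_rows: np.ndarray) -> np.ndarray:
    """Within-subject parts of raw paired rows, from each pair's own mean.

    Used for held-out subjects: needs neither class labels nor training rows,
    which is what keeps per-individual validation leakage-free.
    """
    return X_rows - _pair_means(X_rows)


# ---------------------------------------------------------------------------
# Scaling and block fusion
# ---------------------------------------------------------------------------


@dataclass
class ScalingModel:
    center: np.ndarray          # (p_kept,)
    scale: np.ndarray           # (p_kept,) > 0
    kept: np.ndarray            # (p,) bool, features retained
    feature_names: list[str]    # all p input names
    dropped: list[str]          # names of constant features removed
    block_weight: np.ndarray    # (p_kept,) 1/sqrt(features in block) or 1


def fit_scaling(
    X_train: np.ndarray,
    block_index: np.ndarray,
    autoscale: bool = True,
    block_weight: bool = True,
    feature_names: list[str] | None = None,
) -> ScalingModel:
    """Learn per-feature center/scale and per-block fusion weights.

    Centering and (with ``autoscale``) unit-variance scaling use training rows
    only; features constant in training are dropped and recorded. Block
    weighting divides each feature by sqrt(retained features in its block) so
    a 32-sensor array cannot swamp a 1-feature block in the fused model.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] == 0:
        raise InsufficientDataError("fit_scaling needs a non-empty 2-D training matrix")
    p = X_train.shape[1]
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    sd = X_train.std(axis=0, ddof=1) if X_train.shape[0] > 1 else np.zeros(p)
    ptp = X_train.max(axis=0) - X_train.min(axis=0)
    kept = (sd > 0) & (ptp > 0)
    if not kept.any():
        raise DegenerateDataError("all features are constant in training; nothing to fit")
    center = X_train.mean(axis=0)[kept]
    scale = sd[kept] if autoscale else np.ones(int(kept.sum()))
    blocks_kept = np.asarray(block_index)[kept]
    if block_weight:
        counts = pd.Series(blocks_kept).groupby(blocks_kept).transform("size").to_numpy()
        weights = 1.0 / np.sqrt(counts.astype(float))
    else:
        weights = np.ones(int(kept.sum()))
    return ScalingModel(
        center=center,
        scale=scale,
        kept=kept,
        feature_names=names,
        dropped=[names[j] for j in np.flatnonzero(~kept)],
        block_weight=weights,
    )


def apply_scaling(model: ScalingModel, X: np.ndarray) -> np.ndarray:
    """Apply training centering/scaling/weighting; drops the same features."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.kept.size:
        raise FeatureMismatchError(
            f"expected {model.kept.size} features, got {X.shape[1]}"
        )
    Z = (X[:, model.kept] - model.center) / model.scale
    return Z * model.block_weight


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS, single y column)
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    n_components: int        # requested
    achieved: int            # components actually extracted
    W: np.ndarray            # (p, A) X-weights, unit norm columns
    P: np.ndarray            # (p, A) X-loadings
    q: np.ndarray            # (A,) y-loadings
    T: np.ndarray            # (n, A) training scores
    scaling: ScalingModel | None = None

    @property
    def rotation(self) -> np.ndarray:
        """R = W (P'W)^-1 so that scores = X R for any X in model space."""
        A = self.achieved
        return self.W[:, :A] @ np.linalg.inv(self.P[:, :A].T @ self.W[:, :A])


def fit_pls_da(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    scaling: ScalingModel | None = None,
    tol: float = 1e-12,
) -> PLSModel:
    """Sequential NIPALS extraction with deflation on centered/scaled input.

    X is expected already centered (within-subject matrices are exactly
    column-centered by construction) and scaled. Extraction stops early, with
    the achieved count recorded, once the deflated cross-covariance or score
    norm underflows — i.e. when ``n_components`` exceeds the numerical rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    n, p = X.shape
    ref = max(1.0, float(np.abs(X).max()))
    Xa, ya = X.copy(), y.copy()
    Ws, Ps, qs, Ts = [], [], [], []
    for _ in range(n_components):
        w = Xa.T @ ya
        wn = np.linalg.norm(w)
        if wn <= tol * ref * n:
            break
        w = w / wn
        t = Xa @ w
        tt = float(t @ t)
        if tt <= (tol * ref) ** 2 * n:
            break
        pvec = Xa.T @ t / tt
        qval = float(ya @ t / tt)
        Xa = Xa - np.outer(t, pvec)
        ya = ya - qval * t
        Ws.append(w)
        Ps.append(pvec)
        qs.append(qval)
        Ts.append(t)
    if not Ws:
        raise DegenerateDataError("no PLS component extractable (X'y is numerically zero)")
    return PLSModel(
        n_components=n_components,
        achieved=len(Ws),
        W=np.column_stack(Ws),
        P=np.column_stack(Ps),
        q=np.asarray(qs),
        T=np.column_stack(Ts),
        scaling=scaling,
    )


def project(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Scores of new (already scaled) rows under the fitted model."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.W.shape[0]:
        raise FeatureMismatchError(
            f"model expects {model.W.shape[0]} features, got "
            f"{X_new.shape[1] if X_new.ndim == 2 else 'non-matrix input'}"
        )
    return X_new @ model.rotation
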