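"""Univariate within-group testing cascade and pooled Pearson correlations.

The cascade mirrors common practice in small crossover studies: a
D'Agostino-Pearson omnibus normality check routes each feature either to
repeated-measures ANOVA (normal) or the Friedman test (non-normal) across the
visits; only if the overall p is significant are all pairwise paired t /
Wilcoxon signed-rank tests run. No multiple-testing adjustment is applied
anywhere — a deliberate, exploratory-study choice that trades type-I risk for
sensitivity, so downstream users must read the p-values accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .cohort import Cohort
from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "UnivariateResult",
    "CorrelationMatrix",
    "test_cascade",
    "overall_test",
    "paired_test",
    "correlations",
    "summarize",
    "cascade_report",
]


@dataclass
class UnivariateResult:
    feature: str
    normality_p: float
    normal: bool
    test_name: str                       # "rm_anova" or "friedman"
    overall_stat: float
    overall_p: float
    pairwise_p: dict[tuple[str, str], float]   # empty unless overall_p < alpha
    pairwise_test: str                   # "paired_t" or "wilcoxon"
    summaries: dict[str, dict[str, float]]     # visit -> summary stats
    n_subjects: int = 0


@dataclass
class CorrelationMatrix:
    labels: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    degenerate: list[str] = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (one row per unordered pair), heatmap-ready."""
        rows = []
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1:]:
                rows.append(
                    {
                        "feature_a": a,
                        "feature_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "n": int(self.n.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows)


def _wide_values(values: pd.DataFrame) -> pd.DataFrame:
    """Complete-case subjects x visits table."""
    wide = values.dropna(axis=0, how="any")
    if wide.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 complete subjects, got {wide.shape[0]}"
        )
    return wide


def test_cascade(
    values: pd.DataFrame,
    alpha: float = 0.05,
    normality_on: str = "residuals",
    feature: str = "",
) -> UnivariateResult:
    """Run the normality-routed overall + pairwise cascade on one feature.

    ``values`` is a subjects x visits table (NaN = missing; incomplete
    subjects are dropped). ``normality_on`` is ``"residuals"`` (two-way
    residuals after removing subject and visit means, the default) or
    ``"pooled"`` (raw pooled values).
    """
    wide = _wide_values(values)
    X = wide.to_numpy(dtype=float)
    visits = list(wide.columns)
    if np.ptp(X) == 0.0:
        raise DegenerateDataError("all values identical; tests undefined")

    if normality_on == "residuals":
        resid = X - X.mean(axis=1, keepdims=True) - X.mean(axis=0, keepdims=True) + X.mean()
    elif normality_on == "pooled":
        resid = X - X.mean()
    else:
        raise ValueError("normality_on must be 'residuals' or 'pooled'")
    if np.ptp(resid) == 0.0:
        # no residual variation (e.g. pure subject + visit structure): treat as normal
        normality_p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p = float(sps.normaltest(resid.ravel())[1])
    normal = normality_p >= alpha

    test_name, overall_stat, overall_p = overall_test(X, normal=normal)
    pairwise_test = "paired_t" if normal else "wilcoxon"

    pairwise_p: dict[tuple[str, str], float] = {}
    if overall_p < alpha:
        for i, j in combinations(range(len(visits)), 2):
            _, pval = paired_test(X[:, i], X[:, j], normal=normal)
            pairwise_p[(visits[i], visits[j])] = pval

    summaries = {
        visit: summarize(X[:, j], normal=normal) for j, visit in enumerate(visits)
    }
    return UnivariateResult(
        feature=feature,
        normality_p=normality_p,
        normal=normal,
        test_name=test_name,
        overall_stat=overall_stat,
        overall_p=overall_p,
        pairwise_p=pairwise_p,
        pairwise_test=pairwise_test,
        summaries=summaries,
        n_subjects=wide.shape[0],
    )


def overall_test(X: np.ndarray, normal: bool) -> tuple[str, float, float]:
    """Overall within-group test on a complete subjects x visits array.

    Normal route: one-way repeated-measures ANOVA (no sphericity correction).
    Non-normal route: Friedman rank test. Returns (name, statistic, p).
    """
    X = np.asarray(X, dtype=float)
    if normal:
        wide = pd.DataFrame(X, columns=[f"v{j}" for j in range(X.shape[1])])
        long = wide.reset_index(names="subject").melt(
            id_vars="subject", var_name="visit", value_name="value"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = AnovaRM(long, depvar="value", subject="subject", within=["visit"]).fit()
        row = res.anova_table.iloc[0]
        return "rm_anova", float(row["F Value"]), float(row["Pr > F"])
    stat, p = sps.friedmanchisquare(*(X[:, j] for j in range(X.shape[1])))
    return "friedman", float(stat), float(p)


def paired_test(a: np.ndarray, b: np.ndarray, normal: bool) -> tuple[float, float]:
    """Two-visit paired test: paired t (normal) or Wilcoxon signed rank.

    The Wilcoxon statistic follows the min(W+, W-) convention on midranks of
    the absolute differences. Returns (statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if normal:
        stat, p = sps.ttest_rel(a, b)
        return float(stat), float(p)
    if np.all(a == b):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.wilcoxon(a, b)
    return float(stat), float(p)


def summarize(values: np.ndarray, normal: bool = True) -> dict[str, float]:
    """Per-visit summary: mean +- SEM (normal) or median with IQR and MAD."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise InsufficientDataError("summary needs >= 2 values")
    if normal:
        return {
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(v.size)),
        }
    q25, q75 = np.percentile(v, [25, 75])
    return {
        "median": float(np.median(v)),
        "iqr_low": float(q25),
        "iqr_high": float(q75),
        "mad": float(sps.median_abs_deviation(v, scale=1.0)),
    }


# ---------------------------------------------------------------------------
# Correlations (pooled over all visits, pairwise-complete)
# ---------------------------------------------------------------------------


def correlations(
    cohort: Cohort,
    features: list[tuple[str, str]] | None = None,
    min_n: int = 3,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson r (+ two-sided p) over all pooled samples.

    Repeated measures from the same subject enter as independent observations
    — statistically naive by design, but it is the pooled-sample heatmap
    convention this package reproduces. Zero-variance features are flagged and
    their pairs left NaN rather than fabricated.
    """
    if features is None:
        features = [
            (block, feat)
            for block, df in cohort.blocks.items()
            for feat in df.columns
        ]
    labels = [f"{block}.{feat}" for block, feat in features]
    columns = {
        label: cohort.observed(block)[feat].to_numpy(dtype=float)
        for label, (block, feat) in zip(labels, features)
    }
    k = len(labels)
    r = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    p = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
    n = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    degenerate: list[str] = []
    for label, col in columns.items():
        obs = col[~np.isnan(col)]
        n.loc[label, label] = obs.size
        if obs.size and np.ptp(obs) == 0.0:
            degenerate.append(label)
            r.loc[label, label] = np.nan
            p.loc[label, label] = np.nan
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa, xb = columns[a], columns[b]
            ok = ~np.isnan(xa) & ~np.isnan(xb)
            n_pair = int(ok.sum())
            n.loc[a, b] = n.loc[b, a] = n_pair
            if n_pair < min_n or a in degenerate or b in degenerate or \
                    np.ptp(xa[ok]) == 0.0 or np.ptp(xb[ok]) == 0.0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = sps.pearsonr(xa[ok], xb[ok])
            r.loc[a, b] = r.loc[b, a] = float(rr)
            p.loc[a, b] = p.loc[b, a] = float(pp)
    return CorrelationMatrix(labels=labels, r=r, p=p, n=n, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Tabular report over a cohort
# ---------------------------------------------------------------------------


def cascade_report(cohort: Cohort, alpha: float = 0.05) -> pd.DataFrame:
    """Run the cascade for every feature of every block; one row per feature."""
    visits = cohort.visits
    rows = []
    for block, df in cohort.blocks.items():
        obs = cohort.observed(block)
        for feat in df.columns:
            wide = obs[feat].unstack("visit").reindex(columns=visits)
            try:
                res = test_cascade(wide, alpha=alpha, feature=feat)
            except (InsufficientDataError, DegenerateDataError) as exc:
                rows.append({"block": block, "feature": feat, "error": str(exc)})
                continue
            row: dict = {
                "block": block,
                "feature": feat,
                "n_subjects": res.n_subjects,
                "normality_p": res.normality_p,
                "test": res.test_name,
                "overall_p": res.overall_p,
            }
            for visit in visits:
                s = res.summaries[visit]
                if res.normal:
                    row[f"{visit}_mean"] = s["mean"]
                    row[f"{visit}_sem"] = s["sem"]
                else:
                    row[f"{visit}_median"] = s["median"]
                    row[f"{visit}_mad"] = s["mad"]
            for (va, vb), pval in res.pairwise_p.items():
                row[f"p_{va}_vs_{vb}"] = pval
            rows.append(row)
    return pd.DataFrame(rows)
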