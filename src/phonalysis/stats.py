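"""Cohort statistics for scalar voice biomarkers.

A single feature (MFCC2, Energy Ratio, ...) is evaluated as a scalar
test statistic: the ROC is the full threshold sweep, so the AUC equals
the normalized Mann-Whitney pair count (ties counted one half), with
percentile bootstrap confidence intervals stratified by class. Around
that sit the descriptive machinery: per-cell mean/SD tables, a
correlation screen of interpretable features against MFCC features, AIC
model selection over ordinary least-squares fits, and one-way ANOVA.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import InvalidLabels, RankDeficient

__all__ = [
    "RocResult",
    "ModelFit",
    "auc_scalar",
    "bootstrap_auc_ci",
    "correlation_screen",
    "ols_aic_select",
    "one_way_anova",
    "descriptive_table",
]


@dataclass
class RocResult:
    """AUC of a scalar statistic with a stratified percentile-bootstrap CI."""

    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_cases: int
    n_controls: int
    direction: str


@dataclass
class ModelFit:
    """One OLS fit in the model-selection sweep."""

    response: str
    factors: tuple[str, ...]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    rss: float
    n: int
    aic: float


def _split_classes(values, labels, positive_label):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive_label]
    neg = values[labels != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidLabels("both classes must be present")
    return pos, neg


def auc_scalar(values, labels, positive_label, direction: str = "positive_higher") -> float:
    """AUC of a scalar test statistic, from the full threshold sweep.

    Equals the normalized Mann-Whitney pair count: the fraction of
    (positive, negative) pairs where the positive value is higher
    (``positive_higher``) or lower (``positive_lower``), with tied
    pairs counted 0.5.
    """
    pos, neg = _split_classes(values, labels, positive_label)
    if direction == "positive_lower":
        pos, neg = -pos, -neg
    elif direction != "positive_higher":
        raise ValueError(f"unknown direction {direction!r}")
    combined = np.concatenate([pos, neg])
    ranks = scipy.stats.rankdata(combined)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def bootstrap_auc_ci(
    values,
    labels,
    positive_label,
    direction: str = "positive_higher",
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed=None,
) -> RocResult:
    """Stratified percentile-bootstrap CI for the scalar-statistic AUC.

    Cases and controls are resampled with replacement within class;
    the CI is the (alpha/2, 1 - alpha/2) percentile interval of the
    bootstrap AUC distribution. Deterministic under a fixed seed.
    """
    pos, neg = _split_classes(values, labels, positive_label)
    if min(len(pos), len(neg)) < 5:
        warnings.warn("fewer than 5 per class; bootstrap CI unreliable", stacklevel=2)
    point = auc_scalar(values, labels, positive_label, direction)
    sign = -1.0 if direction == "positive_lower" else 1.0
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    labs = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    for b in range(n_boot):
        bp = sign * rng.choice(sign * pos, size=len(pos), replace=True)
        bn = sign * rng.choice(sign * neg, size=len(neg), replace=True)
        boots[b] = auc_scalar(np.concatenate([bp, bn]), labs, 1.0, direction)
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return RocResult(
        auc=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        n_boot=n_boot,
        n_cases=len(pos),
        n_controls=len(neg),
        direction=direction,
    )


def correlation_screen(
    table: pd.DataFrame,
    mfcc_columns: list[str],
    other_columns: list[str],
    method: str = "spearman",
    threshold: float = 0.3,
) -> pd.DataFrame:
    """Correlations of interpretable features against MFCC features, screened.

    Computes the ``method`` ('pearson' or 'spearman') correlation of
    every other-column against every MFCC column and keeps the rows
    whose maximum |r| exceeds ``threshold``. Constant columns get
    correlation 0 with a warning. Returns a (screened other) x (MFCC)
    matrix.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if len(table) < 10:
        raise ValueError("need at least 10 rows for the correlation screen")
    sub = table[mfcc_columns + other_columns].astype(float)
    constant = [c for c in sub.columns if sub[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns set to zero correlation: {constant}", stacklevel=2)
    corr = sub.corr(method=method).fillna(0.0)
    for c in constant:
        corr.loc[c, :] = 0.0
        corr.loc[:, c] = 0.0
    mat = corr.loc[other_columns, mfcc_columns]
    keep = mat.abs().max(axis=1) > threshold
    return mat.loc[keep]


def _design_matrix(table: pd.DataFrame, factors: tuple[str, ...]):
    """Intercept + numeric/dummy-coded factor columns."""
    cols = [pd.Series(np.ones(len(table)), index=table.index, name="intercept")]
    for f in factors:
        col = table[f]
        if col.dtype.kind in "biufc":
            cols.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=f, drop_first=True).astype(float)
            for c in dummies.columns:
                cols.append(dummies[c])
    return pd.concat(cols, axis=1)


def _fit_ols(table: pd.DataFrame, response: str, factors: tuple[str, ...]) -> ModelFit:
    data = table[[response, *factors]].dropna() if factors else table[[response]].dropna()
    x = _design_matrix(data, factors)
    if np.linalg.matrix_rank(x.values) < x.shape[1]:
        raise RankDeficient(f"design matrix for factors {factors} is rank deficient")
    res = sm.OLS(data[response].astype(float), x).fit()
    n = int(res.nobs)
    rss = float(res.ssr)
    p = x.shape[1]  # estimated mean parameters incl. intercept
    aic = n * np.log(rss / n) + 2.0 * (p + 1)
    return ModelFit(
        response=response,
        factors=factors,
        coefficients=dict(res.params),
        p_values=dict(res.pvalues),
        rss=rss,
        n=n,
        aic=float(aic),
    )


def ols_aic_select(
    table: pd.DataFrame,
    response: str,
    candidate_factors: list[str],
    candidate_sets: list[tuple[str, ...]] | None = None,
) -> tuple[ModelFit, list[ModelFit]]:
    """AIC model selection over OLS fits on all subsets of the candidate factors.

    Each candidate factor set (by default every subset of
    ``candidate_factors``, including the intercept-only model) is fitted
    by least squares; AIC = n ln(RSS/n) + 2(p+1) where p counts the
    mean parameters. Returns the minimum-AIC fit and all fits.
    """
    if candidate_sets is None:
        candidate_sets = [
            tuple(c)
            for k in range(len(candidate_factors) + 1)
            for c in itertools.combinations(candidate_factors, k)
        ]
    fits = [_fit_ols(table, response, fs) for fs in candidate_sets]
    best = min(fits, key=lambda f: f.aic)
    return best, fits


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA over >= 2 groups: (F statistic, p value).

    The degenerate case of zero within-group variance with equal means
    returns F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    means = [g.mean() for g in groups]
    if within == 0.0 and np.allclose(means, means[0]):
        return 0.0, 1.0
    f, p = scipy.stats.f_oneway(*groups)
    return float(f), float(p)


def descriptive_table(
    table: pd.DataFrame,
    metrics: list[str],
    by: list[str] = ("dataset", "sex", "group"),
) -> pd.DataFrame:
    """Mean and SD of each metric per grouping cell, with cell n.

    One row per non-empty cell; columns ``<metric>_mean`` /
    ``<metric>_sd`` for each metric, plus ``n``. Empty cells are simply
    absent (a warning notes how many combinations were unpopulated).
    """
    by = list(by)
    grouped = table.groupby(by, observed=True)
    rows = []
    for key, cell in grouped:
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n"] = len(cell)
        for m in metrics:
            row[f"{m}_mean"] = float(cell[m].mean())
            row[f"{m}_sd"] = float(cell[m].std(ddof=0)) if len(cell) > 1 else 0.0
        rows.append(row)
    n_possible = int(np.prod([table[c].nunique() for c in by]))
    if len(rows) < n_possible:
        warnings.warn(f"{n_possible - len(rows)} empty cells omitted", stacklevel=2)
    return pd.DataFrame(rows)
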