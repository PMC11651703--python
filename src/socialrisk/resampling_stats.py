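"""Nonparametric pooled-bootstrap tests, robust correlation, null Bayes factors.

The testing framework builds a null distribution for each statistic by
resampling under exchangeability and reports a two-tailed p-value as the
fraction of null statistics whose absolute value meets or exceeds the
absolute observed statistic (ties count toward the null, which is the
conservative choice; the p-value is floored at 1/n_iter):

* group comparisons (t, F) — all values are pooled across groups, then
  resampled with replacement into pseudo-groups of the original sizes;
* association tests (Pearson r, regression slope) — the pairing is broken
  by resampling x and y independently;
* chi-squared — category labels are redrawn per group from the pooled
  category distribution.

``robust_correlation`` is a skipped Pearson correlation: bivariate outliers
are flagged by projecting every point onto the directions defined by each
point and the coordinatewise-median center and applying a boxplot rule on
each projection; the correlation is computed on the retained points and its
p-value comes from the unpaired bootstrap on those points.

``bayes_factor_null`` wraps the default-prior (JZS, Cauchy scale sqrt(2)/2)
Bayes factors and reports them in favor of the null (BF_null > 1 supports
no difference / no association).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BootstrapResult",
    "RobustCorrelationResult",
    "bootstrap_group_test",
    "bootstrap_association",
    "bootstrap_chi2",
    "robust_correlation",
    "bayes_factor_null",
    "residualize",
]


@dataclass
class BootstrapResult:
    kind: str
    observed: float
    null: np.ndarray = field(repr=False)
    n_iter: int
    seed: int | None

    @property
    def p_value(self) -> float:
        count = int(np.sum(np.abs(self.null) >= abs(self.observed)))
        return max(count, 1) / self.n_iter

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _as_groups(values_by_group) -> list[np.ndarray]:
    if isinstance(values_by_group, Mapping):
        groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_by_group]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    return groups


def _t_stat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t along the last axis."""
    n1, n2 = a.shape[-1], b.shape[-1]
    m1, m2 = a.mean(axis=-1), b.mean(axis=-1)
    v1, v2 = a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (m1 - m2) / denom, 0.0)


def _f_stat(groups: Sequence[np.ndarray]) -> np.ndarray:
    """One-way ANOVA F along the last axis of each group array."""
    k = len(groups)
    ns = np.array([g.shape[-1] for g in groups])
    n = ns.sum()
    means = np.stack([g.mean(axis=-1) for g in groups], axis=-1)
    grand = sum(g.sum(axis=-1) for g in groups) / n
    ss_between = np.sum(ns * (means - grand[..., None]) ** 2, axis=-1)
    ss_within = sum(((g - m[..., None]) ** 2).sum(axis=-1)
                    for g, m in zip(groups, np.moveaxis(means, -1, 0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return np.where(np.isfinite(f), f, 0.0)


def bootstrap_group_test(
    values_by_group,
    statistic: str = "t",
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> BootstrapResult:
    """Pooled-bootstrap group comparison (two-sample t or one-way F).

    All observations are pooled, resampled with replacement into groups of
    the original sizes, and the statistic recomputed each iteration.
    """
    groups = _as_groups(values_by_group)
    if statistic == "t" and len(groups) != 2:
        raise ValueError("t statistic requires exactly two groups")
    if rng is None:
        rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; test is degenerate, p = 1", stacklevel=2)
        return BootstrapResult(statistic, 0.0, np.zeros(n_iter), n_iter, seed)
    sizes = [len(g) for g in groups]
    resampled = [
        pooled[rng.integers(0, len(pooled), size=(n_iter, m))] for m in sizes
    ]
    if statistic == "t":
        observed = float(_t_stat(groups[0], groups[1]))
        null = _t_stat(resampled[0], resampled[1])
    elif statistic == "F":
        observed = float(_f_stat(groups))
        null = _f_stat(resampled)
    else:
        raise ValueError(f"unknown statistic {statistic!r}; use 't' or 'F'")
    return BootstrapResult(statistic, observed, np.asarray(null), n_iter, seed)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=-1) * (yc**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=-1) / denom
    return np.where(np.isfinite(r), r, 0.0)


def _slope_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    ssx = (xc**2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (xc * yc).sum(axis=-1) / ssx
    return np.where(np.isfinite(b), b, 0.0)


def bootstrap_association(
    x,
    y,
    statistic: str = "pearson",
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> BootstrapResult:
    """Unpaired-bootstrap test of association (Pearson r or regression slope).

    The null distribution breaks the pairing by drawing x and y values
    independently (with replacement) for each pseudo-subject.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(x)
    fn = {"pearson": _pearson_rows, "regression_beta": _slope_rows}.get(statistic)
    if fn is None:
        raise ValueError(f"unknown statistic {statistic!r}")
    observed = float(fn(x, y))
    xs = x[rng.integers(0, n, size=(n_iter, n))]
    ys = y[rng.integers(0, n, size=(n_iter, n))]
    return BootstrapResult(statistic, observed, fn(xs, ys), n_iter, seed)


def _chi2_stat(table: np.ndarray) -> np.ndarray:
    """Pearson chi-squared for (..., R, C) count tables."""
    rowsum = table.sum(axis=-1, keepdims=True)
    colsum = table.sum(axis=-2, keepdims=True)
    total = table.sum(axis=(-1, -2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rowsum * colsum / total
        chi2 = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0).sum(axis=(-1, -2))
    return chi2


def bootstrap_chi2(
    table,
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrapped chi-squared test for an R x C contingency table.

    Under the null, each group's category labels are redrawn from the pooled
    (margin) category distribution, keeping group sizes fixed.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be a 2-way contingency table")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = float(_chi2_stat(table))
    pooled = table.sum(axis=0) / table.sum()
    null_tables = np.stack(
        [rng.multinomial(int(row.sum()), pooled, size=n_iter) for row in table],
        axis=1,
    )  # (n_iter, R, C)
    return BootstrapResult("chi2", observed, _chi2_stat(null_tables), n_iter, seed)


@dataclass
class RobustCorrelationResult:
    r: float
    p_value: float
    n: int
    n_outliers: int
    retained: np.ndarray = field(repr=False)
    pearson_r: float = float("nan")   # plain Pearson on all points, for reference


def _skipped_outliers(x: np.ndarray, y: np.ndarray, whisker: float = 1.5) -> np.ndarray:
    """Projection-based bivariate outlier flags (boxplot rule per direction)."""
    pts = np.stack([x, y], axis=1)
    center = np.median(pts, axis=0)
    rel = pts - center
    norms = np.linalg.norm(rel, axis=1)
    out = np.zeros(len(pts), dtype=bool)
    for i in np.where(norms > 0)[0]:
        u = rel[i] / norms[i]
        proj = rel @ u
        q1, q3 = np.percentile(proj, [25, 75])
        iqr = q3 - q1
        out |= (proj < q1 - whisker * iqr) | (proj > q3 + whisker * iqr)
    return out


def robust_correlation(
    x,
    y,
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> RobustCorrelationResult:
    """Skipped Pearson correlation with an unpaired-bootstrap p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 4")
    outliers = _skipped_outliers(x, y)
    keep = ~outliers
    if keep.sum() < 4:
        raise ValueError("fewer than 4 points retained after outlier removal")
    r = float(_pearson_rows(x[keep], y[keep]))
    boot = bootstrap_association(x[keep], y[keep], "pearson", n_iter=n_iter, rng=rng, seed=seed)
    return RobustCorrelationResult(
        r=r,
        p_value=boot.p_value,
        n=int(keep.sum()),
        n_outliers=int(outliers.sum()),
        retained=keep,
        pearson_r=float(_pearson_rows(x, y)),
    )


def bayes_factor_null(kind: str, *data) -> float:
    """Default-prior JZS Bayes factor in favor of the null hypothesis.

    ``kind="ttest"`` takes two sample arrays (independent groups);
    ``kind="correlation"`` takes the two variables. Values above 1 favor
    "no difference" / "no association".
    """
    import pingouin as pg

    if kind == "ttest":
        a, b = (np.asarray(v, dtype=float) for v in data)
        t = float(_t_stat(a, b))
        bf10 = float(pg.bayesfactor_ttest(t, nx=len(a), ny=len(b), paired=False))
    elif kind == "correlation":
        x, y = (np.asarray(v, dtype=float) for v in data)
        r = float(_pearson_rows(x, y))
        bf10 = float(pg.bayesfactor_pearson(r, len(x)))
    else:
        raise ValueError(f"unknown kind {kind!r}; use 'ttest' or 'correlation'")
    return 1.0 / bf10


def residualize(y, covariates) -> np.ndarray:
    """OLS residuals of y on an intercept plus the covariate columns.

    Used to re-run group comparisons or correlations after controlling for
    nuisance variables (risk preference, age, cognitive-screen scores, ...).
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) != len(y):
        raise ValueError("y and covariates must have the same number of rows")
    X1 = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    return np.asarray(sm.OLS(y, X1).fit().resid)
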