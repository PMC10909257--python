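"""Validation figures of merit and statistical model comparison.

Covers the quantities a multivariate-calibration validation table reports:
per-sample recovery percentages with their mean and SD, RMSEC/RMSEP,
predicted-vs-nominal regression (slope, intercept, r), the Durbin-Watson
statistic on ordered prediction residuals with a permutation p-value, pooled
two-sample t and variance-ratio F tests against a reference method, and the
elliptical joint confidence region (EJCR) accuracy test for the (slope,
intercept) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RecoveryTable",
    "RegressionFOM",
    "ComparisonResult",
    "EJCRResult",
    "recovery_stats",
    "rmse",
    "durbin_watson",
    "regression_fom",
    "compare_methods",
    "ejcr",
]


@dataclass
class RecoveryTable:
    """Per-sample recovery % per analyte, with column mean / SD / RSD."""

    recovery: np.ndarray           # n_samples × n_analytes, percent
    mean: np.ndarray
    sd: np.ndarray                 # sample SD (n−1 denominator), percent points
    rsd: np.ndarray                # 100 · sd / mean
    analytes: tuple | None = None


@dataclass
class RegressionFOM:
    """Predicted-vs-nominal regression and error figures for one analyte."""

    slope: float
    intercept: float
    r: float
    rmsec: float | None
    rmsep: float | None
    dw: float | None
    dw_p: float | None


@dataclass
class ComparisonResult:
    """Pooled t and variance-ratio F between two methods' recovery sets."""

    t_stat: float
    t_crit: float
    f_stat: float
    f_crit: float
    means: tuple
    sds: tuple
    ns: tuple
    t_significant: bool
    f_significant: bool
    df_t: int


@dataclass
class EJCRResult:
    """Elliptical joint confidence region for (intercept, slope)."""

    intercept: float
    slope: float
    shape: np.ndarray              # XᵀX of the design [1, nominal]
    s2: float
    f_crit: float
    n: int
    alpha: float
    contains_ideal: bool

    def quadratic_form(self, intercept: float, slope: float) -> float:
        d = np.array([self.intercept - intercept, self.slope - slope])
        return float(d @ self.shape @ d)

    def contains(self, intercept: float, slope: float, atol: float = 1e-10) -> bool:
        return self.quadratic_form(intercept, slope) <= 2.0 * self.s2 * self.f_crit + atol

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """(intercept, slope) points on the confidence-ellipse boundary."""
        radius2 = 2.0 * self.s2 * self.f_crit
        L = np.linalg.cholesky(np.linalg.inv(self.shape) * radius2)
        theta = np.linspace(0.0, 2.0 * np.pi, n_points)
        circle = np.vstack([np.cos(theta), np.sin(theta)])
        return (np.array([self.intercept, self.slope])[:, None] + L @ circle).T


def recovery_stats(found, nominal, analytes=None) -> RecoveryTable:
    """Recovery % table: 100·found/nominal, column mean and sample SD."""
    found = np.atleast_2d(np.asarray(found, dtype=float))
    nominal = np.atleast_2d(np.asarray(nominal, dtype=float))
    if found.shape != nominal.shape:
        raise ValueError("found and nominal must have the same shape")
    if np.any(nominal <= 0):
        raise ValueError("nominal concentrations must be > 0")
    rec = 100.0 * found / nominal
    mean = rec.mean(axis=0)
    sd = rec.std(axis=0, ddof=1) if rec.shape[0] > 1 else np.zeros(rec.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    return RecoveryTable(rec, mean, sd, rsd, analytes)


def rmse(found, reference) -> np.ndarray | float:
    """Root mean squared error, √(Σ(found−ref)²/n); per column for 2-D input."""
    found = np.asarray(found, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if found.shape != reference.shape:
        raise ValueError("found and reference must have the same shape")
    err2 = (found - reference) ** 2
    if found.ndim <= 1:
        return float(np.sqrt(err2.mean()))
    return np.sqrt(err2.mean(axis=0))


def _dw_stat(e: np.ndarray) -> float:
    return float(np.sum(np.diff(e) ** 2) / np.sum(e * e))


def durbin_watson(
    residuals,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Durbin-Watson statistic and a permutation p-value.

    DW = Σ(eᵢ−eᵢ₋₁)²/Σeᵢ² on residuals in their given order (order them by
    ascending nominal concentration for a predicted-vs-nominal fit). The
    p-value is the two-sided permutation probability of a departure from 2 at
    least as large as observed, under random reshuffling of the residual
    order (add-one convention, seeded).
    """
    e = np.asarray(residuals, dtype=float).ravel()
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.all(e == 0):
        raise ValueError("Durbin-Watson is undefined for all-zero residuals")
    dw = _dw_stat(e)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(e, (n_permutations, 1)), axis=1)
    num = np.sum(np.diff(perms, axis=1) ** 2, axis=1)
    dw_perm = num / np.sum(e * e)
    p = (1.0 + np.count_nonzero(np.abs(dw_perm - 2.0) >= abs(dw - 2.0))) / (
        n_permutations + 1.0
    )
    return dw, float(p)


def regression_fom(
    predicted,
    nominal,
    calibration_errors=None,
    dw_permutations: int = 10_000,
    dw_seed: int = 0,
) -> RegressionFOM:
    """Slope/intercept/r, RMSEP (and RMSEC if given), DW on ordered residuals.

    ``predicted``/``nominal`` are the validation-set values for one analyte;
    residuals are ordered by ascending nominal concentration before the
    Durbin-Watson statistic is computed. ``calibration_errors`` is the
    (found − nominal) vector of the calibration set, if RMSEC is wanted.
    """
    y = np.asarray(predicted, dtype=float).ravel()
    x = np.asarray(nominal, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise ValueError("nominal values are degenerate (all equal)")
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    rmsep = float(np.sqrt(np.mean((y - x) ** 2)))
    rmsec = None
    if calibration_errors is not None:
        ce = np.asarray(calibration_errors, dtype=float).ravel()
        rmsec = float(np.sqrt(np.mean(ce ** 2)))
    order = np.argsort(x, kind="stable")
    resid = (y - (intercept + slope * x))[order]
    if np.allclose(resid, 0):
        dw_val, dw_p = None, None
    else:
        dw_val, dw_p = durbin_watson(resid, n_permutations=dw_permutations, seed=dw_seed)
    return RegressionFOM(float(slope), float(intercept), r, rmsec, rmsep, dw_val, dw_p)


def _group_stats(group) -> tuple[float, float, int]:
    if isinstance(group, tuple) and len(group) == 3:
        mean, sd, n = group
        return float(mean), float(sd), int(n)
    g = np.asarray(group, dtype=float).ravel()
    if g.size < 2:
        raise ValueError("each group needs n >= 2")
    return float(g.mean()), float(g.std(ddof=1)), int(g.size)


def compare_methods(group1, group2, alpha: float = 0.05) -> ComparisonResult:
    """Pooled-variance two-sample t and variance-ratio F between two methods.

    Groups may be raw recovery values or ``(mean, sd, n)`` summaries. F is
    the larger over the smaller variance (so F ≥ 1) with the two-sided
    critical value at ``alpha``; the t critical value is two-sided at
    ``n1 + n2 − 2`` degrees of freedom.
    """
    m1, s1, n1 = _group_stats(group1)
    m2, s2, n2 = _group_stats(group2)
    v1, v2 = s1 * s1, s2 * s2
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t_stat = 0.0 if denom == 0 else (m1 - m2) / denom
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    if v1 >= v2:
        f_stat = np.inf if v2 == 0 else v1 / v2
        dfn, dfd = n1 - 1, n2 - 1
    else:
        f_stat = np.inf if v1 == 0 else v2 / v1
        dfn, dfd = n2 - 1, n1 - 1
    f_crit = float(stats.f.ppf(1.0 - alpha / 2.0, dfn, dfd))
    return ComparisonResult(
        t_stat=float(t_stat),
        t_crit=t_crit,
        f_stat=float(f_stat),
        f_crit=f_crit,
        means=(m1, m2),
        sds=(s1, s2),
        ns=(n1, n2),
        t_significant=abs(t_stat) > t_crit,
        f_significant=f_stat > f_crit,
        df_t=df,
    )


def ejcr(predicted, nominal, alpha: float = 0.05) -> EJCRResult:
    """Elliptical joint confidence region of the predicted-vs-nominal line.

    OLS of predicted on nominal gives (â, b̂); the 100(1−α)% joint region is
    {(a, b) : (β̂−β)ᵀ XᵀX (β̂−β) ≤ 2 s² F(2, n−2, 1−α)} with X = [1, nominal]
    and s² the residual variance. Accuracy holds when the ideal point
    (intercept 0, slope 1) lies inside.
    """
    y = np.asarray(predicted, dtype=float).ravel()
    x = np.asarray(nominal, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("EJCR needs at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("nominal values are degenerate (all equal)")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - 2)
    f_crit = float(stats.f.ppf(1.0 - alpha, 2, n - 2))
    result = EJCRResult(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        shape=X.T @ X,
        s2=s2,
        f_crit=f_crit,
        n=n,
        alpha=alpha,
        contains_ideal=False,
    )
    result.contains_ideal = result.contains(0.0, 1.0)
    return result
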