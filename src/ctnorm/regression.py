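"""Ordinary-least-squares helpers shared by the normalization methods.

Simple regressions (one regressor) are fitted with ``scipy.stats.linregress``
and multiple regressions with ``statsmodels`` OLS.  Both paths return the
same :class:`RegressionFit` record carrying slopes, standard errors, two-sided
slope p-values, residual degrees of freedom and R².

Fitting is always pairwise/casewise complete: rows with a missing response or
regressor are dropped before the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    CollinearityError,
    DegenerateFitWarning,
    DegenerateRegressorError,
    InsufficientDataError,
    OverfitError,
    SmallSampleWarning,
)

__all__ = ["RegressionFit", "fit_simple_regression", "fit_multiple_regression"]

# relative residual tolerance below which a fit counts as zero-residual
_ZERO_RESID_RTOL = 1e-12


@dataclass
class RegressionFit:
    """Result of an OLS fit of a response on one or more regressors.

    ``slopes``/``se``/``p`` are aligned with ``regressors``.  The intercept is
    always estimated; normalization never subtracts it (group comparisons are
    invariant to a per-gene constant).
    """

    regressors: list[str]
    slopes: np.ndarray
    intercept: float
    se: np.ndarray
    p: np.ndarray
    residual_df: int
    r2: float
    n_used: int

    @property
    def slope(self) -> float:
        """The slope of a single-regressor fit."""
        if len(self.slopes) != 1:
            raise ValueError("slope is only defined for single-regressor fits")
        return float(self.slopes[0])

    def coefficients(self) -> pd.Series:
        return pd.Series(self.slopes, index=self.regressors)


def _complete(y, x):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    return y[keep], x[keep]


def fit_simple_regression(y, x, name: str = "x") -> RegressionFit:
    """OLS of ``y`` on ``x`` with intercept, on pairwise-complete pairs.

    The slope p-value is the two-sided t test of b = 0.  Two degenerate cases
    are handled explicitly because the t statistic is undefined when the
    residual variance is zero:

    * exact collinearity of ``y`` with ``x`` (nonzero slope, zero residuals)
      → p = 0, with a :class:`DegenerateFitWarning`;
    * constant ``y`` (slope exactly 0, zero residuals) → p = 1.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 complete pairs.
    DegenerateRegressorError
        ``x`` has zero variance among the complete pairs.
    """
    y, x = _complete(y, x)
    n = len(y)
    if n < 3:
        raise InsufficientDataError(
            f"simple regression needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateRegressorError("regressor has zero variance")

    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    b = sxy / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - ym) ** 2))
    df = n - 2

    if ss_tot == 0.0:
        # constant response: slope is exactly 0, nothing to test
        return RegressionFit([name], np.array([0.0]), float(ym),
                             np.array([0.0]), np.array([1.0]), df, 1.0, n)
    r2 = 1.0 - ss_res / ss_tot
    if ss_res <= _ZERO_RESID_RTOL * ss_tot:
        if b == 0.0:
            p = np.array([1.0])
        else:
            warnings.warn("zero-residual fit: y is perfectly collinear with x; "
                          "slope p-value set to 0", DegenerateFitWarning,
                          stacklevel=2)
            p = np.array([0.0])
        return RegressionFit([name], np.array([b]), float(a),
                             np.array([0.0]), p, df, 1.0, n)

    se = np.sqrt(ss_res / df / sxx)
    from scipy import stats
    t = b / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return RegressionFit([name], np.array([b]), float(a),
                         np.array([se]), np.array([p]), df, r2, n)


def _find_collinear(X: np.ndarray, names) -> list[str]:
    """Columns of X (with intercept prepended) lying in the span of earlier ones."""
    ones = np.ones((X.shape[0], 1))
    offenders = []
    prev = ones
    for j, name in enumerate(names):
        cand = np.hstack([prev, X[:, [j]]])
        if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(prev):
            offenders.append(name)
        else:
            prev = cand
    return offenders


def fit_multiple_regression(y, X: pd.DataFrame) -> RegressionFit:
    """OLS of ``y`` on every column of ``X`` with intercept, complete cases.

    Raises
    ------
    OverfitError
        Fewer complete cases than regressors + 2 (no residual df).
    CollinearityError
        Rank-deficient regressor matrix; the offending columns are named.
    InsufficientDataError
        Fewer than 3 complete cases.
    """
    names = list(X.columns)
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    keep = ~(np.isnan(y) | np.isnan(Xv).any(axis=1))
    y, Xv = y[keep], Xv[keep]
    n, k = Xv.shape
    if n < 3:
        raise InsufficientDataError(
            f"multiple regression needs >= 3 complete cases, got {n}")
    if n < k + 2:
        raise OverfitError(
            f"{n} complete cases cannot support {k} regressors + intercept "
            "with at least 1 residual df (model would over-fit)")
    design = np.column_stack([np.ones(n), Xv])
    if np.linalg.matrix_rank(design) < k + 1:
        offenders = _find_collinear(Xv, names)
        raise CollinearityError(
            f"collinear reference genes: {offenders}", offenders)
    if n < 3 * k:
        warnings.warn(
            f"only {n} complete cases for {k} regressors; multiple-regression "
            "coefficients may be unstable", SmallSampleWarning, stacklevel=2)
    res = sm.OLS(y, sm.add_constant(pd.DataFrame(Xv, columns=names))).fit()
    params = np.asarray(res.params)
    return RegressionFit(
        regressors=names,
        slopes=params[1:],
        intercept=float(params[0]),
        se=np.asarray(res.bse)[1:],
        p=np.asarray(res.pvalues)[1:],
        residual_df=int(res.df_resid),
        r2=float(res.rsquared),
        n_used=n,
    )
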