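"""Regression primitives: OLS, reduced major axis (model II), Spearman, NLS.

Everything downstream (power-law allometries, Y-N curve fits, the
two-model growth comparison) is expressed in terms of these five
operations so that fitting conventions — confidence-interval formulas,
convergence flags, adjusted r² — live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LinearFit",
    "NLSFit",
    "ols",
    "rma",
    "spearman",
    "nls_fit",
    "adjusted_r2",
]


@dataclass(frozen=True)
class LinearFit:
    """A fitted straight line y = slope * x + intercept.

    ``method`` records whether the slope is the ordinary least-squares
    estimate ("OLS") or the reduced-major-axis estimate ("RMA",
    sign(r) * sd(y)/sd(x)).  ``slope_ci95`` is the two-sided 95%
    confidence interval for the slope under the respective method.
    """

    slope: float
    intercept: float
    r: float
    r2: float
    adj_r2: float
    slope_ci95: tuple[float, float]
    n: int
    method: str

    def __post_init__(self) -> None:
        if not np.isclose(self.r2, self.r * self.r, atol=1e-12):
            raise ValueError("r2 must equal r*r")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "slope_ci95": list(self.slope_ci95),
            "n": self.n,
            "method": self.method,
        }


@dataclass(frozen=True)
class NLSFit:
    """Result of a nonlinear least-squares fit."""

    params: tuple[float, ...]
    rss: float
    converged: bool
    n_iter: int
    r2: float
    adj_r2: float

    def to_dict(self) -> dict:
        return {
            "params": list(self.params),
            "rss": self.rss,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
        }


def _validate_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y


def adjusted_r2(ss_res: float, ss_tot: float, n: int, p: int) -> float:
    """r² penalised for the number of predictors p.

    1 − (1 − r²)(n − 1)/(n − 1 − p).  With p = 0 this is plain r²,
    the convention used for plug-in curves whose parameters were all
    estimated upstream rather than fitted to the response.
    """
    if ss_tot <= 0:
        raise ValueError("ss_tot must be positive")
    if n <= p + 1:
        raise ValueError(f"adjusted r2 undefined for n={n}, p={p}")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - p)


def ols(x, y) -> LinearFit:
    """Ordinary least squares with a t-based 95% slope CI (n − 2 df)."""
    x, y = _validate_xy(x, y)
    if np.var(x) == 0:
        raise ValueError("x is constant; OLS slope undefined")
    res = stats.linregress(x, y)
    n = x.size
    resid = y - (res.slope * x + res.intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:  # y constant: flat line fits exactly
        r, r2, adj = 0.0, 0.0, 0.0
    else:
        r = float(res.rvalue)
        r2 = r * r
        adj = adjusted_r2(ss_res, ss_tot, n, 1)
    tq = stats.t.ppf(0.975, n - 2)
    half = tq * res.stderr
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        r2=r2,
        adj_r2=adj,
        slope_ci95=(float(res.slope - half), float(res.slope + half)),
        n=n,
        method="OLS",
    )


def rma(x, y) -> LinearFit:
    """Reduced major axis (standardised/geometric-mean) regression.

    slope = sign(r) * sd(y)/sd(x); the 95% CI uses the standard
    model-II formula: with B = F_0.95(1, n−2) * (1 − r²)/(n − 2) the
    bounds are slope * (sqrt(B + 1) ± sqrt(B)).
    """
    x, y = _validate_xy(x, y)
    n = x.size
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("RMA requires variance in both variables")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    fq = stats.f.ppf(0.95, 1, n - 2)
    bq = fq * (1.0 - r * r) / (n - 2)
    lo = slope * (np.sqrt(bq + 1.0) - np.sqrt(bq))
    hi = slope * (np.sqrt(bq + 1.0) + np.sqrt(bq))
    ci = (float(min(lo, hi)), float(max(lo, hi)))
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return LinearFit(
        slope=float(slope),
        intercept=intercept,
        r=r,
        r2=r * r,
        adj_r2=adjusted_r2(ss_res, ss_tot, n, 1) if ss_tot > 0 else 0.0,
        slope_ci95=ci,
        n=n,
        method="RMA",
    )


def spearman(u, v) -> float:
    """Spearman rank correlation ρ with midrank ties."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    if u.size < 2:
        raise ValueError("need at least 2 observations")
    return float(stats.spearmanr(u, v).statistic)


def nls_fit(
    model: Callable[[np.ndarray, np.ndarray], np.ndarray],
    x,
    y,
    init: Sequence[float],
    bounds=None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> NLSFit:
    """Unweighted nonlinear least squares min_p Σ(y − model(p, x))².

    Uses a damped Gauss–Newton scheme (Levenberg–Marquardt without
    bounds, trust-region reflective with) with a finite-difference
    Jacobian.  Non-convergence within ``max_iter`` function
    evaluations is flagged, not raised: the best point found is
    returned with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    init = np.asarray(init, dtype=float)

    def residuals(p):
        return np.asarray(model(p, x), dtype=float) - y

    kwargs = dict(xtol=tol, ftol=tol, gtol=tol, max_nfev=max_iter)
    if bounds is not None:
        res = optimize.least_squares(residuals, init, bounds=bounds, method="trf", **kwargs)
    else:
        res = optimize.least_squares(residuals, init, method="lm", **kwargs)
    rss = float(2.0 * res.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    p = init.size
    n = y.size
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")
    adj = adjusted_r2(rss, ss_tot, n, p) if (ss_tot > 0 and n > p + 1) else float("nan")
    return NLSFit(
        params=tuple(float(v) for v in res.x),
        rss=rss,
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
        r2=r2,
        adj_r2=adj,
    )
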