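"""Size-structure growth model built on the Y-N cumulative-biomass curve.

The stand's size hierarchy is summarised by

    Y(N) = N / (A N + B)

where Y is the cumulative aboveground biomass of the N largest trees
and N the rank from the largest (1/A is the asymptotic stand biomass
Ymax, 1/B the maximum individual biomass Mmax).  Differentiating gives
the biomass of the rank-N tree, M(N) = B / (A N + B)^2.  Holding a
tree's rank fixed while (A, B) evolve between censuses yields a
closed-form biomass projection; combining it with the B = K3 * A^c
scaling between the two curve parameters and the M = K4 * D^(8/3)
diameter allometry turns the projection into a diameter growth curve
that can be compared, on (D0^(2/3), DT^(2/3)) axes, against the
metabolic-scaling prediction DT^(2/3) = D0^(2/3) + k of slope one.

All biomasses are kg summed per plot (not per hectare): the magnitudes
of A and B depend on this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import regression
from .allometry import DIAMETER_EXPONENT

__all__ = [
    "YNFit",
    "ABScalingFit",
    "GrowthModelParams",
    "EnquistModel",
    "StandAllometryFit",
    "cumulative_curve",
    "yn_value",
    "fit_yn",
    "individual_biomass",
    "rank_from_biomass",
    "project_biomass",
    "project_biomass_scaled",
    "project_diameter",
    "growth_rate_curve",
    "fit_ab_scaling",
    "enquist_project",
    "fit_enquist_rate",
]


@dataclass(frozen=True)
class YNFit:
    """Estimated Y-N curve for one census.

    A is the reciprocal of asymptotic stand biomass (kg^-1), B the
    reciprocal of maximum individual biomass (kg^-1).
    """

    A: float
    B: float
    n: int
    rss: float
    r2: float
    converged: bool

    @property
    def ymax(self) -> float:
        return 1.0 / self.A

    @property
    def mmax(self) -> float:
        return 1.0 / self.B

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "B": self.B,
            "n": self.n,
            "rss": self.rss,
            "r2": self.r2,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class ABScalingFit:
    """B = K3 * A^c scaling between the Y-N curve parameters."""

    K3: float
    c: float
    fit: regression.LinearFit | None  # log-log diagnostics; None for 2-point exact solve

    def __post_init__(self) -> None:
        if self.K3 <= 0:
            raise ValueError("K3 must be positive")

    def predict_b(self, a):
        return self.K3 * np.asarray(a, dtype=float) ** self.c

    def to_dict(self) -> dict:
        return {
            "K3": self.K3,
            "c": self.c,
            "fit": self.fit.to_dict() if self.fit is not None else None,
        }


@dataclass(frozen=True)
class GrowthModelParams:
    """Plug-in parameter bundle that fully determines the growth curves.

    A0/AT come from the first/last census Y-N fits, (K3, c) from the
    B-A scaling fit, K4 (kg cm^-8/3) from the diameter allometry, and
    delta_t (years) is the census span.
    """

    A0: float
    AT: float
    K3: float
    c: float
    K4: float
    delta_t: float

    def __post_init__(self) -> None:
        for name in ("A0", "AT", "K3", "K4", "delta_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def B0(self) -> float:
        return self.K3 * self.A0**self.c

    @property
    def BT(self) -> float:
        return self.K3 * self.AT**self.c

    def max_initial_biomass(self) -> float:
        """Supremum of projectable initial biomass, Mmax(0) = 1/B0."""
        return 1.0 / self.B0

    def max_initial_diameter(self) -> float:
        """Supremum of projectable initial diameter under M = K4 D^(8/3)."""
        return (self.max_initial_biomass() / self.K4) ** (1.0 / DIAMETER_EXPONENT)

    def to_dict(self) -> dict:
        return {
            "A0": self.A0,
            "AT": self.AT,
            "K3": self.K3,
            "c": self.c,
            "K4": self.K4,
            "delta_t": self.delta_t,
            "B0": self.B0,
            "BT": self.BT,
        }


@dataclass(frozen=True)
class EnquistModel:
    """Metabolic-scaling growth model dD/dt = beta * D^(1/3).

    Integrating over the census span gives DT^(2/3) = D0^(2/3) + k,
    a slope-one line with k = (2/3) * beta * delta_t.
    """

    beta: float
    k: float = float("nan")

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def rate(self, d0):
        return self.beta * np.asarray(d0, dtype=float) ** (1.0 / 3.0)

    def to_dict(self) -> dict:
        return {"beta": self.beta, "k": self.k}


@dataclass(frozen=True)
class StandAllometryFit:
    """Ymax = K1 * Hmax^(a+1) stand biomass vs top height scaling."""

    K1: float
    a_plus_1: float
    fit: regression.LinearFit

    def __post_init__(self) -> None:
        if self.K1 <= 0:
            raise ValueError("K1 must be positive")

    def dry_matter_density(self, hmax):
        """d = Ymax/Hmax = K1 * Hmax^a (kg per m of canopy height)."""
        return self.K1 * np.asarray(hmax, dtype=float) ** (self.a_plus_1 - 1.0)

    def to_dict(self) -> dict:
        return {"K1": self.K1, "a_plus_1": self.a_plus_1, "fit": self.fit.to_dict()}


# ---------------------------------------------------------------------------
# Y-N curve


def cumulative_curve(biomasses) -> np.ndarray:
    """Ranked cumulative-biomass pairs (N, Y(N)), N = 1..n from the largest.

    Ties are broken by the stable input order.
    """
    m = np.asarray(biomasses, dtype=float)
    if m.size == 0:
        raise ValueError("empty biomass list")
    if np.any(m <= 0):
        raise ValueError("biomasses must be positive")
    order = np.argsort(-m, kind="stable")
    y = np.cumsum(m[order])
    n = np.arange(1, m.size + 1, dtype=float)
    return np.column_stack([n, y])


def yn_value(A: float, B: float, N):
    """Cumulative biomass of the N largest trees, Y = N/(A N + B)."""
    if A <= 0 or B <= 0:
        raise ValueError("A and B must be positive")
    n = np.asarray(N, dtype=float)
    if np.any(n <= 0):
        raise ValueError("N must be positive")
    out = n / (A * n + B)
    return float(out) if out.ndim == 0 else out


def fit_yn(pairs, max_iter: int = 200) -> YNFit:
    """Fit Y = N/(A N + B) to ranked cumulative-biomass pairs.

    Unweighted nonlinear least squares on Y, started from the natural
    initial values A = 1/Y(n) (reciprocal of total biomass) and
    B = 1/Y(1) (reciprocal of the largest tree's biomass).
    """
    p = np.asarray(pairs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (N, Y)")
    if p.shape[0] < 3:
        raise ValueError("Y-N fit is underdetermined with fewer than 3 trees")
    n, y = p[:, 0], p[:, 1]
    init = [1.0 / y[-1], 1.0 / y[0]]
    res = regression.nls_fit(
        lambda q, nn: nn / (q[0] * nn + q[1]),
        n,
        y,
        init,
        bounds=([1e-300, 1e-300], [np.inf, np.inf]),
        max_iter=max_iter,
    )
    return YNFit(
        A=res.params[0],
        B=res.params[1],
        n=int(p.shape[0]),
        rss=res.rss,
        r2=res.r2,
        converged=res.converged,
    )


def individual_biomass(A: float, B: float, N):
    """Biomass of the rank-N tree on the continuous curve, M = B/(A N + B)^2."""
    if A <= 0 or B <= 0:
        raise ValueError("A and B must be positive")
    n = np.asarray(N, dtype=float)
    if np.any(n <= 0):
        raise ValueError("N must be positive")
    out = B / (A * n + B) ** 2
    return float(out) if out.ndim == 0 else out


def rank_from_biomass(M, A: float, B: float):
    """Invert M = B/(A N + B)^2:  N = (sqrt(B/M) − B)/A.

    Defined for 0 < M < 1/B (a tree cannot out-weigh the curve's
    maximum individual biomass).
    """
    if A <= 0 or B <= 0:
        raise ValueError("A and B must be positive")
    m = np.asarray(M, dtype=float)
    if np.any(m <= 0) or np.any(m >= 1.0 / B):
        raise ValueError("M must lie in (0, 1/B)")
    out = (np.sqrt(B / m) - B) / A
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Rank-preserving projection


def project_biomass(M0, A0: float, B0: float, AT: float, BT: float):
    """Rank-preserving biomass projection between two censuses.

    MT = BT * [ (AT/A0)(sqrt(B0/M0) − B0) + BT ]^(−2), the closed form
    of "find the rank with biomass M0 under (A0, B0), then read the
    biomass of that same rank under (AT, BT)".  Accepts M0 in
    (0, 1/B0]; the supremum maps to 1/BT (largest stays largest).
    """
    for name, v in (("A0", A0), ("B0", B0), ("AT", AT), ("BT", BT)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    m0 = np.asarray(M0, dtype=float)
    if np.any(m0 <= 0) or np.any(m0 > 1.0 / B0):
        raise ValueError("M0 must lie in (0, 1/B0]")
    denom = (AT / A0) * (np.sqrt(B0 / m0) - B0) + BT
    out = BT / denom**2
    return float(out) if out.ndim == 0 else out


def project_biomass_scaled(M0, params: GrowthModelParams):
    """Projection with B eliminated through B = K3 * A^c; algebraically
    identical to :func:`project_biomass` at B0 = K3 A0^c, BT = K3 AT^c."""
    a0c = params.K3 * params.A0**params.c
    atc = params.K3 * params.AT**params.c
    m0 = np.asarray(M0, dtype=float)
    if np.any(m0 <= 0) or np.any(m0 > 1.0 / a0c):
        raise ValueError("M0 must lie in (0, 1/B0]")
    denom = (params.AT / params.A0) * (np.sqrt(a0c / m0) - a0c) + atc
    out = atc / denom**2
    return float(out) if out.ndim == 0 else out


def project_diameter(D0, params: GrowthModelParams):
    """Project initial diameter(s) through the size-structure model.

    D0 -> M0 = K4 D0^(8/3) -> rank-preserving MT -> DT = (MT/K4)^(3/8).
    Returns (DT, DT^(2/3)).
    """
    d0 = np.asarray(D0, dtype=float)
    if np.any(d0 <= 0):
        raise ValueError("D0 must be positive")
    m0 = params.K4 * d0**DIAMETER_EXPONENT
    if np.any(m0 > params.max_initial_biomass()):
        raise ValueError(
            "D0 implies M0 > 1/B0: tree larger than the initial curve's maximum "
            f"(max projectable D0 = {params.max_initial_diameter():.4g} cm)"
        )
    mt = np.asarray(project_biomass_scaled(m0, params))
    dt = (mt / params.K4) ** (1.0 / DIAMETER_EXPONENT)
    dt23 = (mt / params.K4) ** 0.25
    if dt.ndim == 0:
        return float(dt), float(dt23)
    return dt, dt23


def growth_rate_curve(D0, params: GrowthModelParams):
    """Predicted annual diameter growth rate (DT − D0)/delta_t in cm/yr."""
    dt, _ = project_diameter(D0, params)
    d0 = np.asarray(D0, dtype=float)
    out = (dt - d0) / params.delta_t
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Scaling fits and the metabolic-scaling comparison model


def fit_ab_scaling(fits: Iterable[YNFit] | Sequence) -> ABScalingFit:
    """OLS of ln B on ln A across censuses: B = K3 * A^c.

    Accepts YNFit objects or (A, B) pairs.  Two censuses give the
    exact two-point solve (no CI); three or more give full OLS
    diagnostics.
    """
    a, b = [], []
    for f in fits:
        if isinstance(f, YNFit):
            a.append(f.A)
            b.append(f.B)
        else:
            a.append(float(f[0]))
            b.append(float(f[1]))
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size < 2:
        raise ValueError("B-A scaling needs at least 2 censuses")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("A and B must be positive")
    lna, lnb = np.log(a), np.log(b)
    if a.size == 2:
        c = (lnb[1] - lnb[0]) / (lna[1] - lna[0])
        k3 = math.exp(lnb[0] - c * lna[0])
        return ABScalingFit(K3=k3, c=float(c), fit=None)
    lf = regression.ols(lna, lnb)
    return ABScalingFit(K3=math.exp(lf.intercept), c=lf.slope, fit=lf)


def enquist_project(D0, k: float):
    """Metabolic-scaling projection DT = (D0^(2/3) + k)^(3/2)."""
    d0 = np.asarray(D0, dtype=float)
    if np.any(d0 <= 0):
        raise ValueError("D0 must be positive")
    if k < 0:
        raise ValueError("k must be non-negative")
    out = (d0 ** (2.0 / 3.0) + k) ** 1.5
    return float(out) if out.ndim == 0 else out


def fit_enquist_rate(pairs, delta_t: float | None = None) -> EnquistModel:
    """Least-squares rate constant of dD/dt = beta * D0^(1/3).

    The closed form beta = Σ(g D0^(1/3)) / Σ(D0^(2/3)) solves the
    one-parameter normal equation exactly.
    """
    p = np.asarray(pairs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 1:
        raise ValueError("pairs must be an (n, 2) array of (D0, dD/dt)")
    d0, g = p[:, 0], p[:, 1]
    if np.any(d0 < 0) or not np.any(d0 > 0):
        raise ValueError("need positive initial diameters")
    beta = float(np.sum(g * d0 ** (1.0 / 3.0)) / np.sum(d0 ** (2.0 / 3.0)))
    beta = max(beta, 0.0)
    k = (2.0 / 3.0) * beta * delta_t if delta_t is not None else float("nan")
    return EnquistModel(beta=beta, k=k)
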