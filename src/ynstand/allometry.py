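"""Tree allometry: diameter-to-biomass conversion and power-law fits.

Aboveground biomass M (kg) is obtained from stem diameter D (cm, at
breast height) through a generic multi-species equation for natural
forests in Japan,

    M = exp(c0 + c1 ln D + c2 (ln D)^2 + c3 (ln D)^3 + d ln(delta)) * CF

where delta is species wood density (g/cm^3) and CF a lognormal
bias-correction factor.  Power-law relations between any two positive
size variables (M-D, M-H) are fitted in log-log space by OLS or RMA,
or with the exponent pinned (the 8/3 diameter-biomass scaling of
metabolic theory) so only the coefficient is estimated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from . import regression

__all__ = [
    "AllometryConfig",
    "PowerLawFit",
    "generic_biomass",
    "fit_power",
    "fit_fixed_exponent",
    "biomass_to_diameter",
    "DIAMETER_EXPONENT",
]

log = logging.getLogger(__name__)

#: Metabolic-theory diameter-biomass scaling exponent, M ∝ D^(8/3).
DIAMETER_EXPONENT = 8.0 / 3.0


@dataclass(frozen=True)
class AllometryConfig:
    """Coefficients of the generic biomass equation plus a wood-density lookup.

    Defaults are the published generic multi-species equation
    (1203 harvested trees, 70 Japanese natural forests); ``default_density``
    is used, with a warning, for species absent from ``density_table``.
    """

    c0: float = -1.196
    c1: float = 1.622
    c2: float = 0.338
    c3: float = -0.044
    density_coef: float = 0.708
    cf: float = 1.029
    default_density: float = 0.5
    density_table: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cf <= 0:
            raise ValueError("CF must be positive")
        for sp, d in self.density_table.items():
            if not 0 < d <= 1.5:
                raise ValueError(f"wood density of {sp!r} outside (0, 1.5]: {d}")

    def density_for(self, species: str | None) -> float:
        if species is not None and species in self.density_table:
            return self.density_table[species]
        log.warning(
            "no wood density for species %r; using default %.3f g/cm^3",
            species,
            self.default_density,
        )
        return self.default_density

    def to_dict(self) -> dict:
        d = asdict(self)
        d["density_table"] = dict(self.density_table)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AllometryConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted power law y = K * x^e, estimated in log-log space.

    ``method`` is "OLS", "RMA" or "fixed-exponent".  r² refers to the
    log-log fit.  For fixed-exponent fits the exponent was not
    estimated and carries no standard error or CI.
    """

    coefficient: float
    ln_coefficient: float
    exponent: float
    exponent_se: float | None
    exponent_ci95: tuple[float, float] | None
    r2: float
    adj_r2: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if self.exponent_ci95 is not None:
            lo, hi = self.exponent_ci95
            if not (lo <= self.exponent <= hi):
                raise ValueError("exponent CI must contain the point estimate")

    def predict(self, x):
        return self.coefficient * np.asarray(x, dtype=float) ** self.exponent

    def ci_contains(self, value: float) -> bool:
        if self.exponent_ci95 is None:
            raise ValueError("no CI available (fixed-exponent fit)")
        # tiny relative pad so exact-data degenerate CIs are not missed by one ulp
        eps = 1e-9 * max(1.0, abs(value))
        return self.exponent_ci95[0] - eps <= value <= self.exponent_ci95[1] + eps

    def to_dict(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "ln_coefficient": self.ln_coefficient,
            "exponent": self.exponent,
            "exponent_se": self.exponent_se,
            "exponent_ci95": list(self.exponent_ci95) if self.exponent_ci95 else None,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "method": self.method,
        }


def generic_biomass(diameter_cm, density=None, config: AllometryConfig | None = None):
    """Aboveground biomass (kg) from DBH (cm) and wood density (g/cm^3).

    Accepts scalars or arrays.  ``density=None`` falls back to the
    config's default density.
    """
    cfg = config or AllometryConfig()
    d = np.asarray(diameter_cm, dtype=float)
    if density is None:
        density = cfg.default_density
    delta = np.asarray(density, dtype=float)
    if np.any(d <= 0) or np.any(delta <= 0):
        raise ValueError("diameter and wood density must be positive")
    ln_d = np.log(d)
    ln_m = (
        cfg.c0
        + cfg.c1 * ln_d
        + cfg.c2 * ln_d**2
        + cfg.c3 * ln_d**3
        + cfg.density_coef * np.log(delta)
    )
    out = np.exp(ln_m) * cfg.cf
    return float(out) if out.ndim == 0 else out


def _positive_logs(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fits require strictly positive data")
    return np.log(x), np.log(y), x.size


def fit_power(x, y, method: str = "OLS") -> PowerLawFit:
    """Free-exponent power-law fit of y on x by OLS or RMA in log space."""
    lnx, lny, n = _positive_logs(x, y, 3)
    method = method.upper()
    if method == "OLS":
        lf = regression.ols(lnx, lny)
        tq = (lf.slope_ci95[1] - lf.slope) if n > 2 else 0.0
        se = tq / _t975(n - 2) if n > 2 and tq > 0 else 0.0
    elif method == "RMA":
        lf = regression.rma(lnx, lny)
        se = None
    else:
        raise ValueError(f"unknown method {method!r}")
    return PowerLawFit(
        coefficient=math.exp(lf.intercept),
        ln_coefficient=lf.intercept,
        exponent=lf.slope,
        exponent_se=se,
        exponent_ci95=lf.slope_ci95,
        r2=lf.r2,
        adj_r2=lf.adj_r2,
        n=n,
        method=method,
    )


def _t975(df: int) -> float:
    from scipy import stats

    return float(stats.t.ppf(0.975, df))


def fit_fixed_exponent(x, y, exponent: float) -> PowerLawFit:
    """Estimate only the coefficient K of y = K x^e for a pinned e.

    Least squares in log space with a fixed slope reduces to
    ln K = mean(ln y − e ln x); with e = 0, K is the geometric mean of y.
    """
    lnx, lny, n = _positive_logs(x, y, 1)
    ln_k = float(np.mean(lny - exponent * lnx))
    resid = lny - (ln_k + exponent * lnx)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((lny - lny.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PowerLawFit(
        coefficient=math.exp(ln_k),
        ln_coefficient=ln_k,
        exponent=float(exponent),
        exponent_se=None,
        exponent_ci95=None,
        r2=r2,
        adj_r2=r2,  # slope not estimated: no df spent beyond the mean
        n=n,
        method="fixed-exponent",
    )


def biomass_to_diameter(biomass_kg, k4: float, exponent: float = DIAMETER_EXPONENT):
    """Invert M = K4 * D^e:  D = (M / K4)^(1/e)."""
    m = np.asarray(biomass_kg, dtype=float)
    if np.any(m <= 0) or k4 <= 0:
        raise ValueError("biomass and K4 must be positive")
    out = (m / k4) ** (1.0 / exponent)
    return float(out) if out.ndim == 0 else out
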