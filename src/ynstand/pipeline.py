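"""Per-plot assumption tests and the two-model growth comparison.

The size-structure growth model rests on six testable assumptions:

1. the Y-N curve fits each census's size hierarchy;
2. a tree's biomass rank is (nearly) time-invariant;
3. stand biomass is a power function of top height, Ymax = K1 Hmax^(a+1);
4. tree biomass is allometric in height, M = K2 H^b;
5. the curve parameters scale as B = K3 A^c;
6. tree biomass scales as the 8/3 power of stem diameter.

This module runs each test on a cleaned PlotSeries, assembles plug-in
growth-curve parameters (A0, AT, K3, c, K4, delta_t), and scores the
resulting diameter projection against the metabolic-scaling slope-one
line on (D0^(2/3), DT^(2/3)) axes and against observed growth rates.

Verdict thresholds are heuristics (the source analyses report outcomes,
not criteria) and are configurable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry, census_io, regression, yn_growth
from .allometry import AllometryConfig, DIAMETER_EXPONENT, PowerLawFit
from .census_io import CleaningRules, PlotSeries
from .yn_growth import (
    ABScalingFit,
    EnquistModel,
    GrowthModelParams,
    StandAllometryFit,
    YNFit,
)

__all__ = [
    "PipelineConfig",
    "Verdict",
    "AssumptionReport",
    "ModelComparison",
    "census_biomasses",
    "test_assumption1",
    "test_assumption2",
    "test_assumption3",
    "test_assumption4",
    "test_assumption5",
    "test_assumption6",
    "derive_growth_params",
    "compare_models",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    allometry: AllometryConfig = field(default_factory=AllometryConfig)
    cleaning: CleaningRules = field(default_factory=CleaningRules)
    yn_r2_threshold: float = 0.95  # assumption 1 "fits well"
    rho_threshold: float = 0.9  # assumption 2
    k4_override: float | None = None
    per_interval_rates: bool = False

    def to_dict(self) -> dict:
        return {
            "allometry": self.allometry.to_dict(),
            "cleaning": dataclasses.asdict(self.cleaning),
            "yn_r2_threshold": self.yn_r2_threshold,
            "rho_threshold": self.rho_threshold,
            "k4_override": self.k4_override,
            "per_interval_rates": self.per_interval_rates,
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load from a flat-keys YAML config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allom = AllometryConfig(
            **{
                k: raw[k]
                for k in (
                    "c0",
                    "c1",
                    "c2",
                    "c3",
                    "density_coef",
                    "cf",
                    "default_density",
                    "density_table",
                )
                if k in raw
            }
        )
        cleaning = CleaningRules(
            drop_missing_final=raw.get("drop_missing_final", True),
            exclude_ids=tuple(raw.get("exclude_ids", ())),
        )
        return cls(
            allometry=allom,
            cleaning=cleaning,
            yn_r2_threshold=raw.get("yn_r2_threshold", 0.95),
            rho_threshold=raw.get("rho_threshold", 0.9),
            k4_override=raw.get("k4_override"),
            per_interval_rates=raw.get("per_interval_rates", False),
        )


@dataclass(frozen=True)
class Verdict:
    assumption: str
    status: str  # supported | partial | unsupported | not_testable
    criteria: dict

    def to_dict(self) -> dict:
        return {"assumption": self.assumption, "status": self.status, "criteria": self.criteria}


@dataclass
class AssumptionReport:
    plot_id: str
    yn_fits: dict[int, YNFit]
    spearman_rho: float | None
    stand_allometry: StandAllometryFit | None
    mh_fits: dict[int, PowerLawFit]
    ab_scaling: ABScalingFit | None
    md_fits: dict[int, dict]
    verdicts: list[Verdict]

    def to_dict(self) -> dict:
        return {
            "plot_id": self.plot_id,
            "yn_fits": {str(y): f.to_dict() for y, f in self.yn_fits.items()},
            "spearman_rho": self.spearman_rho,
            "stand_allometry": self.stand_allometry.to_dict() if self.stand_allometry else None,
            "mh_fits": {str(y): f.to_dict() for y, f in self.mh_fits.items()},
            "ab_scaling": self.ab_scaling.to_dict() if self.ab_scaling else None,
            "md_fits": {
                str(y): {
                    "ols": d["ols"].to_dict(),
                    "rma": d["rma"].to_dict(),
                    "ci_contains_8_3": d["ci_contains_8_3"],
                }
                for y, d in self.md_fits.items()
            },
            "verdicts": [v.to_dict() for v in self.verdicts],
        }


@dataclass
class ModelComparison:
    plot_id: str
    rma_fit: regression.LinearFit
    enquist_r2: float
    alt_r2: float
    delta_r2: float
    enquist_k: float
    rate_model: EnquistModel
    enquist_rate_r2: float
    alt_rate_r2: float
    n_pairs: int
    n_excluded_domain: int
    params: GrowthModelParams

    def to_dict(self) -> dict:
        return {
            "plot_id": self.plot_id,
            "rma_fit": self.rma_fit.to_dict(),
            "enquist_r2": self.enquist_r2,
            "alt_r2": self.alt_r2,
            "delta_r2": self.delta_r2,
            "enquist_k": self.enquist_k,
            "rate_model": self.rate_model.to_dict(),
            "enquist_rate_r2": self.enquist_rate_r2,
            "alt_rate_r2": self.alt_rate_r2,
            "n_pairs": self.n_pairs,
            "n_excluded_domain": self.n_excluded_domain,
            "params": self.params.to_dict(),
        }


# ---------------------------------------------------------------------------
# biomass plumbing


def census_biomasses(census: census_io.StandCensus, config: PipelineConfig) -> np.ndarray:
    """Per-tree biomass for one census: recorded values take precedence,
    otherwise the generic allometric equation with species wood density."""
    out = np.empty(len(census.trees))
    for i, t in enumerate(census.trees):
        if t.biomass_kg is not None:
            out[i] = t.biomass_kg
        else:
            delta = config.allometry.density_for(None)
            out[i] = allometry.generic_biomass(t.diameter_cm, delta, config.allometry)
    return out


def _census_biomasses_with_species(series: PlotSeries, year: int, config: PipelineConfig):
    census = series.census(year)
    species = {t.tree_id: t.species for t in series.trees}
    out = np.empty(len(census.trees))
    for i, t in enumerate(census.trees):
        if t.biomass_kg is not None:
            out[i] = t.biomass_kg
        else:
            delta = config.allometry.density_for(species.get(t.tree_id))
            out[i] = allometry.generic_biomass(t.diameter_cm, delta, config.allometry)
    return census, out


# ---------------------------------------------------------------------------
# assumption tests


def test_assumption1(series: PlotSeries, config: PipelineConfig | None = None) -> dict[int, YNFit]:
    """Fit the Y-N curve per census; fit errors are recorded, not raised."""
    config = config or PipelineConfig()
    fits: dict[int, YNFit] = {}
    for year in series.census_years:
        _, m = _census_biomasses_with_species(series, year, config)
        try:
            fits[year] = yn_growth.fit_yn(yn_growth.cumulative_curve(m))
        except ValueError as exc:
            log.warning("plot %s, census %d: Y-N fit failed: %s", series.plot_id, year, exc)
    return fits


def test_assumption2(series: PlotSeries, config: PipelineConfig | None = None) -> float:
    """Spearman ρ between biomass ranks at the first and last census."""
    config = config or PipelineConfig()
    years = series.census_years
    c0, m0 = _census_biomasses_with_species(series, years[0], config)
    c1, m1 = _census_biomasses_with_species(series, years[-1], config)
    first = {t.tree_id: m for t, m in zip(c0.trees, m0)}
    last = {t.tree_id: m for t, m in zip(c1.trees, m1)}
    shared = [tid for tid in first if tid in last]
    if len(shared) < 2:
        raise ValueError("fewer than 2 trees measured at both first and last census")
    return regression.spearman([first[t] for t in shared], [last[t] for t in shared])


def test_assumption3(
    series: PlotSeries, config: PipelineConfig | None = None
) -> StandAllometryFit | None:
    """OLS of ln(stand biomass) on ln(top height) across censuses.

    Returns None (not testable) when heights are absent — in the field
    data, heights exist only in the young plots where trees are short
    enough to measure.
    """
    config = config or PipelineConfig()
    ln_y, ln_h = [], []
    for year in series.census_years:
        census, m = _census_biomasses_with_species(series, year, config)
        h = census.heights
        if np.all(np.isnan(h)):
            continue
        ln_y.append(np.log(np.sum(m)))
        ln_h.append(np.log(np.nanmax(h)))
    if len(ln_y) < 3:
        return None
    lf = regression.ols(np.array(ln_h), np.array(ln_y))
    return StandAllometryFit(K1=float(np.exp(lf.intercept)), a_plus_1=lf.slope, fit=lf)


def test_assumption4(
    series: PlotSeries, config: PipelineConfig | None = None
) -> dict[int, PowerLawFit]:
    """Per-census OLS log-log fit of biomass on height, M = K2 H^b."""
    config = config or PipelineConfig()
    fits: dict[int, PowerLawFit] = {}
    for year in series.census_years:
        census, m = _census_biomasses_with_species(series, year, config)
        h = census.heights
        ok = ~np.isnan(h)
        if ok.sum() < 3:
            continue
        fits[year] = allometry.fit_power(h[ok], m[ok], method="OLS")
    return fits


def test_assumption5(fits) -> ABScalingFit:
    """B = K3 A^c scaling across the converged per-census Y-N fits."""
    if isinstance(fits, dict):
        fits = [f for _, f in sorted(fits.items())]
    usable = [f for f in fits if f.converged]
    if len(usable) < 2:
        raise ValueError("B-A scaling needs at least 2 converged census fits")
    return yn_growth.fit_ab_scaling(usable)


def test_assumption6(
    series: PlotSeries, config: PipelineConfig | None = None
) -> dict[int, dict]:
    """Per-census OLS and RMA log-log fits of M on D with an 8/3-containment flag."""
    config = config or PipelineConfig()
    out: dict[int, dict] = {}
    for year in series.census_years:
        census, m = _census_biomasses_with_species(series, year, config)
        d = census.diameters
        if d.size < 3:
            continue
        fo = allometry.fit_power(d, m, method="OLS")
        fr = allometry.fit_power(d, m, method="RMA")
        out[year] = {
            "ols": fo,
            "rma": fr,
            "ci_contains_8_3": bool(fo.ci_contains(DIAMETER_EXPONENT)),
        }
    return out


def _verdicts(
    config: PipelineConfig,
    yn_fits: dict[int, YNFit],
    rho: float | None,
    stand: StandAllometryFit | None,
    mh: dict[int, PowerLawFit],
    ab: ABScalingFit | None,
    md: dict[int, dict],
) -> list[Verdict]:
    v: list[Verdict] = []

    ok1 = [f.converged and f.r2 >= config.yn_r2_threshold for f in yn_fits.values()]
    v.append(
        Verdict(
            "1: Y-N curve fits each census",
            "supported" if ok1 and all(ok1) else ("partial" if any(ok1) else "unsupported"),
            {
                "criterion": f"converged and r2 >= {config.yn_r2_threshold} in every census",
                "n_censuses_ok": int(sum(ok1)),
                "n_censuses": len(ok1),
            },
        )
    )

    v.append(
        Verdict(
            "2: ranks persist over time",
            "supported"
            if rho is not None and rho >= config.rho_threshold
            else ("unsupported" if rho is not None else "not_testable"),
            {"criterion": f"Spearman rho >= {config.rho_threshold}", "rho": rho},
        )
    )

    if stand is None:
        v.append(
            Verdict(
                "3: stand biomass scales with top height",
                "not_testable",
                {"criterion": "95% CI of a+1 excludes values <= 1", "reason": "no heights"},
            )
        )
    else:
        lo = stand.fit.slope_ci95[0]
        v.append(
            Verdict(
                "3: stand biomass scales with top height",
                "supported" if lo > 1.0 else "unsupported",
                {
                    "criterion": "95% CI of a+1 excludes values <= 1",
                    "a_plus_1": stand.a_plus_1,
                    "ci95": list(stand.fit.slope_ci95),
                },
            )
        )

    if not mh:
        v.append(
            Verdict(
                "4: tree biomass allometric in height",
                "not_testable",
                {"criterion": "95% CI of b excludes 0 in every census", "reason": "no heights"},
            )
        )
    else:
        ok4 = [f.exponent_ci95[0] > 0 for f in mh.values()]
        v.append(
            Verdict(
                "4: tree biomass allometric in height",
                "supported" if all(ok4) else ("partial" if any(ok4) else "unsupported"),
                {
                    "criterion": "95% CI of b excludes 0 in every census",
                    "b_range": [min(f.exponent for f in mh.values()), max(f.exponent for f in mh.values())],
                },
            )
        )

    if ab is None:
        v.append(Verdict("5: B scales with A", "not_testable", {"reason": "too few censuses"}))
    else:
        if ab.fit is None:
            status = "supported" if ab.c != 0 else "unsupported"
            crit: dict = {"criterion": "two-census exact solve; c nonzero", "c": ab.c}
        else:
            lo, hi = ab.fit.slope_ci95
            status = "supported" if (lo > 0 or hi < 0) else "unsupported"
            crit = {"criterion": "95% CI of c excludes 0", "c": ab.c, "ci95": [lo, hi]}
        v.append(Verdict("5: B scales with A", status, crit))

    if not md:
        v.append(Verdict("6: biomass scales as D^(8/3)", "not_testable", {"reason": "no data"}))
    else:
        scaling_ok = all(d["ols"].r2 >= config.yn_r2_threshold for d in md.values())
        contains = [d["ci_contains_8_3"] for d in md.values()]
        if scaling_ok and all(contains):
            status = "supported"
        elif scaling_ok:
            status = "partial"  # a power law holds, but the exponent is not 8/3
        else:
            status = "unsupported"
        v.append(
            Verdict(
                "6: biomass scales as D^(8/3)",
                status,
                {
                    "criterion": "log-log r2 high and 95% CI of e contains 8/3",
                    "e_range_ols": [
                        min(d["ols"].exponent for d in md.values()),
                        max(d["ols"].exponent for d in md.values()),
                    ],
                    "n_censuses_containing_8_3": int(sum(contains)),
                    "n_censuses": len(contains),
                },
            )
        )
    return v


def run_assumptions(series: PlotSeries, config: PipelineConfig | None = None) -> AssumptionReport:
    """Run all six assumption tests on a cleaned series."""
    config = config or PipelineConfig()
    yn_fits = test_assumption1(series, config)
    try:
        rho = test_assumption2(series, config)
    except ValueError:
        rho = None
    stand = test_assumption3(series, config)
    mh = test_assumption4(series, config)
    try:
        ab = test_assumption5(yn_fits)
    except ValueError:
        ab = None
    md = test_assumption6(series, config)
    return AssumptionReport(
        plot_id=series.plot_id,
        yn_fits=yn_fits,
        spearman_rho=rho,
        stand_allometry=stand,
        mh_fits=mh,
        ab_scaling=ab,
        md_fits=md,
        verdicts=_verdicts(config, yn_fits, rho, stand, mh, ab, md),
    )


# ---------------------------------------------------------------------------
# growth-model comparison


def derive_growth_params(
    series: PlotSeries,
    yn_fits: dict[int, YNFit],
    ab: ABScalingFit,
    config: PipelineConfig | None = None,
) -> GrowthModelParams:
    """Assemble the plug-in parameter bundle for the growth curves.

    K4 defaults to the fixed-8/3 fit on the plot's own pooled (D, M)
    data; an external estimate (e.g. from harvested trees) can be
    supplied through ``config.k4_override``.
    """
    config = config or PipelineConfig()
    years = series.census_years
    if config.k4_override is not None:
        k4 = config.k4_override
    else:
        d_all, m_all = [], []
        for year in years:
            census, m = _census_biomasses_with_species(series, year, config)
            d_all.append(census.diameters)
            m_all.append(m)
        fit = allometry.fit_fixed_exponent(
            np.concatenate(d_all), np.concatenate(m_all), DIAMETER_EXPONENT
        )
        k4 = fit.coefficient
    return GrowthModelParams(
        A0=yn_fits[years[0]].A,
        AT=yn_fits[years[-1]].A,
        K3=ab.K3,
        c=ab.c,
        K4=k4,
        delta_t=float(years[-1] - years[0]),
    )


def _r2(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum((y_obs - y_pred) ** 2)) / ss_tot


def _per_interval_rates(series: PlotSeries, tree_ids) -> np.ndarray:
    """Mean annual diameter growth over each tree's measured consecutive
    census intervals (shrinkage clamped to zero per interval)."""
    years = series.census_years
    by_id = {t.tree_id: t for t in series.trees}
    out = []
    for tid in tree_ids:
        t = by_id[tid]
        rates = []
        for y0, y1 in zip(years[:-1], years[1:]):
            d0, d1 = t.diameter_at(y0), t.diameter_at(y1)
            if d0 is None or d1 is None:
                continue
            rates.append(max(d1 - d0, 0.0) / (y1 - y0))
        out.append(float(np.mean(rates)) if rates else np.nan)
    return np.asarray(out)


def compare_models(
    series: PlotSeries,
    params: GrowthModelParams,
    first_year: int | None = None,
    last_year: int | None = None,
    per_interval_rates: bool = False,
) -> ModelComparison:
    """Score the size-structure projection against the slope-one line.

    On (x, y) = (D0^(2/3), DT^(2/3)): RMA line with slope CI; variance
    explained by the best slope-one line y = x + k (k = mean residual,
    the metabolic-scaling prediction); variance explained by the
    plug-in projection curve (zero fitted parameters); and on
    (D0, rate) axes the plug-in rate curve vs the fitted dD/dt =
    beta D^(1/3) model.  Trees whose D0 exceeds the projectable domain
    are excluded from the plug-in r2 with a logged count.
    """
    pairs = census_io.growth_pairs(series, first_year, last_year)
    if len(pairs) < 3:
        raise ValueError("need at least 3 growth pairs")
    d0 = np.array([p.d0_cm for p in pairs])
    dt_obs = np.array([p.dt_cm for p in pairs])
    if per_interval_rates:
        rates = _per_interval_rates(series, [p.tree_id for p in pairs])
    else:
        rates = np.array([p.dd_per_year for p in pairs])
    x = d0 ** (2.0 / 3.0)
    y = dt_obs ** (2.0 / 3.0)

    rma_fit = regression.rma(x, y)
    k = float(np.mean(y - x))
    enquist_r2 = _r2(y, x + k)

    dmax = params.max_initial_diameter()
    mask = d0 < dmax
    n_excl = int((~mask).sum())
    if n_excl:
        log.info(
            "plot %s: %d trees exceed the projectable domain (D0 >= %.3g cm)",
            series.plot_id,
            n_excl,
            dmax,
        )
    if mask.sum() < 3:
        raise ValueError("fewer than 3 trees inside the projectable domain")
    _, y_hat = yn_growth.project_diameter(d0[mask], params)
    alt_r2 = _r2(y[mask], y_hat)
    enquist_r2_masked = _r2(y[mask], x[mask] + float(np.mean(y[mask] - x[mask])))
    delta_r2 = alt_r2 - enquist_r2_masked

    rate_model = yn_growth.fit_enquist_rate(
        np.column_stack([d0, rates]), delta_t=params.delta_t
    )
    enquist_rate_r2 = _r2(rates, rate_model.rate(d0))
    alt_rate_r2 = _r2(rates[mask], yn_growth.growth_rate_curve(d0[mask], params))

    return ModelComparison(
        plot_id=series.plot_id,
        rma_fit=rma_fit,
        enquist_r2=enquist_r2,
        alt_r2=alt_r2,
        delta_r2=delta_r2,
        enquist_k=k,
        rate_model=rate_model,
        enquist_rate_r2=enquist_rate_r2,
        alt_rate_r2=alt_rate_r2,
        n_pairs=len(pairs),
        n_excluded_domain=n_excl,
        params=params,
    )


# ---------------------------------------------------------------------------
# orchestration


def curve_grid(params: GrowthModelParams, n: int = 200) -> pd.DataFrame:
    """Prediction grid (D0, DT, DT^(2/3), rate) over the projectable domain."""
    dmax = params.max_initial_diameter()
    d0 = np.linspace(dmax * 1e-3, dmax * 0.999, n)
    dt, dt23 = yn_growth.project_diameter(d0, params)
    rate = (dt - d0) / params.delta_t
    return pd.DataFrame(
        {"d0_cm": d0, "dt_cm": dt, "dt23": dt23, "rate_cm_per_yr": rate}
    )


def run_pipeline(
    inputs,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> dict:
    """Run cleaning, assumption tests and the model comparison per plot.

    ``inputs`` is a list of PlotSeries or paths to wide-format CSVs.
    Hard errors in one plot are recorded and the pipeline moves on.
    Output (if ``out_dir`` is given): report.json, cleaning.json and
    curves.csv; deterministic given inputs and config.
    """
    config = config or PipelineConfig()
    report: dict = {"config": config.to_dict(), "plots": {}}
    cleaning: dict = {}
    curves = []
    for item in inputs:
        try:
            series = (
                item
                if isinstance(item, PlotSeries)
                else census_io.read_census_wide(item)
            )
            series = census_io.clean_series(series, config.cleaning)
            cleaning[series.plot_id] = census_io.cleaning_report(series)
            ar = run_assumptions(series, config)
            entry = ar.to_dict()
            if ar.ab_scaling is not None and len(ar.yn_fits) >= 2:
                params = derive_growth_params(series, ar.yn_fits, ar.ab_scaling, config)
                mc = compare_models(
                    series, params, per_interval_rates=config.per_interval_rates
                )
                entry["comparison"] = mc.to_dict()
                grid = curve_grid(params)
                grid.insert(0, "plot_id", series.plot_id)
                curves.append(grid)
            report["plots"][series.plot_id] = entry
        except Exception as exc:  # noqa: BLE001 — isolate per-plot failures
            plot_id = getattr(item, "plot_id", str(item))
            log.error("plot %s failed: %s", plot_id, exc)
            report["plots"][plot_id] = {"error": str(exc)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        with open(out / "cleaning.json", "w") as fh:
            json.dump(cleaning, fh, indent=1, sort_keys=True)
        if curves:
            pd.concat(curves, ignore_index=True).to_csv(out / "curves.csv", index=False)
    return report
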