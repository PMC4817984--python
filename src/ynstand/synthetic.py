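"""Synthetic multi-census stand generator with retained ground truth.

The generator realises, by construction, exactly the statistical
structure the size-structure growth model assumes: each census t has
Y-N parameters (A_t, B_t = K3 * A_t^c) with A declining geometrically
(the stand accumulates biomass); the rank-N tree receives the integer
increment of the cumulative curve,

    M(N) = Y(N) − Y(N−1),    Y(N) = N/(A_t N + B_t),

so that the generated cumulative curve satisfies the Y-N equation
*exactly* at integer ranks and total biomass equals Y(n) (which is
what makes noise-free parameter recovery exact).  Diameters follow
M = K4 * D^(8/3) with multiplicative lognormal measurement noise;
recorded biomass is recomputed from the noisy diameter, mirroring
field data whose biomass column is itself diameter-derived; heights
follow M = K2 * H^b without noise.  Ranks persist across censuses
except for seeded adjacent-pair swaps.

It is a statistical emulator, not a mechanistic forest: no spatial
competition, recruitment, or process-based growth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
import numpy as np

from .census_io import Measurement, PlotSeries, TreeRecord

__all__ = [
    "SyntheticStandConfig",
    "SyntheticTruth",
    "generate_series",
    "young_and_mature_presets",
    "SPECIES_CYCLE",
    "WOOD_DENSITY_FIXTURE",
]

#: Synthetic species tokens (Hokkaido secondary-forest flora) cycled
#: across trees so species/wood-density plumbing is exercised end to end.
SPECIES_CYCLE: tuple[str, ...] = (
    "Betula ermanii",
    "Betula maximowiczii",
    "Quercus crispula",
    "Acer mono",
    "Carpinus laxiflora",
)

#: Matching synthetic wood-density lookup (g/cm^3, field-plausible values).
WOOD_DENSITY_FIXTURE: dict[str, float] = {
    "Betula ermanii": 0.51,
    "Betula maximowiczii": 0.50,
    "Quercus crispula": 0.62,
    "Acer mono": 0.58,
    "Carpinus laxiflora": 0.67,
}


@dataclass(frozen=True)
class SyntheticStandConfig:
    """Generator parameters; defaults emulate a young, densely censused
    stand (yearly censuses over a decade, total biomass growing ~4x).

    A_schedule, if given, overrides (A0, A_ratio_per_census).
    """

    n_trees: int = 250
    n_censuses: int = 10
    A0: float = 0.02  # kg^-1: asymptotic stand biomass 50 kg at census 1
    A_ratio_per_census: float = 0.85
    A_schedule: tuple[float, ...] | None = None
    K3: float = 33.0
    c: float = 1.2
    K4: float = 0.06  # kg cm^(-8/3)
    diameter_exponent: float = 8.0 / 3.0
    K2: float = 0.1  # kg m^-b
    b: float = 2.5
    noise_sd_lnD: float = 0.02
    rank_swap_probability: float = 0.0
    mortality_probability: float = 0.0
    seed: int = 0
    plot_id: str = "synthetic"
    start_year: int = 1985
    interval_years: int = 1

    def a_schedule(self) -> np.ndarray:
        if self.A_schedule is not None:
            a = np.asarray(self.A_schedule, dtype=float)
        else:
            a = self.A0 * self.A_ratio_per_census ** np.arange(self.n_censuses)
        if np.any(a <= 0):
            raise ValueError("A schedule must be positive")
        if np.any(np.diff(a) > 0):
            raise ValueError("A schedule must be non-increasing (stands accumulate biomass)")
        return a

    def b_schedule(self) -> np.ndarray:
        return self.K3 * self.a_schedule() ** self.c

    def validate(self) -> None:
        if self.n_trees < 3:
            raise ValueError("need at least 3 trees")
        if self.n_censuses < 2:
            raise ValueError("need at least 2 censuses")
        for name in ("K3", "c", "K4", "K2", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.rank_swap_probability <= 1:
            raise ValueError("rank_swap_probability must be in [0, 1]")
        if not 0 <= self.mortality_probability <= 1:
            raise ValueError("mortality_probability must be in [0, 1]")
        if self.noise_sd_lnD < 0:
            raise ValueError("noise_sd_lnD must be >= 0")
        self.a_schedule()


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests."""

    config: SyntheticStandConfig
    years: list[int]
    A: list[float]
    B: list[float]
    rank_of_tree: list[dict[str, int]]  # per census, tree_id -> rank (1 = largest)
    wood_density: dict[str, float] = field(default_factory=lambda: dict(WOOD_DENSITY_FIXTURE))

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "years": self.years,
            "A": self.A,
            "B": self.B,
            "rank_of_tree": self.rank_of_tree,
            "wood_density": self.wood_density,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _rank_increment_biomass(a: float, b: float, n: int) -> np.ndarray:
    """Biomass per integer rank as exact increments of the Y-N curve."""
    ranks = np.arange(0, n + 1, dtype=float)
    y = np.zeros(n + 1)
    y[1:] = ranks[1:] / (a * ranks[1:] + b)
    return np.diff(y)


def generate_series(config: SyntheticStandConfig) -> tuple[PlotSeries, SyntheticTruth]:
    """Generate a PlotSeries plus its ground truth; deterministic in the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    a_sched = config.a_schedule()
    b_sched = config.b_schedule()
    years = [config.start_year + t * config.interval_years for t in range(config.n_censuses)]
    n = config.n_trees
    tree_ids = [f"T{i + 1:04d}" for i in range(n)]
    species = [SPECIES_CYCLE[i % len(SPECIES_CYCLE)] for i in range(n)]

    # perm[k] = index of the tree currently holding rank k+1
    perm = np.arange(n)
    alive = np.ones(n, dtype=bool)
    records = {
        tid: TreeRecord(tree_id=tid, species=sp, family=None)
        for tid, sp in zip(tree_ids, species)
    }
    truth_ranks: list[dict[str, int]] = []

    for t, year in enumerate(years):
        if t > 0:
            # seeded adjacent-pair rank exchanges
            for k in range(n - 1):
                if rng.random() < config.rank_swap_probability:
                    perm[k], perm[k + 1] = perm[k + 1], perm[k]
            if config.mortality_probability > 0:
                dies = rng.random(n) < config.mortality_probability
                alive &= ~dies
        m_true = _rank_increment_biomass(a_sched[t], b_sched[t], n)
        noise = (
            np.exp(rng.normal(0.0, config.noise_sd_lnD, n))
            if config.noise_sd_lnD > 0
            else np.ones(n)
        )
        ranks_this_census: dict[str, int] = {}
        for k in range(n):
            tree_idx = perm[k]
            if not alive[tree_idx]:
                continue
            tid = tree_ids[tree_idx]
            ranks_this_census[tid] = k + 1
            m = m_true[k]
            d_true = (m / config.K4) ** (1.0 / config.diameter_exponent)
            d_obs = d_true * noise[k]
            m_obs = config.K4 * d_obs**config.diameter_exponent
            h = (m / config.K2) ** (1.0 / config.b)
            records[tid].measurements[year] = Measurement(
                diameter_cm=float(d_obs), height_m=float(h), biomass_kg=float(m_obs)
            )
        truth_ranks.append(ranks_this_census)

    trees = [records[tid] for tid in tree_ids if records[tid].measurements]
    series = PlotSeries(
        plot_id=config.plot_id,
        trees=trees,
        plot_area_m2=25.0 if config.A0 >= 1e-2 else 2000.0,
        interval_years=float(config.interval_years),
        metadata={"synthetic": True, "seed": config.seed},
    )
    truth = SyntheticTruth(
        config=config,
        years=years,
        A=[float(v) for v in a_sched],
        B=[float(v) for v in b_sched],
        rank_of_tree=truth_ranks,
    )
    return series, truth


def young_and_mature_presets(seed: int = 0) -> tuple[SyntheticStandConfig, SyntheticStandConfig]:
    """Preset stand conditions bracketing the maturity gradient.

    young: dense regenerating stand, A falling 75% per yearly census
    (total biomass ~7.5x over 8 censuses) — its projection curve is
    strongly curvilinear, so a straight RMA line through
    (D0^(2/3), DT^(2/3)) has slope well above 1.
    mature: old stand with A nearly static (2% total decline), whose
    projection curve is indistinguishable from the slope-one line.
    """
    young = SyntheticStandConfig(
        n_trees=120,
        n_censuses=8,
        A0=0.05,
        A_ratio_per_census=0.75,
        K3=20.0,
        c=1.2,
        K4=0.06,
        K2=0.1,
        b=2.5,
        noise_sd_lnD=0.02,
        seed=seed,
        plot_id="young",
        start_year=1985,
        interval_years=1,
    )
    mature = SyntheticStandConfig(
        n_trees=300,
        n_censuses=6,
        A0=5e-5,
        A_ratio_per_census=0.98 ** (1.0 / 5.0),
        K3=20.0,
        c=1.05,
        K4=0.06,
        K2=0.1,
        b=2.8,
        noise_sd_lnD=0.02,
        seed=seed + 1,
        plot_id="mature",
        start_year=1980,
        interval_years=2,
    )
    return young, mature
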