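"""Reading, validating, cleaning and writing multi-census plot data.

The wide "field" dialect has one row per tree and year-suffixed
measurement columns: ``D85`` (DBH in cm, 1985), ``H85`` (height in m),
``WA85`` (aboveground biomass in kg).  Two-digit years map to the
1900s by default.  A tidy long format (one row per tree per census)
is provided for interchange; the two round-trip exactly.

Units are cm for diameter, m for height, kg for biomass throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CensusFormatError",
    "Dialect",
    "Measurement",
    "TreeRecord",
    "StandCensus",
    "PlotSeries",
    "CleaningRules",
    "read_census_wide",
    "write_wide",
    "clean_series",
    "cleaning_report",
    "growth_pairs",
    "GrowthPair",
    "write_long",
    "read_long",
]

log = logging.getLogger(__name__)


class CensusFormatError(ValueError):
    """Raised for structurally unusable input files."""


@dataclass(frozen=True)
class Dialect:
    """Column conventions of the wide census format."""

    id_column: str = "Tree.Number"
    species_column: str = "Species"
    family_column: str = "Family"
    diameter_prefix: str = "D"
    height_prefix: str = "H"
    biomass_prefix: str = "WA"
    year_digits: int = 2
    century: int = 1900

    def year_columns(self, columns: Iterable[str]) -> dict[str, dict[int, str]]:
        """Map kind -> {census_year: column_name} for matching columns."""
        out: dict[str, dict[int, str]] = {"diameter": {}, "height": {}, "biomass": {}}
        # longest prefix first so WA85 is biomass, not a height column
        kinds = sorted(
            [
                ("diameter", self.diameter_prefix),
                ("height", self.height_prefix),
                ("biomass", self.biomass_prefix),
            ],
            key=lambda kv: -len(kv[1]),
        )
        for col in columns:
            for kind, prefix in kinds:
                m = re.fullmatch(re.escape(prefix) + r"(\d{%d})" % self.year_digits, col)
                if m:
                    out[kind][self.century + int(m.group(1))] = col
                    break
        return out

    def column_name(self, kind: str, year: int) -> str:
        prefix = {
            "diameter": self.diameter_prefix,
            "height": self.height_prefix,
            "biomass": self.biomass_prefix,
        }[kind]
        return f"{prefix}{year % 100:02d}"


@dataclass(frozen=True)
class Measurement:
    diameter_cm: float | None = None
    height_m: float | None = None
    biomass_kg: float | None = None


@dataclass
class TreeRecord:
    tree_id: str
    species: str | None = None
    family: str | None = None
    measurements: dict[int, Measurement] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        years = list(self.measurements)
        if years != sorted(years):
            self.measurements = dict(sorted(self.measurements.items()))
        for y, m in self.measurements.items():
            if m.diameter_cm is not None and m.diameter_cm <= 0:
                raise ValueError(f"tree {self.tree_id}, year {y}: diameter must be > 0")

    def diameter_at(self, year: int) -> float | None:
        m = self.measurements.get(year)
        return None if m is None else m.diameter_cm

    def measured_years(self) -> list[int]:
        return [y for y, m in self.measurements.items() if m.diameter_cm is not None]


class CensusTree(NamedTuple):
    tree_id: str
    diameter_cm: float
    height_m: float | None
    biomass_kg: float | None


@dataclass(frozen=True)
class StandCensus:
    plot_id: str
    census_year: int
    trees: tuple[CensusTree, ...]

    def __post_init__(self) -> None:
        ids = [t.tree_id for t in self.trees]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate tree ids in census {self.census_year}")

    @property
    def diameters(self) -> np.ndarray:
        return np.array([t.diameter_cm for t in self.trees], dtype=float)

    @property
    def biomasses(self) -> np.ndarray:
        return np.array(
            [np.nan if t.biomass_kg is None else t.biomass_kg for t in self.trees],
            dtype=float,
        )

    @property
    def heights(self) -> np.ndarray:
        return np.array(
            [np.nan if t.height_m is None else t.height_m for t in self.trees],
            dtype=float,
        )


@dataclass
class PlotSeries:
    """A plot's tree records across ordered census years."""

    plot_id: str
    trees: list[TreeRecord]
    plot_area_m2: float = float("nan")
    interval_years: float | None = None
    metadata: dict = field(default_factory=dict)
    excluded_trees: list[TreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.tree_id for t in self.trees]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CensusFormatError(f"duplicate tree ids: {dupes}")
        years = self.census_years
        if len(years) < 2:
            raise CensusFormatError(
                f"plot {self.plot_id}: need measurements in >= 2 census years, got {years}"
            )
        if self.interval_years is None and len(years) >= 2:
            diffs = np.diff(years)
            if np.all(diffs == diffs[0]):
                self.interval_years = float(diffs[0])

    @property
    def census_years(self) -> list[int]:
        years: set[int] = set()
        for t in self.trees:
            years.update(t.measured_years())
        return sorted(years)

    def census(self, year: int) -> StandCensus:
        rows = []
        for t in self.trees:
            m = t.measurements.get(year)
            if m is None or m.diameter_cm is None:
                continue
            rows.append(CensusTree(t.tree_id, m.diameter_cm, m.height_m, m.biomass_kg))
        return StandCensus(self.plot_id, year, tuple(rows))

    @property
    def censuses(self) -> list[StandCensus]:
        return [self.census(y) for y in self.census_years]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PlotSeries):
            return NotImplemented
        return (
            self.plot_id == other.plot_id
            and self.trees == other.trees
            and (
                (np.isnan(self.plot_area_m2) and np.isnan(other.plot_area_m2))
                or self.plot_area_m2 == other.plot_area_m2
            )
            and self.interval_years == other.interval_years
        )


def _parse_cell(raw, row_label, col) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.lower() in {"na", "nan"}:
        return None
    try:
        v = float(s)
    except ValueError as exc:
        raise CensusFormatError(
            f"unparseable numeric cell at row {row_label!r}, column {col!r}: {s!r}"
        ) from exc
    return v


def read_census_wide(
    path,
    dialect: Dialect | None = None,
    plot_id: str | None = None,
    plot_area_m2: float = float("nan"),
) -> PlotSeries:
    """Read one plot's wide-format census file into a PlotSeries.

    Rows with no diameter in any census year are dropped with a
    warning (the count lands in ``series.metadata['rows_without_diameter']``).
    """
    dialect = dialect or Dialect()
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    cols = dialect.year_columns(df.columns)
    if not cols["diameter"]:
        raise CensusFormatError(
            f"{path}: no diameter columns matching "
            f"'{dialect.diameter_prefix}<{dialect.year_digits}-digit year>'"
        )
    years = sorted(cols["diameter"])
    trees: list[TreeRecord] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        tree_id = str(row[dialect.id_column]).strip() if dialect.id_column in df.columns else str(idx)
        label = tree_id
        meas: dict[int, Measurement] = {}
        for year in sorted(set(years) | set(cols["height"]) | set(cols["biomass"])):
            d = h = w = None
            if year in cols["diameter"]:
                d = _parse_cell(row.get(cols["diameter"][year]), label, cols["diameter"][year])
            if year in cols["height"]:
                h = _parse_cell(row.get(cols["height"][year]), label, cols["height"][year])
            if year in cols["biomass"]:
                w = _parse_cell(row.get(cols["biomass"][year]), label, cols["biomass"][year])
            if d is not None or h is not None or w is not None:
                meas[year] = Measurement(d, h, w)
        if not any(m.diameter_cm is not None for m in meas.values()):
            n_dropped += 1
            continue
        species = row.get(dialect.species_column)
        family = row.get(dialect.family_column)
        trees.append(
            TreeRecord(
                tree_id=tree_id,
                species=None if pd.isna(species) else str(species),
                family=None if pd.isna(family) else str(family),
                measurements=meas,
            )
        )
    if n_dropped:
        log.warning("%s: dropped %d rows without any diameter", path, n_dropped)
    series = PlotSeries(
        plot_id=plot_id or path.stem,
        trees=trees,
        plot_area_m2=plot_area_m2,
    )
    series.metadata["rows_without_diameter"] = n_dropped
    series.metadata["source"] = str(path)
    return series


def write_wide(series: PlotSeries, path, dialect: Dialect | None = None) -> None:
    """Write a PlotSeries back to the wide year-suffixed dialect."""
    dialect = dialect or Dialect()
    years = series.census_years
    rows = []
    for t in series.trees:
        row: dict[str, object] = {
            dialect.species_column: t.species,
            dialect.family_column: t.family,
            dialect.id_column: t.tree_id,
        }
        for y in years:
            m = t.measurements.get(y)
            row[dialect.column_name("diameter", y)] = None if m is None else m.diameter_cm
            if m is not None and m.height_m is not None:
                row[dialect.column_name("height", y)] = m.height_m
            if m is not None and m.biomass_kg is not None:
                row[dialect.column_name("biomass", y)] = m.biomass_kg
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class CleaningRules:
    """Cleaning policy: drop trees dead/missing at the final census and
    any explicitly listed tree (e.g. a largest tree judged to have
    regenerated at a different time)."""

    drop_missing_final: bool = True
    exclude_ids: tuple[str, ...] = ()
    exclude_reason: str = "listed in exclusion rules"


def clean_series(series: PlotSeries, rules: CleaningRules | None = None) -> PlotSeries:
    """Apply cleaning rules; total (never raises) and idempotent.

    Excluded trees are retained on ``excluded_trees`` with a reason.
    """
    rules = rules or CleaningRules()
    final_year = series.census_years[-1]
    kept: list[TreeRecord] = []
    excluded: list[TreeRecord] = list(series.excluded_trees)
    for t in series.trees:
        if t.tree_id in rules.exclude_ids:
            excluded.append(replace_excluded(t, rules.exclude_reason))
        elif rules.drop_missing_final and t.diameter_at(final_year) is None:
            excluded.append(replace_excluded(t, "no diameter at final census (died or unmeasured)"))
        else:
            kept.append(t)
    out = PlotSeries(
        plot_id=series.plot_id,
        trees=kept,
        plot_area_m2=series.plot_area_m2,
        interval_years=series.interval_years,
        metadata=dict(series.metadata),
        excluded_trees=excluded,
    )
    log.info(
        "plot %s: cleaning kept %d trees, excluded %d",
        series.plot_id,
        len(kept),
        len(excluded),
    )
    return out


def replace_excluded(t: TreeRecord, reason: str) -> TreeRecord:
    out = TreeRecord(
        tree_id=t.tree_id,
        species=t.species,
        family=t.family,
        measurements=dict(t.measurements),
    )
    out.excluded = True
    out.exclusion_reason = reason
    return out


def cleaning_report(series: PlotSeries) -> dict:
    return {
        "plot_id": series.plot_id,
        "n_retained": len(series.trees),
        "n_excluded": len(series.excluded_trees),
        "excluded": [
            {"tree_id": t.tree_id, "reason": t.exclusion_reason}
            for t in series.excluded_trees
        ],
        "rows_without_diameter": series.metadata.get("rows_without_diameter", 0),
    }


class GrowthPair(NamedTuple):
    tree_id: str
    d0_cm: float
    dt_cm: float
    dd_per_year: float


def growth_pairs(
    series: PlotSeries, first_year: int | None = None, last_year: int | None = None
) -> list[GrowthPair]:
    """Per-tree (D0, DT, dD/dt) between two censuses.

    Shrinkage (DT < D0, e.g. bark loss or measurement error) is
    recorded as zero annual growth while the raw pair is preserved.
    """
    years = series.census_years
    first_year = years[0] if first_year is None else first_year
    last_year = years[-1] if last_year is None else last_year
    if first_year >= last_year:
        raise ValueError(f"first_year {first_year} must precede last_year {last_year}")
    if first_year not in years or last_year not in years:
        raise ValueError(f"years {first_year}, {last_year} not both present in {years}")
    dt = last_year - first_year
    out = []
    for t in series.trees:
        d0 = t.diameter_at(first_year)
        d1 = t.diameter_at(last_year)
        if d0 is None or d1 is None:
            continue
        rate = max(d1 - d0, 0.0) / dt
        out.append(GrowthPair(t.tree_id, d0, d1, rate))
    return out


_LONG_COLUMNS = [
    "plot_id",
    "tree_id",
    "species",
    "family",
    "year",
    "diameter_cm",
    "height_m",
    "biomass_kg",
]


def write_long(series: PlotSeries, path) -> None:
    """Write the tidy long format (one row per tree per census year).

    Missing measurements become empty fields, never zero; numeric
    values are written as shortest round-tripping decimals.
    """
    rows = []
    for t in series.trees:
        for year, m in t.measurements.items():
            rows.append(
                {
                    "plot_id": series.plot_id,
                    "tree_id": t.tree_id,
                    "species": t.species,
                    "family": t.family,
                    "year": year,
                    "diameter_cm": m.diameter_cm,
                    "height_m": m.height_m,
                    "biomass_kg": m.biomass_kg,
                }
            )
    df = pd.DataFrame(rows, columns=_LONG_COLUMNS)
    df.to_csv(path, index=False)


def read_long(
    path,
    plot_area_m2: float = float("nan"),
    interval_years: float | None = None,
) -> PlotSeries:
    """Read the tidy long format back into a PlotSeries."""
    df = pd.read_csv(
        path, dtype={"tree_id": str, "plot_id": str}, float_precision="round_trip"
    )
    if not set(["plot_id", "tree_id", "year", "diameter_cm"]).issubset(df.columns):
        raise CensusFormatError(f"{path}: not a long-format census file")
    plot_ids = df["plot_id"].unique()
    if len(plot_ids) != 1:
        raise CensusFormatError(f"{path}: expected one plot, found {list(plot_ids)}")
    trees: dict[str, TreeRecord] = {}
    for _, row in df.iterrows():
        tid = str(row["tree_id"])
        rec = trees.get(tid)
        if rec is None:
            species = row.get("species")
            family = row.get("family")
            rec = trees[tid] = TreeRecord(
                tree_id=tid,
                species=None if pd.isna(species) else str(species),
                family=None if pd.isna(family) else str(family),
            )
        def _opt(v):
            return None if pd.isna(v) else float(v)
        rec.measurements[int(row["year"])] = Measurement(
            _opt(row["diameter_cm"]), _opt(row.get("height_m")), _opt(row.get("biomass_kg"))
        )
    for rec in trees.values():
        rec.measurements = dict(sorted(rec.measurements.items()))
    return PlotSeries(
        plot_id=str(plot_ids[0]),
        trees=list(trees.values()),
        plot_area_m2=plot_area_m2,
        interval_years=interval_years,
    )
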