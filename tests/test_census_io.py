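"""Tests for reading, cleaning and reshaping multi-census plot files."""

import numpy as np
import pytest

from ynstand import census_io
from ynstand.census_io import (
    CensusFormatError,
    CleaningRules,
    Measurement,
    PlotSeries,
    TreeRecord,
)


def make_series(plot_id="p", n=4, years=(1985, 1990)):
    trees = []
    for i in range(n):
        meas = {
            y: Measurement(diameter_cm=1.0 + i + 0.5 * j, height_m=2.0 + i, biomass_kg=0.5 + i)
            for j, y in enumerate(years)
        }
        trees.append(TreeRecord(tree_id=f"t{i}", species="Betula ermanii", measurements=meas))
    return PlotSeries(plot_id=plot_id, trees=trees, plot_area_m2=25.0)


class TestReadWide:
    def test_column_detection_two_censuses(self, tmp_path):
        path = tmp_path / "plot.csv"
        path.write_text(
            "Species,Tree.Number,D85,D86\n"
            "Betula ermanii,1,2.0,2.5\n"
            "Acer mono,2,1.0,1.2\n"
            "Quercus crispula,3,3.0,3.3\n"
        )
        s = census_io.read_census_wide(path)
        assert s.census_years == [1985, 1986]
        assert all(len(c.trees) == 3 for c in s.censuses)

    def test_height_and_biomass_columns_attached(self, tmp_path):
        path = tmp_path / "plot.csv"
        path.write_text(
            "Tree.Number,D85,H85,WA85,D86\n1,2.0,3.1,0.8,2.4\n2,1.5,2.2,0.4,1.8\n"
        )
        s = census_io.read_census_wide(path)
        c85 = s.census(1985)
        assert c85.trees[0].height_m == 3.1
        assert c85.trees[0].biomass_kg == 0.8
        assert s.census(1986).trees[0].height_m is None

    def test_unparseable_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "plot.csv"
        path.write_text("Tree.Number,D85,D86\n7,2.0,abc\n")
        with pytest.raises(CensusFormatError, match=r"'7'.*'D86'|D86"):
            census_io.read_census_wide(path)

    def test_no_matching_columns_is_format_error(self, tmp_path):
        path = tmp_path / "plot.csv"
        path.write_text("Tree.Number,DBH\n1,2.0\n")
        with pytest.raises(CensusFormatError):
            census_io.read_census_wide(path)

    def test_rows_without_diameter_dropped_and_counted(self, tmp_path):
        path = tmp_path / "plot.csv"
        path.write_text("Tree.Number,D85,D86\n1,2.0,2.5\n2,,\n3,1.0,1.1\n")
        s = census_io.read_census_wide(path)
        assert len(s.trees) == 2
        assert s.metadata["rows_without_diameter"] == 1

    def test_duplicate_ids_hard_error(self, tmp_path):
        path = tmp_path / "plot.csv"
        path.write_text("Tree.Number,D85,D86\n1,2.0,2.1\n1,3.0,3.1\n")
        with pytest.raises(CensusFormatError, match="duplicate"):
            census_io.read_census_wide(path)


class TestClean:
    def test_missing_final_census_excluded(self):
        s = make_series(n=5)
        # remove the final measurement of one tree
        del s.trees[2].measurements[1990]
        cleaned = census_io.clean_series(s)
        assert len(cleaned.trees) == 4
        assert cleaned.excluded_trees[0].tree_id == "t2"
        assert "final census" in cleaned.excluded_trees[0].exclusion_reason

    def test_explicit_exclusion_list_with_reason(self):
        s = make_series(n=5)
        largest = max(
            s.trees, key=lambda t: t.measurements[1990].diameter_cm
        ).tree_id
        cleaned = census_io.clean_series(s, CleaningRules(exclude_ids=(largest,)))
        assert largest not in [t.tree_id for t in cleaned.trees]
        assert cleaned.excluded_trees[0].exclusion_reason == "listed in exclusion rules"

    def test_identity_when_nothing_to_exclude(self):
        s = make_series()
        assert census_io.clean_series(s) == s

    def test_idempotent(self):
        s = make_series(n=5)
        del s.trees[1].measurements[1990]
        once = census_io.clean_series(s)
        twice = census_io.clean_series(once)
        assert once == twice
        assert len(twice.excluded_trees) == len(once.excluded_trees)

    def test_report_counts(self):
        s = make_series(n=5)
        del s.trees[0].measurements[1990]
        cleaned = census_io.clean_series(s, CleaningRules(exclude_ids=("t4",)))
        rep = census_io.cleaning_report(cleaned)
        assert rep["n_retained"] == 3
        assert rep["n_excluded"] == 2


class TestGrowthPairs:
    def test_annual_rate(self):
        s = make_series(years=(1985, 1990))
        pairs = census_io.growth_pairs(s, 1985, 1990)
        assert pairs[0].dd_per_year == pytest.approx((1.5 - 1.0) / 5)

    def test_shrinkage_clamped_to_zero_raw_preserved(self):
        s = make_series(years=(1985, 1990))
        s.trees[0].measurements[1990] = Measurement(diameter_cm=0.9)
        p = census_io.growth_pairs(s, 1985, 1990)[0]
        assert p.dd_per_year == 0.0
        assert p.d0_cm == 1.0 and p.dt_cm == 0.9

    def test_tree_missing_a_census_omitted(self):
        s = make_series(n=3)
        del s.trees[1].measurements[1990]
        pairs = census_io.growth_pairs(s)
        assert [p.tree_id for p in pairs] == ["t0", "t2"]

    def test_never_negative(self):
        s = make_series(n=4)
        for t in s.trees:
            t.measurements[1990] = Measurement(diameter_cm=t.measurements[1985].diameter_cm * 0.5)
        assert all(p.dd_per_year >= 0 for p in census_io.growth_pairs(s))

    def test_bad_year_order_errors(self):
        s = make_series()
        with pytest.raises(ValueError):
            census_io.growth_pairs(s, 1990, 1985)


class TestLongFormat:
    def test_row_count(self, tmp_path):
        s = make_series(n=2, years=(1985, 1990))
        path = tmp_path / "long.csv"
        census_io.write_long(s, path)
        assert sum(1 for _ in open(path)) == 5  # header + 2 trees x 2 years

    def test_round_trip_equality(self, tmp_path):
        s = make_series(n=6)
        path = tmp_path / "long.csv"
        census_io.write_long(s, path)
        back = census_io.read_long(path, plot_area_m2=25.0)
        assert back == s

    def test_missing_height_stays_missing(self, tmp_path):
        s = make_series(n=2)
        s.trees[0].measurements[1985] = Measurement(diameter_cm=1.0)
        path = tmp_path / "long.csv"
        census_io.write_long(s, path)
        back = census_io.read_long(path)
        assert back.trees[0].measurements[1985].height_m is None
        assert back.trees[0].measurements[1985].biomass_kg is None

    def test_wide_round_trip(self, tmp_path):
        s = make_series(n=3)
        path = tmp_path / "wide.csv"
        census_io.write_wide(s, path)
        back = census_io.read_census_wide(path, plot_id="p", plot_area_m2=25.0)
        assert back == s

    def test_numeric_values_preserved_exactly(self, tmp_path):
        s = make_series(n=1)
        s.trees[0].measurements[1985] = Measurement(diameter_cm=0.1 + 0.2)  # 0.30000000000000004
        path = tmp_path / "long.csv"
        census_io.write_long(s, path)
        back = census_io.read_long(path)
        assert back.trees[0].measurements[1985].diameter_cm == 0.1 + 0.2
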