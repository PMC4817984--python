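"""Descriptors of the eleven Hokkaido secondary-forest study plots.

Published census metadata for the permanent plots the size-structure
growth model was tested on: secondary deciduous broadleaf stands in
Hokkaido, northern Japan, spanning a maturity gradient from 7-year-old
birch regeneration on 25 m2 plots to a <90-year-old oak-dominated
stand on 2500 m2.  Stand age and maximum stem diameter at the initial
census are strongly collinear, which is why either serves as a
maturity surrogate.

Age coding: ranged ages ("7-10") enter as their midpoint, the bounded
age "<90" as 90.  H_max values are in metres (their published column
label says cm, but 4.3-25 are unambiguously metre-scale heights).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_table", "age_dbh_correlation"]

_ROWS = [
    # plot, location, area_m2, age_yr, dbh_max_cm, h_max_m, n_species, n_trees, study_yr, interval_yr
    ("P1", "Ashibetsu", 25, 8.5, 3.0, 4.3, 3, 52, 7, 1),
    ("P2", "Ashibetsu", 25, 8.5, 3.7, 5.4, 4, 75, 8, 1),
    ("P3", "Ashibetsu", 25, 8.5, 4.9, 4.7, 4, 55, 8, 1),
    ("P4", "Tohbetsu", 100, 10.0, 7.0, 10.0, 3, 68, 12, 1),
    ("P5", "Tohbetsu", 100, 13.0, 9.0, 10.0, 2, 18, 9, 1),
    ("P6", "Okoppe", 100, 20.0, 9.5, 12.0, 16, 139, 15, 2),
    ("P7", "Okoppe", 400, 20.0, 13.2, 10.0, 14, 265, 15, 2),
    ("P8", "Bibai", 1000, 20.0, 15.5, 15.0, 14, 389, 7, 2),
    ("P9", "Okoppe", 2000, 62.0, 26.6, 20.0, 13, 141, 15, 2),
    ("P10", "Okoppe", 2000, 62.0, 35.7, 20.0, 18, 232, 15, 2),
    ("P11", "Mitsuishi", 2500, 90.0, 53.1, 25.0, 25, 441, 11, 2),
]

_COLUMNS = [
    "plot",
    "location",
    "area_m2",
    "age_yr",
    "dbh_max_cm",
    "h_max_m",
    "n_species",
    "n_trees",
    "study_years",
    "interval_yr",
]


def plot_table() -> pd.DataFrame:
    """The 11-plot descriptor table, ordered youngest to most mature."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def age_dbh_correlation() -> float:
    """Pearson r between stand age and maximum DBH across the 11 plots."""
    df = plot_table()
    return float(np.corrcoef(df["age_yr"], df["dbh_max_cm"])[0, 1])
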