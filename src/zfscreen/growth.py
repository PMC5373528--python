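"""Rosette-growth screening statistics.

The phenotyping stage of a genome-interrogation screen selects transgenic
lines with enlarged rosettes in two rounds: primary transformants (T1) are
kept when their rosette surface area (RSA) exceeds the tray average by a
factor (default 1.8, i.e. >= 80% larger), and their progeny lines (T2) are
kept when the line's mean RSA at the selection day (default 25 dpg) exceeds
the wild-type mean by a threshold factor (default 1.2, i.e. >= 20% larger).
Growth is summarized by the relative growth rate (RGR), the least-squares
slope of ln(area) against time, and group differences are tested with
Welch's unequal-variance t-test at p < 0.05.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

GROWTH_COLUMNS = ["plant_id", "genotype", "day", "area"]


def validate_growth_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format growth table (plant_id, genotype, day, area)."""
    missing = [c for c in GROWTH_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"growth table missing columns: {missing}")
    if (table["area"] < 0).any():
        bad = table.loc[table["area"] < 0, "plant_id"].unique()
        raise ValueError(f"negative areas for plants: {list(bad[:5])}")
    if (table["day"] < 0).any():
        raise ValueError("negative day values in growth table")
    dup = table.duplicated(subset=["plant_id", "day"])
    if dup.any():
        bad = table.loc[dup, "plant_id"].unique()
        raise ValueError(f"duplicate (plant, day) records for: {list(bad[:5])}")
    return table


def relative_rsa(
    values: Sequence[float], control_values: Sequence[float]
) -> np.ndarray:
    """Per-plant RSA as a percentage of the control population mean.

    Each area is divided by the mean control (Col-0) area and multiplied by
    100, so the control population itself has mean exactly 100%.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control_values is empty")
    control_mean = control.mean()
    if control_mean <= 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    return np.asarray(values, dtype=float) * 100.0 / control_mean


def relative_growth_rate(
    days: Sequence[float],
    areas: Sequence[float],
    window: Tuple[float, float] = (10, 28),
) -> float:
    """Relative growth rate: slope of ln(area) vs day over a day window.

    The default 10-28 dpg window spans the vegetative phase over which
    rosette area grows near-exponentially.  Requires at least two in-window
    time points with strictly positive areas.
    """
    days_arr = np.asarray(days, dtype=float)
    areas_arr = np.asarray(areas, dtype=float)
    if days_arr.shape != areas_arr.shape:
        raise ValueError("days and areas must have equal length")
    mask = (days_arr >= window[0]) & (days_arr <= window[1])
    days_arr, areas_arr = days_arr[mask], areas_arr[mask]
    if days_arr.size < 2:
        raise ValueError(
            f"need >=2 time points within {window}, got {days_arr.size}"
        )
    if (areas_arr <= 0).any():
        raise ValueError("areas must be strictly positive for log-linear RGR")
    slope, _ = np.polyfit(days_arr, np.log(areas_arr), 1)
    return float(slope)


def growth_rates_by_plant(
    table: pd.DataFrame, window: Tuple[float, float] = (10, 28)
) -> pd.DataFrame:
    """Per-plant RGR from a long-format growth table."""
    validate_growth_table(table)
    rows = []
    for (plant, genotype), grp in table.groupby(["plant_id", "genotype"], sort=False):
        grp = grp.sort_values("day")
        rows.append(
            {
                "plant_id": plant,
                "genotype": genotype,
                "rgr": relative_growth_rate(grp["day"], grp["area"], window),
            }
        )
    return pd.DataFrame(rows)


def select_t1_outliers(
    batch_areas: Mapping[str, float], factor: float = 1.8
) -> List[str]:
    """T1 selection: plants whose RSA is at least ``factor`` x the tray mean.

    The tray mean includes every plant in the batch (the candidate itself
    included); the default factor 1.8 selects plants >= 80% larger than the
    tray average.  Ties at the threshold are selected.
    """
    if not batch_areas:
        raise ValueError("batch is empty")
    mean = float(np.mean(list(batch_areas.values())))
    return [p for p, a in batch_areas.items() if a >= factor * mean]


def select_t2_lines(
    line_means: Mapping[str, float], control_mean: float, threshold: float = 1.2
) -> List[str]:
    """T2 selection: lines whose mean RSA >= ``threshold`` x control mean.

    Default threshold 1.2 keeps lines at least 20% larger than the
    wild-type at the selection day (25 dpg in the screen design).
    """
    if control_mean <= 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    return [l for l, m in line_means.items() if m >= threshold * control_mean]


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> Tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    Degrees of freedom follow Welch-Satterthwaite.  When both samples have
    zero variance and equal means the test is degenerate and (0, df, 1) is
    returned by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def grid_neighbor_classes(rows: int, cols: int) -> Dict[int, float]:
    """Fractions of grid cells with 2, 3 and 4 rook-adjacent neighbours.

    Pot trays are laid out as a rows x cols grid; each plant's number of
    orthogonal neighbours determines its local competition class.  A 4x6
    tray of 24 pots yields fractions ~17% (2 neighbours, corners), 50%
    (3 neighbours, edges) and ~33% (4 neighbours, interior).  Cells with
    fewer than two neighbours (degenerate 1-row/1-column grids) are not in
    any of the three reported classes, so the fractions then sum to < 1.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    counts = {2: 0, 3: 0, 4: 0}
    for r in range(rows):
        for c in range(cols):
            n = sum(
                0 <= r + dr < rows and 0 <= c + dc < cols
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            )
            if n in counts:
                counts[n] += 1
    total = rows * cols
    return {k: v / total for k, v in counts.items()}


def screen_summary(
    table: pd.DataFrame,
    control_genotype: str = "Col-0",
    selection_day: int = 25,
    window: Tuple[float, float] = (10, 28),
) -> pd.DataFrame:
    """Per-genotype screen statistics against a control genotype.

    Returns relative RSA at the selection day, mean RGR over the window,
    and the Welch test of each genotype's selection-day areas against the
    control's.
    """
    validate_growth_table(table)
    at_day = table[table["day"] == selection_day]
    control_areas = at_day.loc[
        at_day["genotype"] == control_genotype, "area"
    ].to_numpy()
    if control_areas.size == 0:
        raise ValueError(
            f"no {control_genotype!r} areas at day {selection_day}"
        )
    rgr = growth_rates_by_plant(table, window)
    rows = []
    for genotype, grp in at_day.groupby("genotype", sort=False):
        areas = grp["area"].to_numpy()
        rel = relative_rsa(areas, control_areas)
        if genotype != control_genotype and areas.size >= 2:
            t, df, p = welch_t_test(areas, control_areas)
        else:
            t = df = p = np.nan
        rows.append(
            {
                "genotype": genotype,
                "n_plants": areas.size,
                "mean_relative_rsa_pct": rel.mean(),
                "mean_rgr_per_day": rgr.loc[
                    rgr["genotype"] == genotype, "rgr"
                ].mean(),
                "welch_t": t,
                "welch_df": df,
                "welch_p": p,
            }
        )
    return pd.DataFrame(rows)
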