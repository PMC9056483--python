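"""Seasonal temperature aggregation and paired between-period tests.

Monthly grid temperatures are averaged into three seasonal windows —
March-April (early spring), May-June (late spring/early summer) and
July-August (late summer) — first within each year, then across the years of
each study period. Change between periods is tested with a paired t-test over
grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AltishiftError

SEASONS = {
    "Mar-Apr": (3, 4),
    "May-Jun": (5, 6),
    "Jul-Aug": (7, 8),
}


def seasonal_period_means(monthly: pd.DataFrame, period1: tuple[int, ...],
                          period2: tuple[int, ...]) -> pd.DataFrame:
    """Two-stage seasonal means: per (grid, season, year) first, then across years.

    Raises if any month of a seasonal window is missing for a (grid, year)
    within the study periods, listing the gaps.
    """
    years = {y: 1 for y in period1} | {y: 2 for y in period2}
    df = monthly[monthly["year"].isin(years)].copy()
    df["period"] = df["year"].map(years)

    needed = sorted({m for months in SEASONS.values() for m in months})
    have = df.groupby(["grid_id", "year"])["month"].agg(set)
    gaps = [(gid, yr, sorted(set(needed) - months)) for (gid, yr), months in have.items()
            if set(needed) - months]
    expected = {(g, y) for g in df["grid_id"].unique() for y in years}
    absent = expected - set(have.index)
    if gaps or absent:
        raise AltishiftError(f"missing months in temperature table: gaps={gaps}, "
                             f"absent grid-years={sorted(absent)}")

    rows = []
    for season, months in SEASONS.items():
        sub = df[df["month"].isin(months)]
        yearly = sub.groupby(["grid_id", "period", "year"])["temperature"].mean()
        per_period = yearly.groupby(["grid_id", "period"]).mean().rename("mean_temp")
        out = per_period.reset_index()
        out["season"] = season
        rows.append(out)
    return pd.concat(rows, ignore_index=True)[["grid_id", "season", "period", "mean_temp"]]


@dataclass
class PairedTestResult:
    season: str
    mean_difference: float   # period 2 - period 1, degrees C
    t: float
    df: int
    p: float
    n_grids: int


def paired_t(seasonal: pd.DataFrame, season: str) -> PairedTestResult:
    """Paired t-test of period-2 minus period-1 seasonal means across grids."""
    sub = seasonal[seasonal["season"] == season]
    wide = sub.pivot(index="grid_id", columns="period", values="mean_temp")
    if wide.isna().any().any() or not {1, 2} <= set(wide.columns):
        raise AltishiftError(f"both periods required for every grid in season {season!r}")
    if len(wide) < 2:
        raise AltishiftError("paired t-test needs at least two grids")
    diff = (wide[2] - wide[1]).to_numpy()
    if np.allclose(diff.std(ddof=1), 0.0):
        t = 0.0 if np.allclose(diff.mean(), 0.0) else np.inf * np.sign(diff.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = stats.ttest_rel(wide[2], wide[1])
    return PairedTestResult(season=season, mean_difference=float(diff.mean()),
                            t=float(t), df=len(wide) - 1, p=float(p), n_grids=len(wide))


def seasonal_tests(seasonal: pd.DataFrame) -> pd.DataFrame:
    """All three seasonal paired tests as a tidy table."""
    return pd.DataFrame([paired_t(seasonal, s).__dict__ for s in SEASONS])
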