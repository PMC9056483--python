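"""The abundance-weighted mean-altitude statistic and its building blocks.

For one species, grid cell and study period the statistic is built in four
steps: (1) the mean annual number of individuals per surveyed point,
A = sum(counts) / N with N the years the point was surveyed; (2) points are
binned on a fixed 300-1400 m gradient in 50 m intervals; (3) the mean
abundance per bin, R_i = sum(A) / n_p over the n_p points in the bin; (4) the
abundance-weighted mean altitude M_alt = sum_i (R_i / sum R_i) * M_i where
M_i is the mean altitude of the bin's points. The between-period difference
of M_alt is the altitudinal abundance shift (positive = uphill).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AltishiftError, UndefinedStatisticError

log = logging.getLogger(__name__)

GRADIENT_LOW = 300.0
GRADIENT_HIGH = 1400.0
BIN_WIDTH = 50.0
N_BINS = int((GRADIENT_HIGH - GRADIENT_LOW) / BIN_WIDTH)  # 22


def assign_period(years: pd.Series, period1: tuple[int, ...], period2: tuple[int, ...]) -> pd.Series:
    """Map calendar years onto study periods 1/2; any other year is an error."""
    p1, p2 = set(period1), set(period2)
    out = pd.Series(np.where(years.isin(p1), 1, np.where(years.isin(p2), 2, 0)),
                    index=years.index)
    if (out == 0).any():
        bad = sorted(years[out == 0].unique().tolist())
        raise AltishiftError(f"years outside both study periods: {bad}")
    return out


def altitude_bin(altitude: np.ndarray) -> np.ndarray:
    """Bin index on the fixed gradient; -1 for points outside 300-1400 m.

    Bins are half-open [lower, upper); the last bin [1350, 1400] is closed.
    """
    a = np.asarray(altitude, dtype=float)
    idx = np.floor((a - GRADIENT_LOW) / BIN_WIDTH).astype(int)
    idx[a == GRADIENT_HIGH] = N_BINS - 1
    idx[(a < GRADIENT_LOW) | (a > GRADIENT_HIGH)] = -1
    return idx


def mean_annual_count(counts: pd.DataFrame, point: str, species: str,
                      period_years: tuple[int, ...]) -> float:
    """A for one (point, species, period): summed counts over surveyed years / N."""
    sub = counts[(counts["point_id"] == point) & (counts["species"] == species)
                 & counts["year"].isin(period_years)]
    n_years = sub["year"].nunique()
    if n_years == 0:
        raise UndefinedStatisticError(f"point {point} was never surveyed in the given period")
    return float(sub["count"].sum()) / n_years


def mean_annual_count_table(counts: pd.DataFrame, period1: tuple[int, ...],
                            period2: tuple[int, ...]) -> pd.DataFrame:
    """A for every (grid, point, species, period), plus the point altitude.

    Relies on the count table carrying one row per surveyed point-year-species
    (zeros explicit), so the per-group row count equals the years surveyed.
    """
    df = counts.copy()
    df["period"] = assign_period(df["year"], period1, period2)
    grouped = df.groupby(["grid_id", "point_id", "altitude", "species", "period"],
                         observed=True, sort=False)
    a = grouped["count"].agg(total="sum", n_years="count").reset_index()
    a["A"] = a["total"] / a["n_years"]
    return a.drop(columns="total")


@dataclass
class AltitudeProfile:
    """Binned abundance profile for one (grid, species, period)."""

    grid_id: str
    species: str
    period: int
    bins: pd.DataFrame  # columns: bin, lower, upper, M (mean point altitude), n_points, R


def bin_profile(a_table: pd.DataFrame, grid: str, species: str, period: int) -> AltitudeProfile:
    """Aggregate per-point A values into the fixed altitudinal bins for one group."""
    sub = a_table[(a_table["grid_id"] == grid) & (a_table["species"] == species)
                  & (a_table["period"] == period)].copy()
    sub["bin"] = altitude_bin(sub["altitude"].to_numpy())
    dropped = int((sub["bin"] < 0).sum())
    if dropped:
        log.warning("%d points of grid %s outside the 300-1400 m gradient were excluded",
                    dropped, grid)
    sub = sub[sub["bin"] >= 0]
    agg = sub.groupby("bin").agg(M=("altitude", "mean"), n_points=("altitude", "size"),
                                 R=("A", "mean")).reset_index()
    agg["lower"] = GRADIENT_LOW + agg["bin"] * BIN_WIDTH
    agg["upper"] = agg["lower"] + BIN_WIDTH
    return AltitudeProfile(grid, species, period, agg)


def mean_altitude(profile: AltitudeProfile) -> float:
    """M_alt: R-weighted mean of the per-bin mean point altitudes."""
    r = profile.bins["R"].to_numpy(dtype=float)
    m = profile.bins["M"].to_numpy(dtype=float)
    total = r.sum()
    if total <= 0:
        raise UndefinedStatisticError(
            f"species {profile.species} has zero abundance in grid {profile.grid_id}, "
            f"period {profile.period}")
    return float((r / total) @ m)


def mean_altitude_table(a_table: pd.DataFrame,
                        pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """M_alt for every (grid, species, period); vectorised form of the four steps.

    ``pairs`` optionally restricts the output to selected (species, grid_id)
    combinations. Groups with zero total abundance are dropped (the statistic
    is undefined there) and logged.
    """
    df = a_table.copy()
    df["bin"] = altitude_bin(df["altitude"].to_numpy())
    outside = int((df["bin"] < 0).sum())
    if outside:
        log.warning("%d point-records outside the 300-1400 m gradient were excluded", outside)
    df = df[df["bin"] >= 0]

    per_bin = (df.groupby(["grid_id", "species", "period", "bin"], observed=True, sort=False)
               .agg(M=("altitude", "mean"), R=("A", "mean")).reset_index())
    per_bin["w"] = per_bin["R"]
    g = per_bin.groupby(["grid_id", "species", "period"], observed=True, sort=False)
    out = g.apply(lambda s: pd.Series({
        "m_alt": np.average(s["M"], weights=s["R"]) if s["R"].sum() > 0 else np.nan,
        "total_weight": s["R"].sum(),
    }), include_groups=False).reset_index()
    n_undefined = int(out["m_alt"].isna().sum())
    if n_undefined:
        log.info("%d (grid, species, period) groups had zero abundance; M_alt undefined", n_undefined)
    out = out.dropna(subset=["m_alt"])
    if pairs is not None:
        key = pd.MultiIndex.from_frame(pairs[["species", "grid_id"]])
        out = out[pd.MultiIndex.from_frame(out[["species", "grid_id"]]).isin(key)]
    return out.reset_index(drop=True)


def shift_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per (species, grid) shift = M_alt(period 2) - M_alt(period 1)."""
    wide = records.pivot_table(index=["species", "grid_id"], columns="period",
                               values="m_alt", observed=True)
    missing = wide.index[wide.isna().any(axis=1)]
    if len(missing):
        log.info("%d (species, grid) pairs lack one period and were skipped", len(missing))
    wide = wide.dropna()
    out = wide.reset_index()
    out["shift"] = out[2] - out[1]
    return out.rename(columns={1: "m_alt_p1", 2: "m_alt_p2"})[
        ["species", "grid_id", "m_alt_p1", "m_alt_p2", "shift"]]


def species_mean_shift(shifts: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-species mean shift across grids."""
    g = shifts.groupby("species", observed=True)["shift"]
    return g.agg(mean_shift="mean", n_grids="size").reset_index()
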