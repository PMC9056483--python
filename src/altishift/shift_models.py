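"""Mixed-model estimation of the community-wide uphill shift.

The response is the per (species, grid, period) mean altitude of abundance.
The main model regresses it on study period (numeric 1/2), the grid's mean
longitude and its altitudinal range, with crossed random intercepts for
country, grid and species; the interaction model adds period x longitude and
period x range. The period coefficient of the main model is the headline
uphill shift in metres between the two periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import CrossedLMM, MixedModelFit

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def grid_covariates(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-grid covariates from the retained survey points.

    Altitudinal range is max - min point altitude; longitude/latitude are the
    means over points (the grid centroid used for residual diagnostics).
    """
    pts = counts.drop_duplicates("point_id")
    g = pts.groupby("grid_id").agg(
        country=("country", "first"),
        mean_longitude=("longitude", "mean"),
        mean_latitude=("latitude", "mean"),
        alt_range=("altitude", lambda a: a.max() - a.min()),
    )
    return g.reset_index()


def build_model_frame(records: pd.DataFrame, grid_cov: pd.DataFrame) -> pd.DataFrame:
    """Join M_alt records to grid covariates; one row per (species, grid, period)."""
    return records.merge(grid_cov, on="grid_id", how="left")


def _fit(frame: pd.DataFrame, interactions: bool) -> MixedModelFit:
    X = pd.DataFrame({
        "intercept": 1.0,
        "period": frame["period"].astype(float),
        "mean_longitude": frame["mean_longitude"].astype(float),
        "alt_range": frame["alt_range"].astype(float),
    }, index=frame.index)
    if interactions:
        X["period_x_longitude"] = X["period"] * X["mean_longitude"]
        X["period_x_alt_range"] = X["period"] * X["alt_range"]
    groups = {
        "country": frame["country"],
        "grid": frame["grid_id"],
        "species": frame["species"],
    }
    return CrossedLMM().fit(X, frame["m_alt"], groups)


def main_model(frame: pd.DataFrame) -> MixedModelFit:
    """Period + longitude + altitudinal range with crossed random intercepts."""
    return _fit(frame, interactions=False)


def interaction_model(frame: pd.DataFrame) -> MixedModelFit:
    """Main model plus period x longitude and period x altitudinal range."""
    return _fit(frame, interactions=True)


def great_circle_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances (km) between points given in degrees."""
    lon_r, lat_r = np.radians(lon), np.radians(lat)
    dlat = lat_r[:, None] - lat_r[None, :]
    dlon = lon_r[:, None] - lon_r[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat_r[:, None]) * np.cos(lat_r[None, :]) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Global Moran's I for a binary/continuous symmetric weight matrix."""
    z = values - values.mean()
    w_sum = weights.sum()
    if w_sum == 0 or (z @ z) == 0:
        return float("nan")
    return float(len(values) / w_sum * (z @ (weights @ z)) / (z @ z))


@dataclass
class CorrelogramBin:
    lower_km: float
    upper_km: float
    mid_km: float
    n_pairs: int
    I: float
    env_low: float
    env_high: float


def residual_correlogram(fit: MixedModelFit, frame: pd.DataFrame,
                         max_distance_km: float = 500.0, n_bins: int = 10,
                         n_permutations: int = 999, seed: int = 0) -> pd.DataFrame:
    """Moran's I of grid-mean residuals per distance class, with a permutation envelope.

    Residuals are averaged per grid; distances are great-circle between grid
    centroids; each distance class uses binary weights (pair in class). The
    envelope is the 2.5/97.5 percentile of I under random relabelling of grids.
    """
    resid = pd.DataFrame({
        "grid_id": frame["grid_id"].to_numpy(),
        "resid": fit.resid,
        "lon": frame["mean_longitude"].to_numpy(),
        "lat": frame["mean_latitude"].to_numpy(),
    }).groupby("grid_id").agg(resid=("resid", "mean"), lon=("lon", "first"),
                              lat=("lat", "first"))
    z = resid["resid"].to_numpy()
    d = great_circle_km(resid["lon"].to_numpy(), resid["lat"].to_numpy())
    np.fill_diagonal(d, np.inf)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_permutations)])
    edges = np.linspace(0.0, max_distance_km, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = ((d >= lo) & (d < hi)).astype(float)
        n_pairs = int(w.sum() // 2)
        if n_pairs < 1:
            rows.append(CorrelogramBin(lo, hi, (lo + hi) / 2, 0, np.nan, np.nan, np.nan))
            continue
        obs = morans_i(z, w)
        null = np.array([morans_i(perms[i], w) for i in range(n_permutations)])
        lo_e, hi_e = np.nanpercentile(null, [2.5, 97.5])
        rows.append(CorrelogramBin(lo, hi, (lo + hi) / 2, n_pairs, obs, lo_e, hi_e))
    return pd.DataFrame([r.__dict__ for r in rows])


def per_species_tests(shifts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided one-sample t-test of each species' per-grid shifts against 0."""
    rows = []
    for sp, grp in shifts.groupby("species", observed=True):
        x = grp["shift"].to_numpy(dtype=float)
        row = {"species": sp, "mean_shift": float(x.mean()), "n_grids": len(x),
               "t": np.nan, "df": len(x) - 1, "p": np.nan,
               "direction": "uphill" if x.mean() > 0 else ("downhill" if x.mean() < 0 else "none"),
               "tested": len(x) >= 2, "degenerate_variance": False}
        if len(x) >= 2:
            if np.allclose(x.std(ddof=1), 0.0):
                if x.mean() != 0:
                    row.update(t=np.inf * np.sign(x.mean()), p=0.0, degenerate_variance=True)
                else:
                    row.update(t=0.0, p=1.0, degenerate_variance=True)
            else:
                t, p = stats.ttest_1samp(x, 0.0)
                row.update(t=float(t), p=float(p))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    return out
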