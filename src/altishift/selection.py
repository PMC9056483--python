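"""Survey-point, grid-cell and species inclusion rules.

Points must be surveyed in at least one year of each study period; grids must
span at least 300 m of altitude and hold at least 10 such points; a species
enters the analysis in a grid only when its summed mean annual abundance
reaches 5 in both periods, and enters at all only when it qualifies in at
least 3 grids. A configurable exclusion list drops species whose dynamics are
known to be non-climatic (introduced populations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, NoCommonPointsError
from .metrics import mean_annual_count_table

log = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    min_alt_range: float = 300.0
    min_points_per_grid: int = 10
    min_mean_individuals: float = 5.0
    min_grids_per_species: int = 3
    excluded_species: tuple[str, ...] = ("Branta canadensis",)
    # "mean annual individuals at least five within a grid cell": either the
    # sum of per-point means over the grid ("grid_sum", default) or the mean
    # per point ("per_point").
    abundance_rule: str = "grid_sum"
    # require the abundance threshold in both periods (needed for a defined
    # shift) or in at least one
    require_both_periods: bool = True
    # count grids toward min_grids_per_species by abundance qualification
    # (default) or by mere presence
    grid_count_rule: str = "qualifying"

    def __post_init__(self):
        if min(self.min_alt_range, self.min_points_per_grid, self.min_mean_individuals,
               self.min_grids_per_species) < 0:
            raise ConfigurationError("selection thresholds must be non-negative")
        if self.abundance_rule not in ("grid_sum", "per_point"):
            raise ConfigurationError(f"unknown abundance_rule {self.abundance_rule!r}")
        if self.grid_count_rule not in ("qualifying", "presence"):
            raise ConfigurationError(f"unknown grid_count_rule {self.grid_count_rule!r}")


@dataclass
class SelectionResult:
    counts: pd.DataFrame
    grids: list[str]
    species: list[str]
    pairs: pd.DataFrame            # qualifying (species, grid_id)
    report: dict = field(default_factory=dict)


def filter_points(counts: pd.DataFrame, period1: tuple[int, ...],
                  period2: tuple[int, ...]) -> pd.DataFrame:
    """Keep points surveyed in >= 1 year of each study period."""
    years = counts.groupby("point_id")["year"].agg(set)
    p1, p2 = set(period1), set(period2)
    keep = years[years.apply(lambda ys: bool(ys & p1) and bool(ys & p2))].index
    dropped = len(years) - len(keep)
    if dropped:
        log.info("filter_points: dropped %d of %d points not surveyed in both periods",
                 dropped, len(years))
    if len(keep) == 0:
        raise NoCommonPointsError("no survey point was visited in both study periods")
    return counts[counts["point_id"].isin(keep)].reset_index(drop=True)


def filter_grids(counts: pd.DataFrame, config: SelectionConfig) -> list[str]:
    """Grids with enough altitudinal extent and enough (period-common) points."""
    pts = counts.drop_duplicates("point_id")
    stats = pts.groupby("grid_id")["altitude"].agg(["min", "max", "size"])
    ok = stats[(stats["max"] - stats["min"] >= config.min_alt_range)
               & (stats["size"] >= config.min_points_per_grid)]
    if ok.empty:
        log.warning("filter_grids: no grid passed the range/point thresholds")
    return sorted(ok.index.tolist())


def filter_species(counts: pd.DataFrame, config: SelectionConfig,
                   period1: tuple[int, ...], period2: tuple[int, ...]
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Qualifying (species, grid) pairs and the retained species list.

    A pair qualifies when the grid-level mean annual abundance reaches
    ``min_mean_individuals`` in both periods (or one, per config); a species
    is retained when it qualifies in ``min_grids_per_species`` grids.
    """
    a = mean_annual_count_table(counts, period1, period2)
    agg_fun = "sum" if config.abundance_rule == "grid_sum" else "mean"
    grid_level = (a.groupby(["species", "grid_id", "period"], observed=True)["A"]
                  .agg(agg_fun).unstack("period"))
    for p in (1, 2):
        if p not in grid_level.columns:
            grid_level[p] = float("nan")
    grid_level = grid_level.fillna(0.0)
    meets = grid_level >= config.min_mean_individuals
    qualifies = meets.all(axis=1) if config.require_both_periods else meets.any(axis=1)
    pairs = grid_level[qualifies].reset_index()[["species", "grid_id"]]

    if config.grid_count_rule == "qualifying":
        grids_per_species = pairs.groupby("species")["grid_id"].nunique()
    else:
        present = counts[counts["count"] > 0]
        grids_per_species = present.groupby("species")["grid_id"].nunique()
    species = grids_per_species[grids_per_species >= config.min_grids_per_species].index
    species = [s for s in species if s not in set(config.excluded_species)]
    pairs = pairs[pairs["species"].isin(species)].reset_index(drop=True)
    return pairs, sorted(species)


def apply_selection(counts: pd.DataFrame, config: SelectionConfig,
                    period1: tuple[int, ...], period2: tuple[int, ...]) -> SelectionResult:
    """Run the three filters in order and restrict the count table."""
    n0 = counts["point_id"].nunique()
    counts = filter_points(counts, period1, period2)
    grids = filter_grids(counts, config)
    counts = counts[counts["grid_id"].isin(grids)].reset_index(drop=True)
    pairs, species = filter_species(counts, config, period1, period2)
    counts = counts[counts["species"].isin(species)].reset_index(drop=True)
    report = {
        "n_points_raw": n0,
        "n_points_retained": counts["point_id"].nunique(),
        "n_grids_retained": len(grids),
        "n_species_retained": len(species),
        "n_pairs": len(pairs),
    }
    log.info("selection: %s", report)
    return SelectionResult(counts, grids, species, pairs, report)
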