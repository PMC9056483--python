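"""End-to-end orchestration: selection -> M_alt -> mixed models -> traits -> temperature.

A run is a pure function of its inputs, configuration and seed; every stage
writes a tidy CSV and the headline quantities land in a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import metrics, selection, shift_models, temperature, traits
from .errors import SchemaError
from .selection import SelectionConfig
from .simulate import COUNT_COLUMNS

log = logging.getLogger(__name__)

DEFAULT_PERIOD1 = (1999, 2000, 2001, 2002)
DEFAULT_PERIOD2 = (2015, 2016, 2017, 2018)


@dataclass
class RunConfig:
    counts: str = "counts.csv"
    traits: str = "traits.csv"
    tree: str = "tree.nwk"
    temperature: str = "temperature.csv"
    output_dir: str = "results"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    years_period1: tuple[int, ...] = DEFAULT_PERIOD1
    years_period2: tuple[int, ...] = DEFAULT_PERIOD2
    interaction: bool = True
    correlogram: bool = True
    averaging: str = "conditional"        # or "full"
    lambda_mode: str = "fixed"            # "fixed" (lambda = 1) or "ml"
    use_body_mass: bool = False
    country: str | None = None            # restrict all stages to one country
    trait_excluded_species: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sel = SelectionConfig(**raw.pop("selection", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for key in ("years_period1", "years_period2", "trait_excluded_species"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(selection=sel, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise SchemaError(f"count table lacks columns: {missing}")
    bad = counts.index[counts["count"] < 0]
    if len(bad):
        raise SchemaError(f"negative counts at rows {bad[:10].tolist()}")
    return counts


@dataclass
class RunResult:
    summary: dict
    tables: dict[str, pd.DataFrame]
    fits: dict


def run_all(config: RunConfig, counts: pd.DataFrame | None = None,
            trait_table: pd.DataFrame | None = None,
            tree: dendropy.Tree | None = None,
            monthly_temperature: pd.DataFrame | None = None,
            write: bool = True) -> RunResult:
    """Execute every stage; inputs may be given in memory or loaded from config paths."""
    if counts is None:
        counts = pd.read_csv(config.counts)
    counts = validate_counts(counts)
    if trait_table is None:
        trait_table = pd.read_csv(config.traits).set_index("species")
    if tree is None:
        tree = dendropy.Tree.get(path=config.tree, schema="newick")
    if monthly_temperature is None:
        monthly_temperature = pd.read_csv(config.temperature)

    if config.country:
        counts = counts[counts["country"] == config.country].reset_index(drop=True)
        monthly_temperature = monthly_temperature[
            monthly_temperature["grid_id"].isin(counts["grid_id"].unique())]
        log.info("restricted to country %s: %d grids", config.country,
                 counts["grid_id"].nunique())

    p1, p2 = config.years_period1, config.years_period2

    # --- selection ---------------------------------------------------------
    sel = selection.apply_selection(counts, config.selection, p1, p2)

    # --- derived statistic --------------------------------------------------
    a_table = metrics.mean_annual_count_table(sel.counts, p1, p2)
    records = metrics.mean_altitude_table(a_table, pairs=sel.pairs)
    shifts = metrics.shift_table(records)
    mean_shifts = metrics.species_mean_shift(shifts)

    # --- mixed models -------------------------------------------------------
    grid_cov = shift_models.grid_covariates(sel.counts)
    frame = shift_models.build_model_frame(records, grid_cov)
    fit_main = shift_models.main_model(frame)
    fit_int = shift_models.interaction_model(frame) if config.interaction else None
    correlogram = (shift_models.residual_correlogram(fit_main, frame, seed=config.seed)
                   if config.correlogram else None)
    species_tests = shift_models.per_species_tests(shifts)

    # --- traits -------------------------------------------------------------
    lam = 1.0 if config.lambda_mode == "fixed" else "ml"
    trait_set = traits.fit_trait_models(
        mean_shifts, trait_table, tree, method=config.averaging,
        use_body_mass=config.use_body_mass, lam=lam,
        excluded_species=config.trait_excluded_species)

    # --- temperature --------------------------------------------------------
    seasonal = temperature.seasonal_period_means(monthly_temperature, p1, p2)
    temp_tests = temperature.seasonal_tests(seasonal)

    year_span = (np.mean(p2) - np.mean(p1))  # midpoint-to-midpoint years
    period_coef = float(fit_main.params["period"])
    summary = {
        "selection": sel.report,
        "headline_shift_m": period_coef,
        "headline_shift_m_per_year": period_coef / year_span,
        "year_span": float(year_span),
        "main_model": fit_main.summary_frame().round(6).to_dict(orient="index"),
        "variance_components": fit_main.vcomp,
        "interaction_period_x_alt_range": (
            float(fit_int.params["period_x_alt_range"]) if fit_int else None),
        "n_species_uphill": int((species_tests["mean_shift"] > 0).sum()),
        "n_species_downhill": int((species_tests["mean_shift"] < 0).sum()),
        "n_species_significant_uphill": int(
            ((species_tests["mean_shift"] > 0) & species_tests["significant"]).sum()),
        "n_species_significant_downhill": int(
            ((species_tests["mean_shift"] < 0) & species_tests["significant"]).sum()),
        "n_candidate_trait_models": len(trait_set.fits),
        "best_trait_model": traits.model_label(trait_set.best()),
        "averaged_coefficients": trait_set.averaged.round(6).to_dict(orient="index"),
        "temperature_tests": temp_tests.round(6).to_dict(orient="records"),
        "seed": config.seed,
    }

    model_table = trait_set.table.copy()
    model_table["model"] = model_table["model"].map(traits.model_label)
    tables = {
        "mean_altitude_records": records,
        "shift_table": shifts,
        "species_mean_shifts": mean_shifts,
        "main_model": fit_main.summary_frame().reset_index(names="variable"),
        "interaction_model": (fit_int.summary_frame().reset_index(names="variable")
                              if fit_int else pd.DataFrame()),
        "per_species_tests": species_tests,
        "trait_model_selection": model_table,
        "trait_averaged_coefficients": trait_set.averaged.reset_index(),
        "temperature_tests": temp_tests,
    }
    if correlogram is not None:
        tables["correlogram"] = correlogram

    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tbl in tables.items():
            tbl.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        log.info("wrote %d tables + summary.json to %s", len(tables), outdir)

    return RunResult(summary=summary,
                     tables=tables,
                     fits={"main": fit_main, "interaction": fit_int, "traits": trait_set})


def sensitivity_analysis(config: RunConfig, counts: pd.DataFrame,
                         alt_ranges=(200.0, 300.0, 400.0),
                         min_points=(5, 10, 15),
                         min_individuals=(3.0, 5.0, 10.0)) -> pd.DataFrame:
    """Re-estimate the headline shift under a grid of selection thresholds."""
    rows = []
    for ar in alt_ranges:
        for mp in min_points:
            for mi in min_individuals:
                sel_cfg = dataclasses.replace(config.selection, min_alt_range=ar,
                                              min_points_per_grid=mp,
                                              min_mean_individuals=mi)
                try:
                    sel = selection.apply_selection(counts, sel_cfg, config.years_period1,
                                                    config.years_period2)
                    a_table = metrics.mean_annual_count_table(sel.counts, config.years_period1,
                                                              config.years_period2)
                    records = metrics.mean_altitude_table(a_table, pairs=sel.pairs)
                    frame = shift_models.build_model_frame(
                        records, shift_models.grid_covariates(sel.counts))
                    fit = shift_models.main_model(frame)
                    rows.append({"min_alt_range": ar, "min_points_per_grid": mp,
                                 "min_mean_individuals": mi,
                                 "n_grids": sel.report["n_grids_retained"],
                                 "n_species": sel.report["n_species_retained"],
                                 "shift_m": float(fit.params["period"]),
                                 "shift_se": float(fit.bse["period"])})
                except Exception as exc:  # a threshold combination may empty the data
                    log.warning("sensitivity cell (%s, %s, %s) failed: %s", ar, mp, mi, exc)
                    rows.append({"min_alt_range": ar, "min_points_per_grid": mp,
                                 "min_mean_individuals": mi, "n_grids": 0, "n_species": 0,
                                 "shift_m": np.nan, "shift_se": np.nan})
    return pd.DataFrame(rows)
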