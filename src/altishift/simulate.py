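"""Synthetic point-count surveys with known ground truth.

The generator emulates a two-country mountain bird monitoring design: grid
cells of heterogeneous altitudinal extent hold fixed survey points; every
surveyed point-year yields one count per species, drawn from a Poisson law
whose rate follows a species-specific Gaussian altitudinal abundance profile.
Between the two four-year study periods each species' profile centre moves
uphill by an amount linked to its longevity, which is what the downstream
analysis is meant to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigurationError

MIGRATION_LEVELS = ("resident", "partial", "short-distance", "long-distance")
HABITAT_LEVELS = ("forest", "mire", "alpine", "generalist")

COUNT_COLUMNS = [
    "country", "grid_id", "point_id", "longitude", "latitude",
    "altitude", "year", "species", "count",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey.

    Altitudes are metres, temperatures degrees Celsius. The true uphill shift
    of species ``s`` in grid ``g`` is

        delta_sg = shift_intercept
                   + shift_longevity_slope * z(longevity_s)
                   + shift_range_slope * (altitudinal range of g - its mean)
                   + eps_s,   eps_s ~ N(0, shift_noise_sd^2)

    so ``shift_intercept`` is the community-mean shift and
    ``shift_longevity_slope`` is expressed per standard deviation of longevity.
    """

    seed: int = 0
    n_grids: int = 11
    points_per_grid: int = 30
    n_species: int = 20
    # per-grid altitude band: low ~ U(grid_low), extent ~ U(grid_range);
    # the last grid always gets `small_grid_range` so the 300 m range filter
    # has something to reject.
    grid_low: tuple[float, float] = (300.0, 360.0)
    grid_range: tuple[float, float] = (800.0, 1000.0)
    small_grid_range: float = 250.0
    years_period1: tuple[int, ...] = (1999, 2000, 2001, 2002)
    years_period2: tuple[int, ...] = (2015, 2016, 2017, 2018)
    niche_sd: float = 120.0
    niche_center_range: tuple[float, float] = (600.0, 800.0)
    base_log_abundance: float = 2.0
    shift_intercept: float = 12.0
    shift_longevity_slope: float = -1.3
    shift_range_slope: float = 0.0
    shift_noise_sd: float = 3.5
    visit_prob: float = 0.8
    n_norwegian_grids: int | None = None  # default: n_grids // 5, at least 1
    temp_offsets: tuple[float, float, float] = (0.54, -0.25, -0.04)
    temp_noise_sd: float = 0.1

    def __post_init__(self):
        if self.n_grids < 2:
            raise ConfigurationError("n_grids must be >= 2 (one grid is reserved for the range filter)")
        if self.points_per_grid <= 0:
            raise ConfigurationError("points_per_grid must be positive")
        if self.n_species < 4:
            raise ConfigurationError("n_species must be >= 4 (phylogeny stage)")
        if not (0.0 < self.visit_prob <= 1.0):
            raise ConfigurationError("visit_prob must lie in (0, 1]")
        if self.grid_range[0] <= 0 or self.grid_range[1] < self.grid_range[0]:
            raise ConfigurationError("grid_range must be a positive (low, high) interval")
        if self.niche_sd <= 0:
            raise ConfigurationError("niche_sd must be positive")
        if set(self.years_period1) & set(self.years_period2):
            raise ConfigurationError("study periods must not overlap")

    @property
    def norwegian_grids(self) -> int:
        if self.n_norwegian_grids is not None:
            return self.n_norwegian_grids
        return max(1, self.n_grids // 5)

    def species_names(self) -> list[str]:
        return [f"species_{i + 1:03d}" for i in range(self.n_species)]


@dataclass
class GroundTruth:
    """True generative parameters, kept for recovery tests."""

    niche_center: pd.Series          # species -> mu_s in period 1 (m)
    shift: pd.Series                 # species -> grid-independent part of delta_s (m)
    shift_range_slope: float         # extra shift per metre of grid range (centred)
    traits: pd.DataFrame             # indexed by species
    tree: dendropy.Tree
    newick: str

    def shift_for_grid(self, range_deviation: float) -> pd.Series:
        """True shift in a grid whose altitudinal range deviates from the mean by the given amount."""
        return self.shift + self.shift_range_slope * range_deviation

    def to_json(self) -> str:
        payload = {
            "niche_center": self.niche_center.to_dict(),
            "shift": self.shift.to_dict(),
            "shift_range_slope": self.shift_range_slope,
            "traits": self.traits.reset_index().to_dict(orient="list"),
            "newick": self.newick,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _grid_ids(config: SimulationConfig) -> list[str]:
    return [f"grid_{i + 1:03d}" for i in range(config.n_grids)]


def generate_landscape(config: SimulationConfig) -> pd.DataFrame:
    """Lay out survey points: one row per point with grid, country and coordinates.

    Altitudes are uniform within each grid's declared band. The first grids are
    Norwegian, the remainder Swedish; the last grid's band is narrower than the
    300 m selection threshold by construction.
    """
    rng = np.random.default_rng(config.seed)
    grids = _grid_ids(config)
    n_nor = config.norwegian_grids

    low = rng.uniform(*config.grid_low, size=config.n_grids)
    extent = rng.uniform(*config.grid_range, size=config.n_grids)
    extent[-1] = config.small_grid_range
    lon = rng.uniform(12.0, 25.0, size=config.n_grids)
    lat = rng.uniform(61.0, 69.0, size=config.n_grids)

    frames = []
    for g, (gid, lo, ext, gl, gla) in enumerate(zip(grids, low, extent, lon, lat)):
        alts = rng.uniform(lo, lo + ext, size=config.points_per_grid)
        frames.append(pd.DataFrame({
            "point_id": [f"{gid}_p{j + 1:03d}" for j in range(config.points_per_grid)],
            "grid_id": gid,
            "country": "NOR" if g < n_nor else "SWE",
            "longitude": gl + rng.uniform(-0.3, 0.3, size=config.points_per_grid),
            "latitude": gla + rng.uniform(-0.3, 0.3, size=config.points_per_grid),
            "altitude": alts,
        }))
    return pd.concat(frames, ignore_index=True)


def _simulate_yule_tree(n_species: int, names: list[str], seed: int,
                        birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth ultrametric tree: exponential holding times between splits.

    With k lineages the next split arrives after Exp(k * birth_rate); after the
    n-th lineage appears the tree grows for one more Exp(n * birth_rate)
    holding time, so no terminal branch has zero length.
    """
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    t = 0.0
    root = tree.seed_node
    start = {}
    lineages = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        start[child] = 0.0
        lineages.append(child)
    while len(lineages) < n_species:
        t += rng.exponential(1.0 / (len(lineages) * birth_rate))
        node = lineages.pop(int(rng.integers(len(lineages))))
        node.edge.length = t - start[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            start[child] = t
            lineages.append(child)
    t += rng.exponential(1.0 / (n_species * birth_rate))
    order = rng.permutation(n_species)
    for name_idx, node in zip(order, lineages):
        node.edge.length = t - start[node]
        node.taxon = taxa.get_taxon(names[name_idx])
    return tree


def tree_vcv(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    """Shared root-to-MRCA path lengths between tips (Brownian covariance up to a rate)."""
    from .phylo import phylo_covariance

    return phylo_covariance(tree, species)


def generate_traits_and_tree(config: SimulationConfig) -> GroundTruth:
    """Draw the phylogeny, the trait table and the true shifts.

    Longevity evolves under Brownian motion on the simulated Yule tree, so the
    PGLS error model downstream is correctly specified for the one trait that
    truly drives the shift. The remaining continuous traits are independent
    noise; categorical traits are uniform over their levels.
    """
    rng = np.random.default_rng(config.seed + 1)
    names = config.species_names()
    tree = _simulate_yule_tree(config.n_species, names, seed=config.seed + 2)
    newick = tree.as_string(schema="newick").strip()

    C = tree_vcv(tree, names)
    height = float(np.max(np.diag(C)))
    # unit-marginal Brownian transform: each tip is marginally N(0, 1)
    L_unit = np.linalg.cholesky(C / max(height, 1e-12) + 1e-10 * np.eye(len(names)))
    # Brownian rate chosen so longevity spans a realistic range (~4 yr SD).
    longevity = 10.0 + 4.0 * (L_unit @ rng.standard_normal(len(names)))
    longevity = np.clip(longevity, 2.0, None)

    traits = pd.DataFrame({
        "clutch_size": np.clip(rng.normal(5.0, 1.5, config.n_species), 1.0, None),
        "longevity": longevity,
        "body_mass": np.exp(rng.normal(3.5, 1.0, config.n_species)),
        "sti": rng.normal(10.0, 3.0, config.n_species),
        "population_trend": rng.normal(0.0, 1.0, config.n_species),
        "habitat": rng.choice(HABITAT_LEVELS, config.n_species),
        "diet_specialization": rng.integers(1, 6, config.n_species).astype(float),
        "migration": rng.choice(MIGRATION_LEVELS, config.n_species),
    }, index=pd.Index(names, name="species"))

    z_longevity = (longevity - longevity.mean()) / longevity.std(ddof=0)
    # residual shift noise evolves on the tree as well (marginally
    # N(0, shift_noise_sd^2) at every tip since the tree is ultrametric), so
    # the trait stage's Brownian error model is correctly specified
    eps = config.shift_noise_sd * (L_unit @ rng.standard_normal(config.n_species))
    shift = config.shift_intercept + config.shift_longevity_slope * z_longevity + eps

    lo, hi = config.niche_center_range
    centers = rng.uniform(lo, hi, config.n_species)

    return GroundTruth(
        niche_center=pd.Series(centers, index=names, name="niche_center"),
        shift=pd.Series(shift, index=names, name="shift"),
        shift_range_slope=config.shift_range_slope,
        traits=traits,
        tree=tree,
        newick=newick,
    )


def _visit_matrix(rng, n_points: int, n_years: int, p: float) -> np.ndarray:
    """Bernoulli visits, redrawn per point until every point has >= 1 visit."""
    visits = rng.random((n_points, n_years)) < p
    while True:
        empty = ~visits.any(axis=1)
        if not empty.any():
            return visits
        visits[empty] = rng.random((int(empty.sum()), n_years)) < p


def generate_counts(landscape: pd.DataFrame, truth: GroundTruth,
                    config: SimulationConfig) -> pd.DataFrame:
    """Per point-year-species Poisson counts; zero counts are explicit rows.

    The rate for species ``s`` at altitude ``a`` is
    ``exp(base_log_abundance - (a - mu_s)^2 / (2 niche_sd^2))`` with ``mu_s``
    moved by the species' true shift in period 2. Only surveyed point-years
    produce rows, and every surveyed point-year carries one row per species so
    that surveyed-but-empty visits are observable downstream.
    """
    rng = np.random.default_rng(config.seed + 3)
    species = list(truth.niche_center.index)
    n_sp = len(species)

    grid_range = landscape.groupby("grid_id")["altitude"].agg(lambda a: a.max() - a.min())
    range_dev = grid_range - grid_range.mean()

    out = []
    for period, years in ((1, config.years_period1), (2, config.years_period2)):
        visits = _visit_matrix(rng, len(landscape), len(years), config.visit_prob)
        mu = truth.niche_center.to_numpy()[None, :]  # (1, S)
        if period == 2:
            # per-grid true shift: species component + range-deviation component
            dev = landscape["grid_id"].map(range_dev).to_numpy()[:, None]
            mu = mu + truth.shift.to_numpy()[None, :] + truth.shift_range_slope * dev
        a = landscape["altitude"].to_numpy()[:, None]
        lam = np.exp(config.base_log_abundance - (a - mu) ** 2 / (2.0 * config.niche_sd ** 2))
        for yi, year in enumerate(years):
            idx = np.flatnonzero(visits[:, yi])
            counts = rng.poisson(lam[idx])  # (n_visited, S)
            block = landscape.iloc[np.repeat(idx, n_sp)].reset_index(drop=True)
            block["year"] = year
            block["species"] = np.tile(species, len(idx))
            block["count"] = counts.ravel()
            out.append(block)
    table = pd.concat(out, ignore_index=True)[COUNT_COLUMNS]
    return table.sort_values(["grid_id", "point_id", "year", "species"], ignore_index=True)


def generate_temperature(config: SimulationConfig, grid_ids: list[str] | None = None) -> pd.DataFrame:
    """Monthly grid temperatures: seasonal sinusoid plus second-period seasonal offsets.

    The offsets apply to March-April, May-June and July-August respectively
    and default to the warming/cooling pattern the analysis is meant to detect.
    """
    rng = np.random.default_rng(config.seed + 4)
    if grid_ids is None:
        grid_ids = _grid_ids(config)
    years = list(config.years_period1) + list(config.years_period2)
    period2 = set(config.years_period2)
    off = {3: config.temp_offsets[0], 4: config.temp_offsets[0],
           5: config.temp_offsets[1], 6: config.temp_offsets[1],
           7: config.temp_offsets[2], 8: config.temp_offsets[2]}

    base = rng.uniform(-2.0, 4.0, size=len(grid_ids))
    rows = []
    for gid, b in zip(grid_ids, base):
        for year in years:
            months = np.arange(1, 13)
            temp = b + 10.0 * np.sin(2.0 * np.pi * (months - 4) / 12.0)
            if year in period2:
                temp = temp + np.array([off.get(m, 0.0) for m in months])
            temp = temp + rng.normal(0.0, config.temp_noise_sd, size=12)
            rows.append(pd.DataFrame({
                "grid_id": gid, "year": year, "month": months, "temperature": temp,
            }))
    return pd.concat(rows, ignore_index=True)


@dataclass
class SimulatedBundle:
    """Everything one synthetic study produces."""

    config: SimulationConfig
    landscape: pd.DataFrame
    counts: pd.DataFrame
    temperature: pd.DataFrame
    truth: GroundTruth


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Run all four generators with a shared seed."""
    landscape = generate_landscape(config)
    truth = generate_traits_and_tree(config)
    counts = generate_counts(landscape, truth, config)
    temperature = generate_temperature(config)
    return SimulatedBundle(config, landscape, counts, temperature, truth)


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> dict[str, Path]:
    """Write counts/traits/temperature CSVs, the Newick tree and the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.csv",
        "traits": outdir / "traits.csv",
        "temperature": outdir / "temperature.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "ground_truth.json",
        "config": outdir / "simulation_config.json",
    }
    bundle.counts.to_csv(paths["counts"], index=False)
    bundle.truth.traits.reset_index().to_csv(paths["traits"], index=False)
    bundle.temperature.to_csv(paths["temperature"], index=False)
    paths["tree"].write_text(bundle.truth.newick + "\n")
    paths["truth"].write_text(bundle.truth.to_json())
    paths["config"].write_text(json.dumps(asdict(bundle.config), indent=2))
    return paths
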