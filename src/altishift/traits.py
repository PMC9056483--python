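"""Trait analysis of shift speed: PGLS over a 16-model hypothesis set.

Species-level mean shifts are regressed on trait combinations under a
Brownian-motion phylogenetic error structure (lambda = 1 by default, i.e. the
error covariance is proportional to shared root-to-MRCA path lengths). The
candidate set is every subset of four hypothesis groups — fastness-slowness
of life history, ecological niche, migratory behaviour, population dynamics —
ranked by AICc, with Akaike-weight model averaging of all models within a
configurable AICc window.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AltishiftError, RankDeficiencyError
from .phylo import phylo_covariance
from .simulate import MIGRATION_LEVELS

log = logging.getLogger(__name__)

# hypothesis group -> trait columns; body mass replaces longevity in the
# mass variant of the fastness-slowness group
HYPOTHESIS_GROUPS = {
    "fastness_slowness": ("clutch_size", "longevity"),
    "ecological_niche": ("habitat", "diet_specialization", "sti"),
    "migratory_behaviour": ("migration",),
    "population_dynamics": ("population_trend",),
}

CONTINUOUS_TRAITS = ("clutch_size", "longevity", "body_mass", "sti",
                     "population_trend", "diet_specialization")


def standardize_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean unit-SD copies of the continuous trait columns (over included species)."""
    out = traits.copy()
    for col in CONTINUOUS_TRAITS:
        if col in out.columns:
            x = out[col].astype(float)
            sd = x.std(ddof=0)
            if sd == 0:
                raise AltishiftError(f"trait {col!r} is constant; cannot standardize")
            out[col] = (x - x.mean()) / sd
    return out


def collinearity_report(traits: pd.DataFrame, threshold: float = 0.5) -> list[tuple[str, str, float]]:
    """Warn about |Spearman r| >= threshold among continuous traits; no automatic exclusion."""
    cols = [c for c in CONTINUOUS_TRAITS if c in traits.columns]
    flagged = []
    for a, b in itertools.combinations(cols, 2):
        r, _ = stats.spearmanr(traits[a], traits[b])
        if np.isfinite(r) and abs(r) >= threshold:
            flagged.append((a, b, float(r)))
            warnings.warn(f"traits {a!r} and {b!r} are strongly correlated (Spearman r={r:.3f})")
    return flagged


def design_matrix(traits: pd.DataFrame, groups: frozenset[str],
                  use_body_mass: bool = False) -> pd.DataFrame:
    """Design columns (with intercept) for one hypothesis combination.

    Categorical traits are dummy-coded against a baseline (first habitat level
    alphabetically; 'resident' for migration).
    """
    X = pd.DataFrame({"intercept": 1.0}, index=traits.index)
    for gname in sorted(groups):
        for col in HYPOTHESIS_GROUPS[gname]:
            if col == "longevity" and use_body_mass:
                col = "body_mass"
            if col == "habitat":
                levels = sorted(traits["habitat"].unique())
                for lev in levels[1:]:
                    X[f"habitat[{lev}]"] = (traits["habitat"] == lev).astype(float)
            elif col == "migration":
                for lev in MIGRATION_LEVELS[1:]:
                    X[f"migration[{lev}]"] = (traits["migration"] == lev).astype(float)
            else:
                X[col] = traits[col].astype(float)
    return X


@dataclass
class PglsFit:
    """One PGLS fit (maximum likelihood in sigma^2, fixed lambda)."""

    params: pd.Series
    bse: pd.Series
    loglik: float
    k: int                       # parameters counted for AICc: slopes + intercept + sigma^2
    sigma2_ml: float
    n: int
    lam: float = 1.0

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def pvalues(self) -> pd.Series:
        df = self.n - len(self.params)
        return pd.Series(2.0 * stats.t.sf(np.abs(self.tvalues), df), index=self.params.index)


def _scale_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def pgls_fit(y: np.ndarray | pd.Series, X: pd.DataFrame, C: np.ndarray,
             lam: float | str = 1.0) -> PglsFit:
    """Generalized least squares with error covariance sigma^2 * C.

    beta = (X' C^-1 X)^-1 X' C^-1 y; sigma^2 is the ML estimate (residual
    quadratic form / n); the log-likelihood is that of the multivariate
    normal. ``lam="ml"`` profiles Pagel's lambda over [0, 1].
    """
    yv = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xm = np.asarray(X, dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise AltishiftError(f"need more species ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(Xm) < p:
        # name degenerate columns: those whose removal restores full rank
        bad = [names[j] for j in range(p)
               if np.linalg.matrix_rank(np.delete(Xm, j, axis=1)) == np.linalg.matrix_rank(Xm)]
        raise RankDeficiencyError(bad or names)

    def fit_fixed(l: float) -> PglsFit:
        Cl = _scale_lambda(C, l)
        try:
            L = np.linalg.cholesky(Cl)
        except np.linalg.LinAlgError:
            log.info("covariance not positive definite; adding 1e-10 jitter to the diagonal")
            L = np.linalg.cholesky(Cl + 1e-10 * np.eye(n))
        # whiten: solve L a = y etc.
        yw = np.linalg.solve(L, yv)
        Xw = np.linalg.solve(L, Xm)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        r = yw - Xw @ beta
        rss = float(r @ r)
        sigma2 = rss / n
        logdetC = 2.0 * np.log(np.diag(L)).sum()
        loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdetC + n)
        # SEs use the unbiased variance estimate, as GLS software reports
        cov = rss / (n - p) * np.linalg.inv(XtX)
        return PglsFit(
            params=pd.Series(beta, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
            loglik=float(loglik), k=p + 1, sigma2_ml=sigma2, n=n, lam=l,
        )

    if lam == "ml":
        res = optimize.minimize_scalar(lambda l: -fit_fixed(l).loglik,
                                       bounds=(0.0, 1.0), method="bounded")
        return fit_fixed(float(res.x))
    return fit_fixed(float(lam))


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); undefined when n <= k + 1."""
    if k < 2:
        raise AltishiftError("k must count at least the intercept and sigma^2 (k >= 2)")
    if n - k - 1 <= 0:
        raise AltishiftError(f"AICc undefined for n={n}, k={k} (n must exceed k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def enumerate_models(groups: dict[str, tuple[str, ...]] | None = None) -> list[frozenset[str]]:
    """All subsets of the hypothesis groups, null through full (2^4 = 16 by default)."""
    names = sorted(groups or HYPOTHESIS_GROUPS)
    out = []
    for r in range(len(names) + 1):
        out.extend(frozenset(c) for c in itertools.combinations(names, r))
    return out


@dataclass
class TraitModelSet:
    """The fitted candidate set plus its AICc ranking and averaged coefficients."""

    table: pd.DataFrame                    # model, k, loglik, AICc, delta_aicc, weight
    fits: dict[frozenset, PglsFit]
    averaged: pd.DataFrame                 # estimate, se, z, p per coefficient
    window: float

    def best(self) -> frozenset:
        return self.table.iloc[0]["model"]


def model_average(fits: dict[frozenset, PglsFit], window: float = 4.0,
                  method: str = "conditional") -> tuple[pd.DataFrame, pd.DataFrame]:
    """AICc ranking plus averaged coefficients over models within the window.

    Conditional (natural) averaging averages each coefficient over the window
    models that contain it; full averaging substitutes 0 (with 0 variance) in
    models that do not. Averaged SEs use the standard within + between-model
    variance formula.
    """
    rows = []
    for model, fit in fits.items():
        rows.append({"model": model, "k": fit.k, "loglik": fit.loglik,
                     "aicc": aicc(fit.loglik, fit.k, fit.n)})
    table = pd.DataFrame(rows).sort_values("aicc", ignore_index=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    rel = np.exp(-0.5 * table["delta_aicc"])
    table["weight"] = rel / rel.sum()

    in_window = table[table["delta_aicc"] <= window]
    w = in_window["weight"].to_numpy()
    w = w / w.sum()
    window_models = list(in_window["model"])

    coef_names: list[str] = []
    for m in window_models:
        for c in fits[m].params.index:
            if c not in coef_names:
                coef_names.append(c)

    avg_rows = []
    for cname in coef_names:
        betas, ses, weights = [], [], []
        for wm, m in zip(w, window_models):
            fit = fits[m]
            if cname in fit.params.index:
                betas.append(fit.params[cname]); ses.append(fit.bse[cname]); weights.append(wm)
            elif method == "full":
                betas.append(0.0); ses.append(0.0); weights.append(wm)
        betas, ses, weights = map(np.asarray, (betas, ses, weights))
        weights = weights / weights.sum()
        est = float(weights @ betas)
        se = float(weights @ np.sqrt(ses ** 2 + (betas - est) ** 2))
        z = est / se if se > 0 else np.nan
        avg_rows.append({"coefficient": cname, "estimate": est, "se": se, "z": z,
                         "p": 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                         "n_models": int((weights > 0).sum())})
    averaged = pd.DataFrame(avg_rows).set_index("coefficient")
    return table, averaged


def fit_trait_models(mean_shifts: pd.DataFrame, traits: pd.DataFrame, tree,
                     window: float = 4.0, method: str = "conditional",
                     use_body_mass: bool = False, lam: float | str = 1.0,
                     excluded_species: tuple[str, ...] = ()) -> TraitModelSet:
    """Full trait stage: standardize, build the 16 designs, fit PGLS, rank, average.

    ``mean_shifts`` needs columns species/mean_shift; species present in the
    shifts but absent from traits or tree raise; ``excluded_species`` drops
    species before standardization (e.g. a trait value of doubtful provenance).
    """
    df = mean_shifts[~mean_shifts["species"].isin(set(excluded_species))]
    species = sorted(df["species"])
    missing = [s for s in species if s not in traits.index]
    if missing:
        raise AltishiftError(f"species missing from trait table: {missing}")
    tr = standardize_traits(traits.loc[species])
    collinearity_report(tr)
    y = df.set_index("species").loc[species, "mean_shift"].to_numpy()
    C = phylo_covariance(tree, species)

    fits = {}
    for model in enumerate_models():
        X = design_matrix(tr, model, use_body_mass=use_body_mass)
        fits[model] = pgls_fit(y, X, C, lam=lam)
    table, averaged = model_average(fits, window=window, method=method)
    return TraitModelSet(table=table, fits=fits, averaged=averaged, window=window)


def model_label(model: frozenset) -> str:
    return " + ".join(sorted(model)) if model else "null"
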