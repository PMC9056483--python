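"""Gaussian linear mixed model with crossed random intercepts, fitted by REML.

The model is y = X beta + sum_k Z_k b_k + e with b_k ~ N(0, s2_k I) for each
grouping factor (country, grid, species in the shift analysis) and
e ~ N(0, s2_e I). The REML criterion is profiled over the variance ratios
gamma_k = s2_k / s2_e: for fixed gamma the GLS estimate of beta and the
residual variance are closed-form, so the optimiser only searches the
K-dimensional log-ratio space. All solves use the Woodbury identity on
W = I + Z Gamma Z', which keeps the cost at O(n q^2) for q total random
levels rather than O(n^3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import RankDeficiencyError

log = logging.getLogger(__name__)

_LOG_VAR_BOUND = 20.0
_REML_TOL = 1e-10
_MAX_ITER = 500


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved via pivoted QR
        _, r, piv = linalg.qr(X, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(X.shape[1]) if i >= len(diag) or diag[i] <= tol]
        raise RankDeficiencyError(bad)


@dataclass
class MixedModelFit:
    """REML fit: fixed effects, variance components, diagnostics."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: float
    vcomp: dict[str, float]          # per-factor variance + "residual"
    reml_criterion: float            # -2 * restricted log-likelihood (up to a constant)
    fittedvalues: np.ndarray
    resid: np.ndarray
    ranef: dict[str, pd.Series]
    converged: bool
    n_obs: int

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse, "df": self.df_resid,
            "t": self.tvalues, "p": self.pvalues,
        })


class CrossedLMM:
    """REML estimator for a Gaussian LMM with crossed random intercepts.

    Parameters
    ----------
    tol : float
        Relative convergence tolerance on the profiled REML criterion.
    """

    def __init__(self, tol: float = _REML_TOL, max_iter: int = _MAX_ITER):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y: np.ndarray | pd.Series,
            groups: dict[str, pd.Series | np.ndarray]) -> MixedModelFit:
        """Fit by REML.

        ``X`` must already contain an intercept column if one is wanted;
        ``groups`` maps factor names to label vectors. Factors with a single
        level are dropped with a warning.
        """
        names = list(X.columns)
        Xm = np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float)
        n, p = Xm.shape
        _check_rank(Xm, names)

        Zs, factor_names, level_index = [], [], []
        for fname, labels in groups.items():
            codes, levels = pd.factorize(np.asarray(labels))
            if len(levels) < 2:
                warnings.warn(f"random factor {fname!r} has a single level; dropped")
                continue
            Z = np.zeros((n, len(levels)))
            Z[np.arange(n), codes] = 1.0
            Zs.append(Z)
            factor_names.append(fname)
            level_index.append(levels)
        K = len(Zs)
        sizes = [Z.shape[1] for Z in Zs]
        Zall = np.hstack(Zs) if K else np.zeros((n, 0))

        def profile(log_gamma: np.ndarray):
            """Profiled REML pieces for fixed variance ratios."""
            gamma = np.exp(np.clip(log_gamma, -_LOG_VAR_BOUND, _LOG_VAR_BOUND))
            sg = np.repeat(np.sqrt(gamma), sizes)
            M = Zall * sg                                 # n x q
            A = M.T @ M + np.eye(M.shape[1])              # I_q + M'M
            cA = np.linalg.cholesky(A)
            logdetW = 2.0 * np.log(np.diag(cA)).sum()

            def Winv(U):
                MtU = M.T @ U
                return U - M @ np.linalg.solve(A, MtU)

            WiX = Winv(Xm)
            Wiy = Winv(yv)
            XtWiX = Xm.T @ WiX
            beta = np.linalg.solve(XtWiX, Xm.T @ Wiy)
            r = yv - Xm @ beta
            rss = float(r @ Winv(r))
            sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
            crit = logdetW + logdetXtWiX + (n - p) * np.log(rss)
            return crit, beta, rss, XtWiX, Winv, gamma, M

        if K:
            res = optimize.minimize(
                lambda lg: profile(lg)[0], x0=np.zeros(K), method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": self.tol, "maxiter": self.max_iter * K,
                         "maxfev": self.max_iter * K},
            )
            log_gamma, converged = res.x, bool(res.success)
        else:
            log_gamma, converged = np.zeros(0), True

        crit, beta, rss, XtWiX, Winv, gamma, M = profile(log_gamma)
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(XtWiX)
        bse = np.sqrt(np.diag(cov))
        df = float(n - p)
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

        vcomp = {f: float(g * sigma2) for f, g in zip(factor_names, gamma)}
        vcomp["residual"] = float(sigma2)

        # BLUPs: b = Gamma Z' W^{-1} (y - X beta), in original (unscaled) units
        resid_marginal = yv - Xm @ beta
        ranef: dict[str, pd.Series] = {}
        if K:
            Wir = Winv(resid_marginal)
            offset = 0
            for f, Z, g, levels in zip(factor_names, Zs, gamma, level_index):
                b = g * (Z.T @ Wir)
                ranef[f] = pd.Series(b, index=levels, name=f)
                offset += Z.shape[1]
        blup_contrib = sum((Zs[i] @ ranef[factor_names[i]].to_numpy() for i in range(K)),
                           np.zeros(n))
        fitted = Xm @ beta + blup_contrib

        return MixedModelFit(
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(pvals, index=names),
            df_resid=df,
            vcomp=vcomp,
            reml_criterion=float(crit),
            fittedvalues=fitted,
            resid=yv - fitted,
            ranef=ranef,
            converged=converged,
            n_obs=n,
        )
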