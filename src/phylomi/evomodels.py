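"""Maximum-likelihood fits of BM, OU and EB trait-evolution models.

Three classic Gaussian models of continuous trait evolution on a tree:

* **BM** — Brownian motion, variance grows linearly with time;
  Cov(i, j) = sigma2 * t_ij, with t_ij the root-to-MRCA depth.
* **OU** — Ornstein-Uhlenbeck, a random walk pulled toward an optimum theta
  with strength alpha; with the root at the optimum,
  Cov(i, j) = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij)),
  d_ij the patristic distance between tips i and j.
* **EB** — early burst, BM whose rate decays as exp(a t) with a <= 0, so a
  branch running from time t1 to t2 contributes (exp(a t2) - exp(a t1))/a;
  along root-to-MRCA paths this integrates to Cov(i, j) =
  sigma2 * (exp(a t_ij) - 1)/a.

For each model the root state (and OU optimum) and the rate sigma2 profile
out analytically; OU's alpha and EB's a are found by a deterministic grid
search refined with bounded scalar minimization.  Model fit is compared by
AIC (no small-sample correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .tables import TraitTable
from .trees import Phylogeny, PhyloCovariance, phylo_vcv

__all__ = [
    "EvoModelFit",
    "bm_covariance",
    "ou_covariance",
    "eb_covariance",
    "fit_bm",
    "fit_ou",
    "fit_eb",
    "compare_models",
    "per_landmass_analysis",
    "assess_fit_by_simulation",
]

_ALPHA_TINY = 1e-10


def bm_covariance(C: np.ndarray) -> np.ndarray:
    """Unit-rate BM covariance (the phylogenetic VCV itself)."""
    return np.asarray(C, dtype=float).copy()


def ou_covariance(C: np.ndarray, alpha: float) -> np.ndarray:
    """Unit-rate OU covariance from the BM matrix (root at the optimum)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    C = np.asarray(C, dtype=float)
    if alpha < _ALPHA_TINY:
        return C.copy()
    t = np.diag(C)
    d = t[:, None] + t[None, :] - 2.0 * C  # patristic distances
    return np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * C)) / (2.0 * alpha)


def eb_covariance(C: np.ndarray, eb_rate: float) -> np.ndarray:
    """Unit-rate early-burst covariance from the BM matrix (a <= 0)."""
    if eb_rate > 0:
        raise ValueError("eb_rate must be <= 0")
    C = np.asarray(C, dtype=float)
    if eb_rate == 0:
        return C.copy()
    return np.expm1(eb_rate * C) / eb_rate


@dataclass
class EvoModelFit:
    model: str  # "BM" | "OU" | "EB"
    sigma2: float
    z0: float
    loglik: float
    n_params: int
    aic: float
    alpha: float | None = None
    theta: float | None = None
    eb_rate: float | None = None
    delta_aic: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _profile_loglik(y: np.ndarray, M: np.ndarray) -> tuple[float, float, float]:
    """(loglik, z0_hat, sigma2_hat) for y ~ N(z0*1, sigma2*M), profiled."""
    n = y.size
    cf = cho_factor(M, lower=True)
    ones = np.ones(n)
    Mi1 = cho_solve(cf, ones)
    z0 = float(ones @ cho_solve(cf, y) / (ones @ Mi1))
    r = y - z0
    q = float(r @ cho_solve(cf, r))
    if q <= 0 or not np.isfinite(q):
        raise ValueError("degenerate trait: zero residual variance under the model")
    sigma2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)
    return ll, z0, sigma2


def _resolve_C(tree: Phylogeny | None, C: PhyloCovariance | np.ndarray | None) -> np.ndarray:
    if C is None:
        if tree is None:
            raise ValueError("either tree or C must be given")
        C = phylo_vcv(tree)
    return C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)


def _check_y(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 tips")
    if np.ptp(y) == 0:
        raise ValueError("degenerate trait: constant values")
    return y


def fit_bm(y, tree: Phylogeny | None = None, C=None) -> EvoModelFit:
    """ML Brownian-motion fit (2 parameters: sigma2, root state)."""
    y = _check_y(y)
    Cm = _resolve_C(tree, C)
    ll, z0, s2 = _profile_loglik(y, Cm)
    return EvoModelFit("BM", s2, z0, ll, 2, 2 * 2 - 2 * ll)


def _optimize_1d(y, Cm, builder, lo, hi, n_grid=32, log_grid=False):
    """Grid + bounded refinement of a single structural parameter."""

    def nll(p):
        try:
            return -_profile_loglik(y, builder(Cm, p))[0]
        except (np.linalg.LinAlgError, ValueError):
            return np.inf

    grid = np.geomspace(lo, hi, n_grid) if log_grid else np.linspace(lo, hi, n_grid)
    vals = np.array([nll(p) for p in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    if a == b:
        best_p, best_v = grid[k], vals[k]
    else:
        res = minimize_scalar(nll, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-10})
        best_p, best_v = float(res.x), float(res.fun)
        if vals[k] < best_v:
            best_p, best_v = float(grid[k]), float(vals[k])
    return best_p, -best_v


def fit_ou(y, tree: Phylogeny | None = None, C=None) -> EvoModelFit:
    """ML Ornstein-Uhlenbeck fit (3 parameters: sigma2, alpha, theta = z0).

    alpha is searched over [1e-8, 50/depth] on a log grid with bounded
    refinement; the BM limit (alpha -> 0) is always evaluated so the OU
    log-likelihood can never fall below BM's.
    """
    y = _check_y(y)
    Cm = _resolve_C(tree, C)
    T = float(np.diag(Cm).max())
    lo, hi = 1e-8, 50.0 / T
    alpha, ll = _optimize_1d(y, Cm, ou_covariance, lo, hi, log_grid=True)
    ll_bm, z0_bm, s2_bm = _profile_loglik(y, Cm)
    if ll_bm >= ll:  # alpha -> 0 nesting limit
        alpha, ll = 0.0, ll_bm
        z0, s2 = z0_bm, s2_bm
    else:
        ll, z0, s2 = _profile_loglik(y, ou_covariance(Cm, alpha))
    if alpha >= hi * (1 - 1e-6):
        warnings.warn("OU alpha at upper search bound: white-noise limit", stacklevel=2)
    return EvoModelFit("OU", s2, z0, ll, 3, 2 * 3 - 2 * ll, alpha=alpha, theta=z0)


def fit_eb(y, tree: Phylogeny | None = None, C=None) -> EvoModelFit:
    """ML early-burst fit (3 parameters: sigma2, a, root state).

    The decay a is searched over [-10/depth, 0]; a = 0 (plain BM) is an
    explicit candidate, so EB's log-likelihood can never fall below BM's.
    """
    y = _check_y(y)
    Cm = _resolve_C(tree, C)
    T = float(np.diag(Cm).max())
    a, ll = _optimize_1d(y, Cm, eb_covariance, -10.0 / T, 0.0)
    ll_bm, z0_bm, s2_bm = _profile_loglik(y, Cm)
    if ll_bm >= ll:  # a -> 0 nesting limit
        a, ll, z0, s2 = 0.0, ll_bm, z0_bm, s2_bm
    else:
        ll, z0, s2 = _profile_loglik(y, eb_covariance(Cm, a))
    return EvoModelFit("EB", s2, z0, ll, 3, 2 * 3 - 2 * ll, eb_rate=a)


def compare_models(y, tree: Phylogeny | None = None, C=None) -> list[EvoModelFit]:
    """Fit BM, OU and EB and rank them by AIC (ascending, with delta AIC)."""
    fits = [fit_bm(y, tree, C), fit_ou(y, tree, C), fit_eb(y, tree, C)]
    fits.sort(key=lambda f: f.aic)
    best = fits[0].aic
    for f in fits:
        f.delta_aic = f.aic - best
    return fits


def per_landmass_analysis(
    table: TraitTable,
    tree: Phylogeny,
    subset_column: str = "origin",
    traits: tuple[str, ...] = ("log_ecv", "log_body"),
    min_tips: int = 10,
) -> pd.DataFrame:
    """Rank evolutionary models per subset (e.g. landmass) and trait.

    The tree is pruned to each level of ``subset_column``; subsets smaller
    than ``min_tips`` are skipped with a warning.  Returns one row per
    (subset, trait, model).
    """
    rows = []
    for level in table.levels(subset_column):
        taxa = [s for s in table.species
                if table.df.loc[s, subset_column] == level]
        if len(taxa) < min_tips:
            warnings.warn(
                f"subset {subset_column}={level!r} has {len(taxa)} tips "
                f"(< {min_tips}); skipped", stacklevel=2)
            continue
        sub = tree.prune_to(taxa)
        Csub = phylo_vcv(sub)
        for trait in traits:
            y = table.df.loc[Csub.taxa, trait].astype(float).to_numpy()
            for rank, fit in enumerate(compare_models(y, C=Csub)):
                rows.append({
                    "subset": level, "trait": trait, "model": fit.model,
                    "sigma2": fit.sigma2, "z0": fit.z0, "alpha": fit.alpha,
                    "eb_rate": fit.eb_rate, "loglik": fit.loglik,
                    "aic": fit.aic, "delta_aic": fit.delta_aic,
                    "best": rank == 0, "n_tips": len(taxa),
                })
    return pd.DataFrame(rows)


def assess_fit_by_simulation(y, tree: Phylogeny, fit: EvoModelFit,
                             n_sim: int = 200, seed: int = 0) -> pd.DataFrame:
    """Parametric-bootstrap adequacy check of a fitted model.

    Simulates ``n_sim`` datasets under the fitted model and compares the
    observed tip mean and variance against the simulated null distribution
    (z-scores).  A complement to AIC ranking, not a replacement.
    """
    C = phylo_vcv(tree).matrix
    if fit.model == "BM":
        V = fit.sigma2 * bm_covariance(C)
    elif fit.model == "OU":
        V = fit.sigma2 * ou_covariance(C, fit.alpha)
    else:
        V = fit.sigma2 * eb_covariance(C, fit.eb_rate)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(C)))
    sims = fit.z0 + L @ rng.standard_normal((len(C), n_sim))
    y = np.asarray(y, dtype=float)
    rows = []
    for name, func in (("mean", np.mean), ("variance", np.var)):
        obs = float(func(y))
        null = func(sims, axis=0)
        rows.append({
            "statistic": name, "observed": obs,
            "null_mean": float(null.mean()), "null_sd": float(null.std(ddof=1)),
            "z": (obs - null.mean()) / null.std(ddof=1),
        })
    return pd.DataFrame(rows)
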