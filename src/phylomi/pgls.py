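"""Phylogenetic generalized least squares under Brownian motion.

Regression with error covariance proportional to the phylogenetic matrix C:
y = X b + e,  e ~ N(0, sigma2 * C).  Fitting whitens both sides with the
Cholesky factor of C, after which GLS is exactly OLS on the transformed
data.  Also provides posterior coefficient draws for predictive mean
matching, the nested-model F-test used by the phylogenetic ANCOVA, and
variance inflation factors in the whitened design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .trees import PhyloCovariance

__all__ = [
    "PGLSFit",
    "AncovaResult",
    "fit_pgls",
    "draw_beta_posterior",
    "pgls_ancova_ftest",
    "vif",
]


@dataclass
class PGLSFit:
    beta_hat: np.ndarray
    beta_cov: np.ndarray          # sigma2_hat * (X' C^-1 X)^-1
    sigma2_hat: float
    df_resid: int
    loglik: float
    design_labels: list[str]
    xtcx_inv: np.ndarray = field(repr=False)  # unscaled (X' C^-1 X)^-1
    rss: float = field(repr=False, default=0.0)  # residual SS in the C^-1 metric
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.design_labels, map(float, self.beta_hat))),
            "se": dict(zip(self.design_labels,
                           map(float, np.sqrt(np.diag(self.beta_cov))))),
            "sigma2_hat": float(self.sigma2_hat),
            "df_resid": int(self.df_resid),
            "loglik": float(self.loglik),
            "n": int(self.n),
        }


@dataclass
class AncovaResult:
    F: float
    p: float
    df_num: int
    df_den: int
    df_full: int
    df_reduced: int
    vif: dict[str, float] | None = None


def _as_matrix(C) -> np.ndarray:
    return C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)


def _whiten(C: np.ndarray):
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "C is singular or not positive definite; consider inflating "
            "zero-length branches (resolve_zero_branches)") from exc
    return L


def fit_pgls(y, X, C, labels: list[str] | None = None) -> PGLSFit:
    """GLS fit of y on X under covariance proportional to C.

    beta_hat = (X'C^-1X)^-1 X'C^-1 y; sigma2_hat uses the unbiased n - p
    divisor; loglik is the multivariate-normal density of y at
    (X beta_hat, sigma2_hat * C).
    """
    if isinstance(X, pd.DataFrame):
        labels = labels or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Cm = _as_matrix(C)
    n, p = X.shape
    labels = labels or [f"x{j}" for j in range(p)]
    if n != y.size or Cm.shape != (n, n):
        raise ValueError("y, X and C dimensions do not align")
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")

    L = _whiten(Cm)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)

    sv = np.linalg.svd(Xw, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        # name the columns implicated via pivoted QR
        from scipy.linalg import qr as _qr
        _, R, piv = _qr(Xw, mode="economic", pivoting=True)
        rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * np.abs(R[0, 0])))
        bad = [labels[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    G = Xw.T @ Xw
    xtcx_inv = np.linalg.inv(G)
    beta = xtcx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    if rss <= 1e-12 * max(float(yw @ yw), 1.0):
        sigma2 = 0.0
        loglik = np.inf
    else:
        loglik = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2)
                         + logdet + rss / sigma2)
    return PGLSFit(beta, sigma2 * xtcx_inv, sigma2, df, loglik, list(labels),
                   xtcx_inv, rss, n)


def draw_beta_posterior(fit: PGLSFit, rng: np.random.Generator) -> np.ndarray:
    """One draw from the approximate joint posterior of (sigma2, beta).

    sigma2* = sigma2_hat * df / chi2(df), then
    beta* ~ N(beta_hat, sigma2* (X'C^-1X)^-1) — the standard proper
    Bayesian draw used by predictive mean matching.
    """
    if fit.df_resid <= 0:
        raise ValueError("df_resid must be positive")
    if fit.sigma2_hat == 0:
        return fit.beta_hat.copy()
    sigma2_star = fit.sigma2_hat * fit.df_resid / rng.chisquare(fit.df_resid)
    cov = sigma2_star * fit.xtcx_inv
    L = np.linalg.cholesky(cov + 1e-14 * np.trace(cov) / len(cov) * np.eye(len(cov)))
    return fit.beta_hat + L @ rng.standard_normal(len(fit.beta_hat))


def pgls_ancova_ftest(fit_full: PGLSFit, fit_reduced: PGLSFit) -> AncovaResult:
    """Nested-model F-test with residual sums of squares in the C^-1 metric.

    F = [(RSS_r - RSS_f)/(p_f - p_r)] / [RSS_f / df_f], upper-tail p-value.
    """
    if not set(fit_reduced.design_labels) <= set(fit_full.design_labels):
        raise ValueError("models are not nested: reduced design must be a "
                         "column subset of the full design")
    if fit_full.n != fit_reduced.n:
        raise ValueError("models fit to different numbers of observations")
    p_full = fit_full.n - fit_full.df_resid
    p_red = fit_reduced.n - fit_reduced.df_resid
    if p_full <= p_red:
        raise ValueError("full model must have more parameters than reduced")
    df_num = p_full - p_red
    df_den = fit_full.df_resid
    F = ((fit_reduced.rss - fit_full.rss) / df_num) / (fit_full.rss / df_den)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df_num, df_den))
    return AncovaResult(float(F), p, df_num, df_den, p_full, p_red)


def vif(X, C, labels: list[str] | None = None,
        intercept_label: str = "(Intercept)") -> dict[str, float]:
    """Variance inflation factors in the C^-1-whitened design.

    VIF_j = 1/(1 - R2_j) from regressing whitened column j on all other
    whitened columns.  The intercept is used as a regressor but not
    reported.  Perfectly collinear columns report ``inf`` with a warning.
    """
    if isinstance(X, pd.DataFrame):
        labels = labels or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        labels = labels or [f"x{j}" for j in range(X.shape[1])]
    L = _whiten(_as_matrix(C))
    Xw = solve_triangular(L, X, lower=True)
    has_intercept = intercept_label in labels
    out: dict[str, float] = {}
    for j, name in enumerate(labels):
        if name == intercept_label:
            continue
        yj = Xw[:, j]
        others = np.delete(Xw, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        pred = others @ coef
        ss_res = float(np.sum((yj - pred) ** 2))
        if has_intercept:
            ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        else:
            ss_tot = float(np.sum(yj ** 2))
        if ss_tot == 0 or ss_res <= 1e-12 * ss_tot:
            warnings.warn(f"column {name!r} is perfectly collinear; VIF = inf",
                          stacklevel=2)
            out[name] = np.inf
        else:
            out[name] = max(1.0, ss_tot / ss_res)
    return out
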