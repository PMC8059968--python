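"""Phylogenetic multiple imputation by chained equations with PMM.

Each incomplete column is imputed conditionally on the others: a
Brownian-motion PGLS of the target on the currently-complete predictors is
fit over the observed rows, a coefficient vector is drawn from its
approximate joint posterior, and every missing cell is filled by predictive
mean matching (PMM) — the observed value of one of the k donors whose
predicted score is closest to the missing case's predicted score.  Donor
matching compares observed-row scores under the point estimate with
missing-row scores under the posterior draw (the classical type-1 scheme),
so imputed values are always members of the observed value set.

Categorical targets are integer-coded, matched on the codes, and receive a
donor's category, which guarantees valid levels.  The whole procedure is
repeated to produce m completed datasets whose spread carries the
imputation uncertainty forward into pooled inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.linalg import cho_factor, cho_solve, qr as _qr

from .design import build_design
from .pgls import draw_beta_posterior, fit_pgls
from .tables import CATEGORICAL, TraitTable
from .trees import Phylogeny, PhyloCovariance, phylo_vcv

__all__ = [
    "ImputationConfig",
    "ImputationResult",
    "choose_m",
    "select_predictors",
    "pmm_impute_variable",
    "chained_equations",
    "convergence_summary",
]


@dataclass
class ImputationConfig:
    """Settings for one multiple-imputation run.

    ``m=None`` derives the number of datasets from the percentage of
    missing cells (:func:`choose_m`).  ``n_iter`` is the number of
    chained-equation sweeps per dataset (full-scale runs use hundreds, e.g. 500;
    the default here is a desk-scale setting adequate for the synthetic
    generator's missingness patterns).
    """

    m: int | None = None
    n_iter: int = 10
    k_donors: int = 5
    predictor_max_missing: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m is not None and self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_iter < 1 or self.k_donors < 1:
            raise ValueError("n_iter and k_donors must be >= 1")
        if not 0 < self.predictor_max_missing <= 1:
            raise ValueError("predictor_max_missing must be in (0, 1]")


@dataclass
class ImputationResult:
    datasets: list[TraitTable]
    chain_stats: pd.DataFrame  # dataset, iteration, column, mean, sd

    @property
    def m(self) -> int:
        return len(self.datasets)

    def write_datasets(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, tab in enumerate(self.datasets, start=1):
            tab.to_csv(d / f"imputed_{i}.csv")
        self.chain_stats.to_csv(d / "chain_stats.csv", index=False)


def choose_m(missing_fraction: float) -> int:
    """Number of imputed datasets = percentage of missing cells.

    Follows the rule of thumb that m should match the percentage of missing
    information (so 25% missing -> 25 datasets), floored at 2 whenever any
    value is missing; 0 when nothing is missing.
    """
    if not 0 <= missing_fraction <= 1:
        raise ValueError("missing_fraction must be in [0, 1]")
    if missing_fraction == 0:
        return 0
    return max(2, int(round(100 * missing_fraction)))


def select_predictors(table: TraitTable, max_missing: float) -> list[str]:
    """Columns usable as imputation predictors: missing fraction < threshold."""
    cols = [c for c in table.df.columns
            if table.missing_fraction(c) < max_missing]
    if not cols:
        raise ValueError("no columns qualify as imputation predictors")
    return cols


def _prune_design(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns until full rank (pivoted QR), keeping the intercept."""
    A = X.to_numpy(dtype=float)
    if A.shape[1] == 0:
        return X
    _, R, piv = _qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > max(A.shape) * np.finfo(float).eps * (diag[0] or 1.0)))
    keep = sorted(piv[:rank])
    return X.iloc[:, keep]


def pmm_impute_variable(target: pd.Series, predictors: pd.DataFrame,
                        C, k: int, rng: np.random.Generator) -> pd.Series:
    """Fill the missing entries of one numeric column by phylogenetic PMM.

    ``predictors`` is a complete numeric design (no intercept; one is
    added).  ``C`` is the phylogenetic covariance aligned to
    ``target.index``.  Returns the completed column; observed entries are
    untouched and every imputed value is an observed value of the column.

    Predicted scores condition on tree position: a missing row's score is
    X b* plus the Brownian conditional mean of its residual given the
    observed rows' residuals (C_mo C_oo^-1 r); an observed row's score is
    X b_hat plus its leave-one-out conditional residual, computed from the
    precision matrix as r_i - (C_oo^-1 r)_i / (C_oo^-1)_ii.  With C = I
    both corrections vanish and the procedure reduces exactly to classical
    type-1 predictive mean matching.
    """
    Cm = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    obs = target.notna().to_numpy()
    if obs.all():
        return target.copy()
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("cannot impute a column with zero observed values")
    if n_obs < k:
        warnings.warn(f"only {n_obs} observed values; donor pool truncated "
                      f"from k={k}", stacklevel=2)
        k = n_obs

    X = pd.concat(
        [pd.DataFrame({"(Intercept)": np.ones(len(target))}, index=target.index),
         predictors], axis=1)
    y = target.to_numpy(dtype=float)
    # rank-prune on the observed rows (where the PGLS is actually fit)
    X = X[_prune_design(X.loc[obs]).columns]
    # with few observed rows, keep only the predictors most correlated with
    # the target so the PGLS stays identifiable (n_obs > p + 2)
    max_p = n_obs - 3
    if X.shape[1] > max_p:
        strength = {}
        for c in X.columns[1:]:
            v = X[c].to_numpy(dtype=float)[obs]
            strength[c] = (abs(np.corrcoef(v, y[obs])[0, 1])
                           if np.ptp(v) > 0 else 0.0)
        keep = sorted(sorted(strength, key=lambda c: -strength[c])[:max(max_p - 1, 1)])
        X = X[[X.columns[0], *keep]]
        X = X[_prune_design(X.loc[obs]).columns]
    Xm = X.to_numpy(dtype=float)

    C_oo = Cm[np.ix_(obs, obs)]
    fit = fit_pgls(y[obs], Xm[obs], C_oo, labels=list(X.columns))
    beta_star = draw_beta_posterior(fit, rng)

    resid = y[obs] - Xm[obs] @ fit.beta_hat
    cf = cho_factor(C_oo, lower=True)
    prec_r = cho_solve(cf, resid)                    # C_oo^-1 r
    prec_diag = 1.0 / np.diag(cho_solve(cf, np.eye(n_obs)))
    loo_resid = resid - prec_r * prec_diag           # leave-one-out fit
    scores_obs = Xm[obs] @ fit.beta_hat + loo_resid
    blup = Cm[np.ix_(~obs, obs)] @ prec_r            # conditional residual mean
    scores_mis = Xm[~obs] @ beta_star + blup

    obs_labels = np.asarray(target.index)[obs]
    obs_values = y[obs]
    out = target.copy()
    mis_idx = np.flatnonzero(~obs)
    for row, score in zip(mis_idx, scores_mis):
        diffs = np.abs(scores_obs - score)
        order = np.lexsort((obs_labels, diffs))  # ties broken by taxon label
        donor = order[rng.integers(k)]
        out.iloc[row] = obs_values[donor]
    return out


def _numeric_frame(table: TraitTable, df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Encode ``columns`` of ``df`` numerically (dummies for categoricals)."""
    return build_design(table, columns, df=df, intercept=False)


def _codes(table: TraitTable, col: str, values: pd.Series) -> pd.Series:
    levels = table.levels(col)
    mapping = {lv: float(i) for i, lv in enumerate(levels)}
    return values.map(lambda v: mapping.get(v, np.nan))


def chained_equations(table: TraitTable, tree: Phylogeny,
                      config: ImputationConfig) -> ImputationResult:
    """Produce m completed datasets by chained phylogenetic PMM.

    Missing cells are initialized by resampling observed values of the same
    column, then columns are revisited in order of ascending missingness
    for ``config.n_iter`` sweeps.  Per-sweep means/SDs of the imputed cells
    are recorded for convergence diagnostics.
    """
    table.assert_species_match(tree.tips)
    Cfull = phylo_vcv(tree)
    C = Cfull.submatrix(table.species) if table.species != Cfull.taxa else Cfull

    for c in table.df.columns:
        if table.df[c].notna().sum() == 0:
            raise ValueError(f"column {c!r} has zero observed values")

    frac = table.missing_fraction()
    m = config.m if config.m is not None else choose_m(frac)
    missing_cols = [c for c in table.df.columns if table.df[c].isna().any()]
    missing_cols.sort(key=lambda c: (table.missing_fraction(c), c))

    if not missing_cols or m == 0:
        datasets = [table.copy() for _ in range(m)]
        empty = pd.DataFrame(columns=["dataset", "iteration", "column", "mean", "sd"])
        return ImputationResult(datasets, empty)

    predictors_all = select_predictors(table, config.predictor_max_missing)
    obs_mask = table.df.notna()
    levels_cache = {c: table.levels(c) for c in table.categorical_columns()}

    datasets: list[TraitTable] = []
    records: list[dict] = []
    for d in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, d]))
        cur = table.df.copy()
        # marginal initialization, seeded
        for col in missing_cols:
            observed = table.df.loc[obs_mask[col], col].to_numpy()
            fill = rng.choice(observed, size=(~obs_mask[col]).sum(), replace=True)
            cur.loc[~obs_mask[col], col] = fill
        for it in range(1, config.n_iter + 1):
            for col in missing_cols:
                preds = [c for c in predictors_all if c != col]
                Xpred = _numeric_frame(table, cur, preds)
                is_cat = table.column_types[col] == CATEGORICAL
                target = table.df[col].copy()  # observed values + NaN holes
                if is_cat:
                    target = _codes(table, col, target)
                completed = pmm_impute_variable(target, Xpred, C,
                                                config.k_donors, rng)
                imputed_vals = completed[~obs_mask[col]].to_numpy(dtype=float)
                if is_cat:
                    lv = levels_cache[col]
                    cur[col] = [lv[int(v)] for v in completed.to_numpy()]
                else:
                    cur[col] = completed
                records.append({
                    "dataset": d, "iteration": it, "column": col,
                    "mean": float(np.mean(imputed_vals)),
                    "sd": float(np.std(imputed_vals)),
                })
        # observed cells must be untouched
        assert cur.where(obs_mask).equals(table.df.where(obs_mask))
        datasets.append(TraitTable(cur, dict(table.column_types),
                                   set(table.complete_columns)))
    return ImputationResult(datasets, pd.DataFrame.from_records(records))


def convergence_summary(result: ImputationResult,
                        slope_alpha: float = 0.05) -> pd.DataFrame:
    """Per-column trend diagnostics over the final half of the sweeps.

    Reports the slope of imputed-cell means against iteration (pooled over
    datasets), its p-value, the between-/within-dataset variance ratio of
    those means, and a ``converged`` flag set when the slope is
    statistically indistinguishable from zero.
    """
    cs = result.chain_stats
    rows = []
    for col in sorted(cs["column"].unique()) if len(cs) else []:
        sub = cs[cs["column"] == col]
        half = sub["iteration"].max() / 2
        tail = sub[sub["iteration"] > half]
        x = tail["iteration"].to_numpy(float)
        y = tail["mean"].to_numpy(float)
        if len(tail) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            slope, pval = 0.0, 1.0
        else:
            res = sp_stats.linregress(x, y)
            slope, pval = float(res.slope), float(res.pvalue)
        per_ds_mean = tail.groupby("dataset")["mean"]
        between = float(per_ds_mean.mean().var(ddof=1)) if result.m > 1 else 0.0
        within = float(per_ds_mean.var(ddof=1).mean())
        ratio = between / within if within > 0 else np.nan
        rows.append({"column": col, "slope": slope, "slope_p": pval,
                     "bw_ratio": ratio, "converged": pval >= slope_alpha})
    return pd.DataFrame(rows)
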