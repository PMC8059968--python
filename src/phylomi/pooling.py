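"""Rubin's rules: pooling estimates across imputations (and chains).

For m per-imputation estimates Q_i with within variances U_i:
Qbar = mean(Q_i), Ubar = mean(U_i), B = sample variance of Q_i,
T = Ubar + (1 + 1/m) B, se = sqrt(T).  Posterior tail fractions are pooled
by concatenating all runs' samples (equal weight per run) because Rubin's
rules are defined for point estimates, not tail probabilities; DIC and
heritability are pooled as plain means across runs.  Interval degrees of
freedom use the Barnard-Rubin small-sample formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import GLMMResult, significance

__all__ = ["PooledEstimate", "rubin_pool", "pool_posterior", "pooled_table"]


@dataclass
class PooledEstimate:
    q_bar: float
    u_bar: float
    b: float
    t: float
    se: float
    m: int
    df: float | None = None
    frac_above_zero: float | None = None
    mean_posterior_sd: float | None = None


def rubin_pool(estimates, variances, n_complete: int | None = None) -> PooledEstimate:
    """Combine m point estimates and their within-run variances."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size != u.size:
        raise ValueError("estimates and variances must have equal length")
    m = q.size
    if m < 2:
        raise ValueError("need m >= 2 runs to estimate between-run variance")
    if np.any(u < 0):
        raise ValueError("variances must be >= 0")
    q_bar = float(q.mean())
    u_bar = float(u.mean())
    b = float(q.var(ddof=1))
    t = u_bar + (1.0 + 1.0 / m) * b
    df = None
    if t > 0:
        # Barnard-Rubin adjusted degrees of freedom
        lam = (1.0 + 1.0 / m) * b / t
        if lam > 0:
            df_old = (m - 1) / lam**2
            if n_complete is not None:
                k = 1  # one parameter at a time
                df_obs = ((n_complete - k + 1) / (n_complete - k + 3)
                          * (n_complete - k) * (1 - lam))
                df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
            else:
                df = df_old
    return PooledEstimate(q_bar, u_bar, b, t, float(np.sqrt(t)), m, df)


def pool_posterior(results: list[GLMMResult]) -> dict[str, PooledEstimate]:
    """Pool per-run posterior means/variances of each coefficient.

    Every entry of ``results`` is one model run (one imputed dataset x one
    chain).  All runs must share the model's coefficient set.
    """
    if len(results) < 2:
        raise ValueError("need at least two runs to pool")
    names = results[0].draws.names
    for r in results[1:]:
        if r.draws.names != names:
            raise ValueError("runs have mismatched coefficient sets")
    pooled: dict[str, PooledEstimate] = {}
    for j, name in enumerate(names):
        ests = [float(r.draws.fixed_effects[:, j].mean()) for r in results]
        vars_ = [float(r.draws.fixed_effects[:, j].var(ddof=1)) for r in results]
        pe = rubin_pool(ests, vars_)
        allsamp = np.concatenate([r.draws.fixed_effects[:, j] for r in results])
        pe.frac_above_zero = float(np.mean(allsamp > 0))
        pe.mean_posterior_sd = float(np.mean(np.sqrt(vars_)))
        pooled[name] = pe
    return pooled


def pooled_table(model_results: dict[str, list[GLMMResult]]) -> pd.DataFrame:
    """Report shaped like the study's model table.

    One row per (model, coefficient): pooled beta (Qbar), s.e. (sqrt(T),
    primary; mean posterior SD also emitted), % posterior mass above zero,
    significance label, and per-model mean DIC and mean heritability.
    """
    rows = []
    for model_name, runs in model_results.items():
        pooled = pool_posterior(runs)
        mean_dic = float(np.mean([r.dic for r in runs]))
        mean_h2 = float(np.mean([r.heritability_samples.mean() for r in runs]))
        for name, pe in pooled.items():
            rows.append({
                "model": model_name,
                "term": name,
                "beta": pe.q_bar,
                "se": pe.se,
                "se_mean_posterior_sd": pe.mean_posterior_sd,
                "pct_above_zero": 100.0 * pe.frac_above_zero,
                "significance": significance(pe.frac_above_zero),
                "mean_dic": mean_dic,
                "mean_heritability": mean_h2,
                "m_runs": pe.m,
            })
    return pd.DataFrame(rows)
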