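"""End-to-end analysis: diagnose -> impute -> fit -> pool -> evo -> ANCOVA.

The pipeline is a pure function of (inputs, config, master seed): per-stage
seeds are derived by hashing the master seed with the stage name, so any
stage can be re-run from cached upstream artifacts and reproduce downstream
results exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import build_design
from .diagnostics import missing_pattern, phylo_d
from .evomodels import per_landmass_analysis
from .glmm import ModelSpec, fit_phylo_glmm, load_model_registry
from .impute import ImputationConfig, chained_equations, convergence_summary
from .pgls import PGLSFit, fit_pgls, pgls_ancova_ftest, vif
from .pooling import pooled_table
from .simulate import impose_missingness, marsupial_emulation_config, simulate_dataset, simulate_tree
from .tables import TraitTable
from .trees import Phylogeny, phylo_vcv, read_newick

log = logging.getLogger("phylomi")

__all__ = ["AnalysisReport", "run_full_analysis", "complete_case_validation",
           "stage_seed", "default_config"]


def stage_seed(master: int, stage: str, rep: int = 0) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.blake2b(f"{master}:{stage}:{rep}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


def default_config() -> dict:
    """Desk-scale defaults; reference-scale settings are applied by the CLI's
    ``--reference-scale`` flag (m from the 25%-rule, 500 sweeps, 1,000,042
    MCMC iterations with 150,000 burn-in and thinning 250)."""
    return {
        "seed": 0,
        "output_dir": None,
        "data": {"preset": "marsupial-emulation", "n_tips": 176,
                 "litter_effect": -0.2, "null_effects": False,
                 "tree": None, "table": None},
        "imputation": {"m": 5, "n_iter": 5, "k_donors": 5,
                       "predictor_max_missing": 0.35},
        "sampler": {"n_iter": 20_000, "burnin": 4_000, "thin": 10,
                    "chains": 2, "prior_shape": 0.001, "prior_scale": 0.001},
        "evo": {"subset_column": "origin", "traits": ["log_ecv", "log_body"],
                "min_tips": 10},
        "diagnostics": {"n_perm": 200},
        "ancova": {"response": "log_ecv", "covariate": "log_body",
                   "group": "origin"},
        "models": "default",
    }


def apply_reference_scale(config: dict) -> dict:
    config = json.loads(json.dumps(config))
    config["imputation"].update({"m": None, "n_iter": 500})
    config["sampler"].update({"n_iter": 1_000_042, "burnin": 150_000,
                              "thin": 250, "chains": 2})
    return config


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(default_config(), user)


@dataclass
class AnalysisReport:
    model_table: pd.DataFrame
    evo_table: pd.DataFrame
    ancova: dict
    diagnostics: dict
    imputation_convergence: pd.DataFrame
    complete_case: dict
    provenance: dict
    config: dict = field(repr=False, default_factory=dict)

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.model_table.to_csv(d / "model_table.csv", index=False)
        self.evo_table.to_csv(d / "evo_models.csv", index=False)
        self.imputation_convergence.to_csv(d / "imputation_convergence.csv",
                                           index=False)
        self.diagnostics["per_column"].to_csv(d / "missingness.csv")
        payload = {
            "ancova": self.ancova,
            "phylo_d": self.diagnostics.get("phylo_d", {}),
            "complete_case": self.complete_case,
            "provenance": self.provenance,
        }
        with open(d / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _load_data(config: dict) -> tuple[Phylogeny, TraitTable]:
    data = config["data"]
    if data.get("tree") and data.get("table"):
        tree = read_newick(data["tree"])
        table = TraitTable.from_csv(data["table"])
        shared = sorted(set(tree.tips) & set(table.species))
        if not shared:
            raise ValueError("tree and table share no taxa")
        if set(tree.tips) != set(table.species):
            tree = tree.prune_to(shared)
            table = TraitTable(table.df.loc[shared], table.column_types,
                               table.complete_columns)
        return tree, table
    if data.get("preset") in ("marsupial-emulation", "marsupial_emulation"):
        seed = stage_seed(config["seed"], "simulate")
        sim = marsupial_emulation_config(
            seed=seed, n_tips=data.get("n_tips", 176),
            litter_effect=data.get("litter_effect", -0.2),
            null_effects=data.get("null_effects", False))
        tree = simulate_tree(sim.n_tips, seed)
        table = simulate_dataset(tree, sim)
        table = impose_missingness(table, sim, tree=tree)
        return tree, table
    raise ValueError("config must give either a preset or tree+table paths")


def _model_specs(config: dict) -> list[ModelSpec]:
    if config.get("models") in ("default", None):
        return load_model_registry()
    return [ModelSpec(m["name"], list(m["fixed"]),
                      m.get("response", "log_ecv"),
                      dict(m.get("reference_levels", {})))
            for m in config["models"]]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage=%s failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage=%s elapsed=%.1fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def complete_case_validation(table: TraitTable, tree: Phylogeny,
                             spec: ModelSpec) -> tuple[PGLSFit, int]:
    """Listwise-deletion PGLS companion to the pooled mixed-model fit."""
    cols = {spec.response}
    for t in spec.fixed:
        cols.update(p.strip() for p in t.split(":"))
    keep = table.df[sorted(cols)].notna().all(axis=1)
    sub = table.df.loc[keep]
    X = build_design(table, spec.fixed, spec.reference_levels, df=sub)
    n_keep = len(sub)
    if n_keep < X.shape[1] + 3:
        raise ValueError(f"too few complete cases: {n_keep}")
    C = phylo_vcv(tree).submatrix(list(sub.index))
    y = pd.to_numeric(sub[spec.response]).to_numpy(float)
    return fit_pgls(y, X, C), n_keep


def run_full_analysis(config) -> AnalysisReport:
    """Execute every stage of the comparative pipeline.

    ``config`` is a dict (see :func:`default_config`) or a path to a YAML
    file with the same structure.  Any stage failure aborts with the stage
    name; outputs written so far are retained.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config["seed"])

    tree, table = _stage("load")(_load_data)(config)
    C = phylo_vcv(tree).submatrix(table.species)

    @_stage("diagnose")
    def diagnose():
        diag = missing_pattern(table)
        dstats = {}
        n_perm = config["diagnostics"].get("n_perm", 200)
        for col in table.df.columns:
            ind = table.df[col].isna()
            if 0 < ind.sum() < len(ind):
                dstats[col] = phylo_d(
                    ind.astype(int), tree, n_perm=max(100, n_perm),
                    seed=stage_seed(seed, f"diagnose:{col}")).to_dict()
        diag["phylo_d"] = dstats
        diag.pop("co_missing", None)
        diag["co_missing_corr"] = diag["co_missing_corr"].to_dict()
        return diag

    diagnostics = diagnose()

    @_stage("impute")
    def impute():
        icfg = ImputationConfig(seed=stage_seed(seed, "impute"),
                                **config["imputation"])
        return chained_equations(table, tree, icfg)

    imputation = impute()
    imp_convergence = convergence_summary(imputation)

    specs = _model_specs(config)

    @_stage("fit")
    def fit_all():
        sk = config["sampler"]
        results = {}
        for spec in specs:
            runs = []
            for d, dataset in enumerate(imputation.datasets):
                res = fit_phylo_glmm(
                    dataset, C, spec,
                    n_iter=sk["n_iter"], burnin=sk["burnin"], thin=sk["thin"],
                    chains=sk["chains"],
                    seed=stage_seed(seed, f"glmm:{spec.name}", d),
                    prior_shape=sk["prior_shape"], prior_scale=sk["prior_scale"])
                # each chain counts as one run for pooling (m datasets x chains)
                for c in range(sk["chains"]):
                    sub = res.draws.subset_chain(c)
                    runs.append(type(res)(res.spec, sub,
                                          sub.var_phylo / (sub.var_phylo + sub.var_resid),
                                          res.dic, {}))
            results[spec.name] = runs
        return results

    model_results = fit_all()
    model_table = _stage("pool")(pooled_table)(model_results)

    @_stage("evomodels")
    def evo():
        e = config["evo"]
        return per_landmass_analysis(table, tree,
                                     subset_column=e["subset_column"],
                                     traits=tuple(e["traits"]),
                                     min_tips=e["min_tips"])

    evo_table = evo()

    @_stage("ancova")
    def ancova():
        a = config["ancova"]
        y = pd.to_numeric(table.df[a["response"]]).to_numpy(float)
        X_full = build_design(table, [a["covariate"], a["group"],
                                      f"{a['covariate']}:{a['group']}"])
        X_red = build_design(table, [a["covariate"]])
        fit_full = fit_pgls(y, X_full, C)
        fit_red = fit_pgls(y, X_red, C)
        res = pgls_ancova_ftest(fit_full, fit_red)
        # multicollinearity is assessed among the additive predictors;
        # interaction columns are collinear with their main effects by
        # construction and would not be informative here
        X_add = build_design(table, [a["covariate"], a["group"]])
        res.vif = vif(X_add, C)
        return {"F": res.F, "p": res.p, "df_num": res.df_num,
                "df_den": res.df_den, "df_full": res.df_full,
                "df_reduced": res.df_reduced, "vif": res.vif,
                "max_vif": max(res.vif.values()) if res.vif else None}

    ancova_res = ancova()

    @_stage("complete_case")
    def complete_case():
        out = {}
        for spec in specs:
            try:
                fit, n_keep = complete_case_validation(table, tree, spec)
                out[spec.name] = {"n": n_keep, **fit.to_dict()}
            except ValueError as exc:
                out[spec.name] = {"error": str(exc)}
        return out

    cc = complete_case()

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    provenance = {
        "config_sha256": cfg_hash,
        "seed": seed,
        "versions": {
            "phylomi": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    report = AnalysisReport(model_table, evo_table, ancova_res, diagnostics,
                            imp_convergence, cc, provenance, config)
    if config.get("output_dir"):
        report.write(config["output_dir"])
    return report
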