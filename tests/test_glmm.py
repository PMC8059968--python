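import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylomi.glmm import (
    GLMMResult,
    ModelSpec,
    PosteriorDraws,
    convergence,
    dic,
    fit_phylo_glmm,
    heritability,
    load_model_registry,
    significance,
)
from phylomi.simulate import simulate_bm, simulate_tree
from phylomi.tables import TraitTable
from phylomi.trees import phylo_vcv

SAMPLER = dict(n_iter=4000, burnin=1000, thin=5, chains=2)


def _animal_table(n, seed, va, ve, beta=(1.0, 0.5)):
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n, seed)
    C = phylo_vcv(tree)
    x = rng.standard_normal(n)
    u = simulate_bm(tree, va, 0.0, C=C.matrix, rng=rng).to_numpy()
    y = beta[0] + beta[1] * x + u + rng.normal(0, np.sqrt(ve), n)
    df = pd.DataFrame({"log_ecv": y, "x": x}, index=tree.tips)
    tab = TraitTable(df, {"log_ecv": "continuous", "x": "continuous"})
    return tab, C


class TestModelRegistry:
    def test_eight_models_all_with_body_covariate(self):
        specs = load_model_registry()
        assert len(specs) == 8
        assert [s.name for s in specs] == [
            "developmental", "environmental", "social", "metabolic",
            "torpor", "play", "vulnerability", "origin"]
        for s in specs:
            assert "log_body" in s.fixed
            assert s.response == "log_ecv"


class TestFitPhyloGLMM:
    def test_no_phylo_signal_reduces_to_ols(self):
        tab, C = _animal_table(150, 3, va=0.0, ve=1.0)
        spec = ModelSpec("t", fixed=["x"])
        res = fit_phylo_glmm(tab, C, spec, seed=0, **SAMPLER)
        X = np.column_stack([np.ones(150), tab.df.x])
        ols = np.linalg.lstsq(X, tab.df.log_ecv.to_numpy(), rcond=None)[0]
        post_mean = res.draws.fixed_effects.mean(axis=0)
        se = res.draws.fixed_effects.std(axis=0)
        assert np.all(np.abs(post_mean - ols) < 3 * se)

    def test_h2_recovery_single_instance(self):
        tab, C = _animal_table(200, 5, va=0.8, ve=0.2)
        spec = ModelSpec("t", fixed=["x"])
        res = fit_phylo_glmm(tab, C, spec, seed=1, **SAMPLER)
        assert 0.65 <= res.heritability_samples.mean() <= 0.95

    def test_seed_bit_identical(self):
        tab, C = _animal_table(40, 7, va=0.5, ve=0.5)
        spec = ModelSpec("t", fixed=["x"])
        a = fit_phylo_glmm(tab, C, spec, seed=9, n_iter=500, burnin=100,
                           thin=2, chains=2)
        b = fit_phylo_glmm(tab, C, spec, seed=9, n_iter=500, burnin=100,
                           thin=2, chains=2)
        assert np.array_equal(a.draws.fixed_effects, b.draws.fixed_effects)
        assert np.array_equal(a.draws.var_phylo, b.draws.var_phylo)

    def test_doubling_thin_halves_samples_same_means(self):
        tab, C = _animal_table(80, 11, va=0.5, ve=0.5)
        spec = ModelSpec("t", fixed=["x"])
        a = fit_phylo_glmm(tab, C, spec, seed=2, n_iter=6000, burnin=1000,
                           thin=5, chains=2)
        b = fit_phylo_glmm(tab, C, spec, seed=2, n_iter=6000, burnin=1000,
                           thin=10, chains=2)
        assert len(b.draws.var_phylo) == pytest.approx(
            len(a.draws.var_phylo) / 2, abs=2)
        sd = a.draws.fixed_effects.std(axis=0)
        assert np.all(np.abs(a.draws.fixed_effects.mean(axis=0)
                             - b.draws.fixed_effects.mean(axis=0)) < 0.5 * sd)

    def test_incomplete_table_rejected(self):
        tab, C = _animal_table(20, 1, va=0.5, ve=0.5)
        tab.df.iloc[0, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_phylo_glmm(tab, C, ModelSpec("t", fixed=["x"]), **SAMPLER)

    def test_single_chain_warns(self):
        tab, C = _animal_table(30, 2, va=0.5, ve=0.5)
        with pytest.warns(UserWarning, match="chain"):
            res = fit_phylo_glmm(tab, C, ModelSpec("t", fixed=["x"]),
                                 seed=0, n_iter=400, burnin=100, thin=2,
                                 chains=1)
        assert res.draws.gelman_rubin is None


def _toy_draws(rng, n_per_chain=500, chains=2, beta_shift=0.0):
    betas, vas, ves, cid = [], [], [], []
    for c in range(chains):
        betas.append(rng.normal(beta_shift * c, 1.0, (n_per_chain, 2)))
        vas.append(rng.gamma(2.0, 1.0, n_per_chain))
        ves.append(rng.gamma(2.0, 1.0, n_per_chain))
        cid.append(np.full(n_per_chain, c))
    return PosteriorDraws(["a", "b"], np.concatenate(betas),
                          np.concatenate(vas), np.concatenate(ves),
                          np.concatenate(cid))


class TestHeritability:
    def test_equal_variances_half(self, rng):
        d = _toy_draws(rng)
        d.var_resid = d.var_phylo.copy()
        assert np.allclose(heritability(d), 0.5)

    def test_vanishing_residual_tends_to_one(self, rng):
        d = _toy_draws(rng)
        d.var_resid = np.full_like(d.var_phylo, 1e-12)
        assert np.all(heritability(d) > 0.999)

    def test_bounded(self, rng):
        h = heritability(_toy_draws(rng))
        assert np.all((h >= 0) & (h <= 1))


class TestDIC:
    def _setup(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(n, seed)
        C = phylo_vcv(tree).matrix
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 0.3] + rng.standard_normal(n)
        return y, X, C

    def test_single_sample_chain_has_zero_pd(self):
        y, X, C = self._setup()
        d = PosteriorDraws(["i", "x"], np.array([[1.0, 0.3]]),
                           np.array([0.4]), np.array([0.6]), np.array([0]))
        expected = -2 * stats.multivariate_normal.logpdf(
            y, mean=X @ [1.0, 0.3], cov=0.4 * C + 0.6 * np.eye(len(y)))
        assert dic(d, y, X, C) == pytest.approx(expected, rel=1e-10)

    def test_matches_termwise_oracle_on_fixed_chain(self):
        y, X, C = self._setup(seed=4)
        rng = np.random.default_rng(1)
        betas = rng.normal(0, 1, (5, 2))
        vas = rng.gamma(2, 1, 5)
        ves = rng.gamma(2, 1, 5)
        d = PosteriorDraws(["i", "x"], betas, vas, ves, np.zeros(5))
        devs = [-2 * stats.multivariate_normal.logpdf(
                    y, mean=X @ b, cov=va * C + ve * np.eye(len(y)))
                for b, va, ve in zip(betas, vas, ves)]
        dbar = np.mean(devs)
        dhat = -2 * stats.multivariate_normal.logpdf(
            y, mean=X @ betas.mean(axis=0),
            cov=vas.mean() * C + ves.mean() * np.eye(len(y)))
        assert dic(d, y, X, C) == pytest.approx(dbar + (dbar - dhat),
                                                rel=1e-10)

    def test_noise_predictor_increases_mean_dic(self):
        deltas = []
        for rep in range(12):
            tab, C = _animal_table(60, 100 + rep, va=0.5, ve=0.5)
            tab.df["noise"] = np.random.default_rng(rep).standard_normal(60)
            tab.column_types["noise"] = "continuous"
            small = dict(n_iter=1500, burnin=300, thin=3, chains=2)
            r0 = fit_phylo_glmm(tab, C, ModelSpec("m0", fixed=["x"]),
                                seed=rep, **small)
            r1 = fit_phylo_glmm(tab, C, ModelSpec("m1", fixed=["x", "noise"]),
                                seed=rep, **small)
            deltas.append(r1.dic - r0.dic)
        assert np.mean(deltas) > 0


class TestConvergence:
    def test_white_noise_chains_pass(self, rng):
        d = _toy_draws(rng, n_per_chain=2000)
        diag = convergence(d, ess_min=3000)
        assert (diag["ess"] > 2500).all()
        assert (diag["rhat"] < 1.05).all()

    def test_shifted_chains_fail_rhat(self, rng):
        d = _toy_draws(rng, beta_shift=5.0)
        diag = convergence(d)
        assert diag.set_index("parameter").loc["b", "rhat"] > 1.1
        assert not diag.set_index("parameter").loc["b", "passed"]

    def test_single_chain_reports_ess_warns_on_rhat(self, rng):
        d = _toy_draws(rng, chains=1)
        with pytest.warns(UserWarning, match="R-hat"):
            diag = convergence(d)
        assert diag["rhat"].isna().all()
        assert (diag["ess"] > 0).all()


class TestSignificance:
    @pytest.mark.parametrize("frac,label", [
        (0.9694, "significant-positive"),
        (0.50, "not significant"),
        (0.0474, "significant-negative"),
        (0.95, "significant-positive"),
        (0.05, "significant-negative"),
    ])
    def test_labels(self, frac, label):
        assert significance(frac) == label

    def test_bounds(self):
        with pytest.raises(ValueError):
            significance(1.2)
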