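# phylomi

Phylogenetic multiple imputation and Bayesian phylogenetic mixed models for
comparative trait analysis.

Comparative studies of relative brain size — log endocranial volume (ECV)
regressed on log body mass plus behavioural, ecological and life-history
predictors across species — face two chronic problems: species share
ancestry (residuals are correlated, with covariance proportional to the
phylogenetic matrix **C** of shared branch lengths under Brownian motion),
and trait tables are full of holes (some behavioural traits are missing for
more than half the species). Deleting incomplete species wastes most of the
data; ignoring phylogeny invalidates the inference.

`phylomi` implements the full pipeline that deals with both at once:

1. **Tree preprocessing** — Newick input, zero-branch inflation
   (1e-4 × median positive branch length) with re-ultrametricization, and
   construction of C.
2. **Phylogenetic multiple imputation** — chained equations where every
   conditional model is a Brownian-motion PGLS and every missing cell is
   filled by predictive mean matching (k = 5 donors, posterior-drawn
   coefficients, scores conditioned on tree position), producing *m*
   completed datasets (*m* = percentage of missing cells, e.g. 25).
3. **Bayesian phylogenetic mixed model** ("animal model"),
   y = Xβ + u + e with u ~ N(0, σ²ₐC), e ~ N(0, σ²ₑI), sampled by a fast
   blocked Gibbs sampler in the eigenbasis of C; reports phylogenetic
   heritability h² = σ²ₐ/(σ²ₐ+σ²ₑ), DIC, ESS and split-R̂, and labels a
   coefficient significant when ≥ 95% of its posterior mass lies on one
   side of zero.
4. **Rubin's-rules pooling** across all runs (m datasets × 2 chains):
   Q̄, Ū, B, T = Ū + (1+1/m)B.
5. **Evolutionary-mode selection** — ML fits of Brownian motion,
   Ornstein–Uhlenbeck and early-burst models compared by AIC, per landmass.
6. **Phylogenetic ANCOVA** (nested-model F-test in the C⁻¹ metric, VIF)
   and **missingness diagnostics** (patterns, and the Fritz–Purvis D
   statistic of each column's missingness indicator: D ≈ 1 random,
   D ≈ 0 phylogenetically clumped).

A seeded synthetic-data generator (`phylomi.simulate`) emulates a
176-species marsupial brain/body/life-history dataset — 16 predictor
traits, threshold-model categoricals, a built-in negative litter-size
effect on relative brain size, and per-column MCAR/MAR/phylogenetically
clumped missingness — so the entire pipeline is testable end-to-end without
downloading anything. See `docs/methods.md` for models, assumptions and
design choices.

## Worked example

```python
from phylomi.pipeline import default_config, run_full_analysis

cfg = default_config()
cfg["seed"] = 1
cfg["data"].update({"n_tips": 80})           # synthetic preset, 80 species
cfg["imputation"].update({"m": 3, "n_iter": 3})
cfg["sampler"].update({"n_iter": 4000, "burnin": 1000, "thin": 5})
report = run_full_analysis(cfg)

t = report.model_table
print(t[t.model == "developmental"].round(3).to_string(index=False))
```

```
       term   beta    se  pct_above_zero         significance  mean_dic  mean_heritability
(Intercept) -2.705 0.287           0.000 significant-negative   -82.021              0.931
   log_body  0.776 0.028         100.000 significant-positive   -82.021              0.931
litter_size -0.195 0.059           0.083 significant-negative   -82.021              0.931
weaning_age -0.081 0.065           9.278      not significant   -82.021              0.931
```

The generator built in a litter-size coefficient of −0.2 on log ECV; the
pooled model recovers β = −0.195 with only 0.08% of the posterior mass
above zero — labelled significant-negative — while weaning age, which has
no built-in effect, is not significant. The body-mass allometry (true slope
0.75) is recovered at 0.776, and the pooled phylogenetic heritability of
0.93 reflects the generator's strongly heritable residual. The same report
carries the per-landmass BM/OU/EB table (`report.evo_table`), the
phylogenetic ANCOVA (`report.ancova`, here F = 5.06 on the slope-by-origin
interaction with max VIF = 1.73 among the additive predictors), the
missingness pattern (25.3% of cells missing overall) and the D statistic of
each column's missingness indicator (play: D = 0.02, i.e. strongly
clade-clumped, as simulated).

The same stages are available from the shell:

```sh
phylomi simulate --n-tips 176 --seed 1 --out runs/sim
phylomi diagnose --tree runs/sim/tree.nwk --table runs/sim/traits.csv
phylomi impute   --tree runs/sim/tree.nwk --table runs/sim/traits.csv \
                 --m 5 --n-iter 5 --out runs/imp
phylomi fit      --tree runs/sim/tree.nwk --imputed-dir runs/imp \
                 --out runs/model_table.csv
phylomi run-all  --seed 1 --out runs/full          # everything at once
```

`--reference-scale` switches imputation and sampler settings to the reference
analysis scale (m from the 25%-rule, 500 sweeps, 1,000,042 MCMC iterations,
burn-in 150,000, thinning 250); defaults are desk-scale.

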