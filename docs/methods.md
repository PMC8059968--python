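# Methods

This note documents the statistical models implemented in `phylomi`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## The problem

Comparative analyses of relative brain size regress log endocranial volume
(ECV) on log body mass plus candidate predictors across species. Two
obstacles dominate: species are not independent (shared ancestry induces
correlated residuals) and trait tables are riddled with missing values
(behavioural and life-history traits are unmeasured for many species).
`phylomi` implements a pipeline that addresses both: phylogenetically
informed multiple imputation by chained equations, Bayesian phylogenetic
mixed models fitted to every completed dataset, and pooling of all runs by
Rubin's rules — together with evolutionary-mode model selection, a
phylogenetic ANCOVA, and diagnostics for phylogenetic signal in the
missingness itself.

## Phylogenetic covariance

Under Brownian motion (BM) with rate σ², the trait covariance of species i
and j is σ²·C[i,j], where C[i,j] is the branch length shared by their
root-to-tip paths (the depth of their most recent common ancestor). All
matrix rows follow lexicographic tip order so results are reproducible and
alignable by construction. Zero-length branches (used by time trees to
encode polytomies) are inflated to 1e-4 × the median *positive* branch
length — zeros are excluded from the median so they cannot drag it down —
and the tree is then re-ultrametricized by extending terminal branches to
the maximum depth, the simplest deterministic method. The resolver is
idempotent and leaves trees without zero branches bit-identical.

## PGLS core

`fit_pgls` solves generalized least squares by Cholesky whitening of C,
which makes "GLS = OLS on transformed data" exact: with C = I the estimates
equal ordinary least squares to machine precision. The residual variance
uses the unbiased n − p divisor, matching the nested-model F-test; the
reported log-likelihood is the multivariate-normal density at
(Xβ̂, σ̂²C). Posterior coefficient draws for the imputer use the standard
normal-inverse-chi-square draw: σ²* = σ̂²·df/χ²(df), β* ~ N(β̂,
σ²*(XᵀC⁻¹X)⁻¹). Variance inflation factors are computed in the whitened
design (intercept used as a regressor, not reported); for the ANCOVA
report, VIF is evaluated on the additive design only, since interaction
columns are collinear with their main effects by construction.

## Phylogenetic predictive mean matching

Each incomplete column is imputed by chained equations: initialize missing
cells from the column's observed marginal, then revisit columns in order of
ascending missingness, each time fitting a BM-PGLS of the target on the
currently complete predictors (those with < 35% missing values in the
original table) over the observed rows, drawing β* from its approximate
posterior, and filling each missing cell with the observed value of one of
k = 5 donors whose predicted score is closest (ties broken by taxon label,
then a uniform choice). Imputed values are therefore always members of the
observed value set, and observed cells are never modified.

**Design choice — conditioning on tree position.** Predicted scores are not
taken at the root of the tree: a missing row's score is Xβ* plus the BM
conditional mean of its residual given the observed rows' residuals
(C_mo·C_oo⁻¹·r), and an observed row's score is Xβ̂ plus its leave-one-out
conditional residual (r_i − (C_oo⁻¹r)_i/(C_oo⁻¹)_ii). Both corrections
vanish when C = I, so the identity ablation *is* classical mice type-1 PMM.
We adopted this after measuring the root-level alternative: without the
conditional correction, score rankings are essentially independent of C and
the phylogenetic pipeline performs identically to the ordinary one (it won
the MSE comparison in only ~1/3 of replicates); with it, the phylogenetic
imputer wins in ≳90% of MCAR replicates on strongly heritable traits. The
correction is exactly the conditional mean of a multivariate normal given
the observed margin, so no new assumption is introduced beyond BM itself.

Categorical targets are integer-coded in sorted level order, matched on the
codes, and receive a donor's category — donors guarantee valid levels; no
polytomous regression model is involved. When a column has very few
observed rows relative to the design (e.g. a 68%-missing trait in a small
subset), predictors are ranked by absolute correlation with the target and
only the strongest are retained so the PGLS stays identifiable; the design
is additionally rank-pruned on the observed rows by pivoted QR.

The number of datasets m defaults to the percentage of missing cells
(25% missing → m = 25), floored at 2. Chain convergence is summarized by
the slope of imputed-cell means over the final half of sweeps (flagged
converged when statistically indistinguishable from zero) and the
between-/within-dataset variance ratio of those means.

## Phylogenetic mixed model

The animal model y = Xβ + u + e, u ~ N(0, σ²_a·C), e ~ N(0, σ²_e·I) is
sampled by a blocked Gibbs sampler in the eigenbasis of C (C = QΛQᵀ):
rotating by Qᵀ makes the random-effect covariance diagonal, so each
iteration draws β from its exact conditional with u integrated out
(a p-dimensional Gaussian), then the rotated u elementwise, then both
variances from conjugate inverse-gamma conditionals. The prior is flat on
β and IG(0.001, 0.001) on both variances — a weakly informative proper
stand-in for "uniform and uninformative" (a truly flat variance prior
breaks conjugacy); shape and scale are exposed for sensitivity analysis.
Categorical fixed effects use treatment coding with explicit baselines
(registry file `data/models.yaml`); interactions multiply encoded columns.

Summaries: phylogenetic heritability h² = σ²_a/(σ²_a + σ²_e) per sample;
DIC = D̄ + pD with the deviance evaluated with u integrated out
(y ~ N(Xβ, σ²_a C + σ²_e I)) and pD = D̄ − D(posterior means); per-parameter
effective sample size and split-R̂ via ArviZ; a coefficient is labelled
significant when ≥ 95% of its posterior mass lies above zero (positive) or
≤ 5% (negative).

Default sampler settings are desk-scale (20,000 iterations, 4,000 burn-in,
thinning 10, two chains), adequate for the effect sizes the generator
builds in; full scale (1,000,042 / 150,000 / 250, two
chains) is available behind the CLI's `--reference-scale` flag. Tests and the
acceptance script use 3,000–4,000 iterations, which this sampler's mixing
(independence-like draws of β) makes sufficient; these problem sizes are
the package's own test-design choice.

## Pooling

Per coefficient, each run (one imputed dataset × one chain) contributes its
posterior mean and variance; Rubin's rules give Q̄, Ū, B and
T = Ū + (1 + 1/m)B, with √T the primary standard error (the mean posterior
SD is also emitted). Posterior tail fractions are pooled by concatenating
all runs' samples with equal weight — Rubin's rules are defined for point
estimates, not tail probabilities. DIC and heritability pool as plain means
across runs. Interval degrees of freedom use the Barnard–Rubin small-sample
formula; the significance rule is fraction-based and does not use them.

## Evolutionary-mode selection

BM, Ornstein–Uhlenbeck (OU) and early-burst (EB) models are fit by maximum
likelihood with the root state (and OU optimum θ = z0, the
ultrametric-tree convention) and rate σ² profiled out analytically; OU's α
and EB's a are found by a 32-point grid (log-spaced for α over
[1e-8, 50/depth]; linear for a over [−10/depth, 0]) refined by bounded
scalar minimization. The BM limit (α → 0, a → 0) is always an explicit
candidate, so the nesting inequalities loglik(OU), loglik(EB) ≥ loglik(BM)
hold on every instance. Models are ranked by AIC (no small-sample
correction). An optional parametric-bootstrap adequacy check
(`assess_fit_by_simulation`) simulates under the fitted model and z-scores
the observed tip mean and variance against the simulated null — a
complement to AIC ranking for users who prefer simulation-based assessment.

Per-landmass analysis prunes the tree to each level of a grouping column
(default `origin`), skipping subsets below a 10-tip floor, and ranks the
three models for each trait.

## Missingness diagnostics

Per-column counts/fractions, the overall fraction, and pairwise
co-missingness (indicator correlation) summarize the pattern — the
co-missingness correlation is a stand-in for a formal collinearity-of-
missingness statistic. Phylogenetic signal in each column's missingness
indicator uses the Fritz–Purvis D statistic: the observed sum of
sister-clade differences (equal-weights node averaging; polytomies sum
over child pairs) standardized between a tip-shuffle null (D ≈ 1) and a
Brownian-threshold null at the observed prevalence (D ≈ 0). The minority
state count parameterizes the BM null so D is exactly invariant to
relabelling 0 ↔ 1.

## Synthetic data generator

The generator emulates the structure of a 176-species marsupial dataset
with 18 columns: log ECV, log body mass, and 16 predictor traits, of which
log ECV, log body, origin and activity period are always complete. Log
body mass evolves by BM (rate 2.25 on a unit-depth tree, root ln ≈ 6.9,
i.e. ~1 kg, spanning shrew-sized dasyurids to large kangaroos); log ECV
follows the allometry −2.87 + 0.75·log body plus trait effects plus a
residual with a phylogenetic BM part (rate 0.04) and an i.i.d. part
(sd 0.05), giving a phylogenetic heritability near 0.95 — high, as
expected for a size-driven trait. Continuous predictors combine an
allometric slope on body, their own BM part, and i.i.d. noise; categorical
predictors are threshold (liability) traits: a BM latent plus noise cut at
its sample quantiles, so their phylogenetic signal is tunable and level
shares are exact. The built-in effect is a negative litter-size
coefficient on log ECV (default −0.2 per unit log litter size); all other
effects default to zero, and `null_effects=True` zeroes everything.
Inter-predictor relationships (e.g. home range and metabolic rate scaling
with body mass) are modelling choices for realistic collinearity, not
claims about marsupials.

Missingness is imposed per column with exact counts (round(rate·n)):
MCAR uniformly; MAR with selection probability tilted by log-odds per SD of
a driver column (field metabolic rate and home range are masked
preferentially for small-bodied species); phylogenetically clumped
missingness thresholds a fresh BM liability so whole clades go missing
together (play and torpor — behavioural traits whose study effort clusters
by clade). The preset rates anchor on the emulated dataset's printed
figures (play 68% → 120/176; torpor 94/176) and sum to an overall cell-wise
fraction of ≈ 25%, which drives m = 25 under the percentage rule and leaves
exactly 13 columns below the 35% predictor threshold.

What the generator does **not** emulate: measurement error on endocranial
volumes, body-mass dimorphism, correlated missingness across columns, and
any real marsupial parameter values. Passing tests therefore demonstrate
that the pipeline's machinery is correct and calibrated under its stated
assumptions, not that any biological conclusion holds.

## Numerical choices and degenerate inputs

- Cholesky factorization is the standard whitening everywhere; covariance
  matrices get a relative 1e-12 jitter only where a sampled matrix can be
  numerically semidefinite.
- An exactly linear response gives σ̂² = 0 and an infinite log-likelihood,
  reported as such rather than masked; constant traits are rejected as
  degenerate in the evolutionary-model fits.
- Donor-pool ties break by taxon label, then a seeded uniform choice —
  reproducibility over elegance.
- All randomness flows from numpy `SeedSequence`s; per-stage seeds derive
  from a master seed hashed with the stage name, so any stage re-run from
  cached upstream artifacts reproduces downstream results bit-for-bit.

## Known limitations

- The PGLS ANCOVA assumes residuals exactly proportional to C. The
  generator's i.i.d. residual component (and any real measurement error)
  violates this, which makes the F-test anti-conservative — visibly so in
  null simulations. The mixed model does not share this problem because it
  estimates the phylogenetic and i.i.d. variance components jointly;
  branch-length transforms such as Pagel's λ, which would fix the PGLS
  side, are out of scope.
- Imputation assumes the missingness mechanism is ignorable given the
  predictors and the tree (MAR); phylogenetically clumped missingness is
  handled well precisely because tree position is part of the conditioning.
- Categorical PMM on integer codes treats levels as ordered during
  matching; with few levels and donor-based filling this is benign, but a
  dedicated polytomous model would be preferable for many-level nominal
  traits.
- The Gibbs sampler covers Gaussian responses only, and a single
  phylogenetic variance component (no multi-tree uncertainty, no Pagel's λ
  estimation).
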