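# Methods

`emaord` fits Bayesian ordinal regression models to ecological momentary
assessment (EMA) diary data: repeated, patient-nested self-reports in which
five predictor items (mood, worry, sleep, enjoyed activities, social
contact) and the outcome (self-esteem) are all scored as integers on a
1..C scale (C = 10). This note documents the models, priors, estimation,
evaluation protocol, the synthetic-data generator, and the numerical and
design choices behind them.

## Models

Let `x_jt` be the 5-vector of predictor scores for patient `j` on diary day
`t`, and `Y_jt ∈ {1..C}` the self-esteem score. Four variants are supported,
crossing two ordinal families with two slope structures.

**Cumulative (proportional-odds / ordered) logit.** The log odds of
observing rank `c` or lower are

    logit P(Y ≤ c | x) = α_c − x·β,      c = 1..C−1,

with nondecreasing cutpoints `α_1 ≤ … ≤ α_{C−1}`. Category probabilities
are successive differences of the logistic CDF. Under this sign convention
a positive slope shifts probability toward *higher* self-esteem categories.

**Stereotype logit.** Category `c`'s log odds against the baseline (last)
category are `α_c + φ_c · x·β` with identification constraints
`α_1 = φ_1 = 0` and monotone category scores `0 = φ_1 ≤ … ≤ φ_C = 1`:

    P(Y = c | x) ∝ exp(α_c + φ_c · x·β).

The scores are built as the cumulative sum of a simplex `γ` of length C−1,
so monotonicity and the endpoint constraints hold by construction. (A
nominal Dirichlet of length C is sometimes written for this construction,
but the two endpoint constraints leave exactly C−1 free increments; `φ_C`
is set to exactly 1.)

**Slope structure.** The homogeneous variants use one population slope
vector `δ` for everyone. The heterogeneous variants give each patient their
own `β_j`, partially pooled around `δ`.

## Priors

With `σ² = 100` fixed (a deliberately weak scale on the raw 1..10 predictor
metric) the hierarchy is

    δ_p  ~ Normal(μ_p, σ²),   μ_p = +1 for mood, sleep, enjoyed activities,
                               social contact; −1 for worry
    α_c  ~ Normal(0, σ²)       (free cutpoints / intercepts)
    γ    ~ Dirichlet(A, …, A), A = 1          (stereotype only)
    β_j  ~ Normal(δ, σ²)                      (heterogeneous only)
    Y_jt ~ Categorical(θ_jt).

The ±1 prior means encode the hypothesised effect directions; with variance
100 they are dominated by even modest data. The hierarchy's spread for
`β_j` is *fixed*, not learned — patient slopes are only weakly pooled
toward `δ`. All hyperparameters are configurable through `PriorConfig`.

## Estimation

Posteriors are sampled by Hamiltonian Monte Carlo written in this package:
leapfrog integration with a Metropolis correction, dual-averaging step-size
adaptation (target acceptance 0.8), a diagonal mass matrix re-estimated
once mid-warmup from warmup draws, and a jittered number of leapfrog steps
(uniform on 1..32 by default) to avoid resonant trajectories. Gradients of
the log posterior are analytic for all four variants.

Constrained blocks are sampled on unconstrained scales with the log-Jacobian
added to the target: ordered cutpoints via a first-element/log-increment
parameterization, and the simplex `γ` via logistic stick-breaking (the
zero vector maps to the uniform simplex). This is an order-preserving
transformation approach rather than rejection, chosen for sampler
efficiency; the induced posterior on the constrained parameters is exactly
likelihood × prior.

`MCMCConfig` defaults to a full-scale profile: 4 chains × 60,000
iterations, draws stored every 20th from the final 30,000 (6,000 retained
draws). `MCMCConfig.desk()` is a reduced preset (4 × 2,000, no thinning)
for interactive work; the test-suite and acceptance-script runs use an even
smaller profile (2 chains × 1,000, 500 warmup) because the posteriors
exercised there are low-dimensional and easy — verified by split R-hat
≈ 1.00 and near-nominal effective sample sizes on those runs. Chains are
seeded from a single `SeedSequence` with per-chain spawns, so runs are
bit-reproducible. Warmup tuning beyond iteration counts (step size, mass)
is left to the sampler's own adaptation.

Initialization: slopes start at 0; cumulative cutpoints start at the logit
of the empirical cumulative outcome frequencies (monotonized), which places
the latent scale correctly even for raw-scale predictors; each chain adds
N(0, 0.1²) jitter in the unconstrained space.

Parameter summaries report the posterior median and a 95% equal-tailed
interval by default; a parameter is flagged "significant" when its interval
excludes 0. Reported interval bounds at the 2.5%/97.5% labels are
equal-tailed quantiles; a highest-density option (`method="hdi"`) is
available since the two conventions are both in use for such tables.
Convergence diagnostics (rank-normalized split R-hat, bulk ESS) come from
arviz; parameters with R-hat > 1.05 are flagged.

## Evaluation protocol

**Cross-validation.** 10-fold, stratified *within* patient: each patient's
observations are shuffled and dealt round-robin across folds (random
starting fold per patient), so per-patient fold counts differ by at most
one and every patient with ≥ k observations appears in every fold. Test
folds therefore contain only patients seen in training; a genuinely new
patient is predicted from the population slopes `δ` (the stated fallback
for patients without individual parameters). Fold assignment uses an RNG
independent of the MCMC seed.

**Point predictions.** The posterior predictive category probabilities are
averaged over all stored draws; the default point prediction is the
predictive *median* (smallest category whose cumulative probability reaches
0.5), which is optimal under absolute error for ordinal outcomes. The
predictive mode and sampled categorical draws are available alternatives;
no single rule is canonical for ordinal predictions, so it is
configuration, not dogma.

**Measures.** RMSE and MAE are computed on point predictions pooled over
all folds. DIC and WAIC are computed from a single fit on the full dataset
(the comparison table carries one DIC/WAIC per model alongside the CV
errors). DIC uses `p_D = mean(D) − D(θ̄)` with the plug-in deviance
evaluated at the posterior mean taken on the *unconstrained* scale and
transformed back, which respects the ordering/simplex constraints. WAIC
uses `lppd − p_waic` on the deviance scale with the *sample* variance
(ddof = 1) of the pointwise log-likelihood as the penalty; note arviz uses
the population variance, a conversion handled exactly in the cross-check
test. Two baselines anchor the table: the **mean model** (global training
mean of the outcome, unrounded) and the **mean individual model**
(per-patient training mean). Paired absolute errors are compared with the
two-sided Wilcoxon signed-rank test (zero differences dropped; all-zero
differences give p = 1 by convention). Model-baseline and model-model
pairs are all reported rather than privileging one pairing.

## Synthetic cohorts

The generator's default design is a realistic blended-care diary cohort:
130 patients and 2,326 complete
diary days by default (116 patients × 18 days, 14 × 17), outcomes on a
10-point scale. Predictors are drawn independently and uniformly over 1..C
unless per-item marginals are supplied — no predictor joint distribution
was available to emulate, so correlation structure is deliberately out of
scope. Patient slopes are Normal(slope_means, heterogeneity_sd²); the
default population slopes (0.4, −0.3, 0.2, 0.3, 0.2) are modest raw-scale
effects with the hypothesised signs, and the default between-patient SD of
1.0 per slope makes heterogeneity strong enough that heterogeneity-aware
models are clearly separated from pooled ones.

Cumulative-family cutpoints are drawn around quantile-spaced centers of the
induced linear-predictor distribution (including the heterogeneity
contribution) and sorted, so simulated outcomes cover all C categories
rather than piling at the extremes. Stereotype-family scores come from a
symmetric Dirichlet; intercepts are centered at `−φ_c · E[x·β]` with small
noise so the average patient is not pinned to a boundary category.

What the generator does **not** emulate: the diary prompt schedule,
missing-data mechanisms and dropout, predictor autocorrelation and
between-item correlation, or temporal dynamics (the models are
contemporaneous, so time indices are ordinal bookkeeping only). Passing
tests on these cohorts therefore demonstrate correctness of the machinery
and the qualitative value of patient-level slopes under the stated
conditions — not clinical performance on real diary data.

A consequence of the strong default heterogeneity is worth stating: a
*homogeneous* model is patient-blind, while the mean-individual baseline
conditions on patient identity. With between-patient slope SD 1.0 the
baseline therefore outpredicts the homogeneous models — only the
heterogeneity-aware models beat it (the true-parameter oracle and the
fitted heterogeneous models do so comfortably). On data with modest
heterogeneity, all four models can beat
both baselines; that full ordering is not reproducible under the strong
heterogeneity used here, and the test suite marks that distinction
explicitly.

## Numerical choices

- Cumulative log-probabilities use
  `log(σ(a) − σ(b)) = log σ(a) + log σ(−b) + log1p(−exp(b−a))`, stable for
  linear predictors up to ±1e4 and at the ±∞ padding of the boundary
  categories; stereotype probabilities use max-subtracted softmax.
- Zero-probability proposals (e.g. cutpoint increments underflowing to 0)
  evaluate to −∞ and are rejected by the sampler rather than clipped.
- Ties in the predictive mode break toward the lower category; the
  predictive median uses the smallest category reaching cumulative 0.5.
- Stored draws satisfy their constraints exactly (`φ_C = 1` is forced after
  the cumulative sum; sorted cutpoints come from the strictly increasing
  transform).
- Degenerate inputs: empty datasets and incomplete datasets are rejected
  before fitting; an all-missing filter result is allowed with a warning;
  fold counts k > N are rejected.

## Known limitations

- The fixed `σ² = 100` hierarchy spread means patient slopes are barely
  pooled; with few observations per patient their posteriors are wide, and
  out-of-sample prediction approaches the oracle only as per-patient data
  grows. An optional learned heterogeneity scale is a natural extension and
  is intentionally not enabled by default.
- The HMC sampler is a straightforward fixed-trajectory implementation, not
  NUTS; very high-dimensional fits (hundreds of patients, heterogeneous
  slopes) mix more slowly than a tree-building sampler would.
- DIC's plug-in estimate can misbehave under strong posterior asymmetry;
  WAIC is the preferred comparison measure here.
- No partial-proportional-odds or adjacent-category variants, no covariate
  interactions, and no temporal/lagged terms.
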