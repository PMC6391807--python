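# Methods

## Model

`gsscox` estimates posterior modes of a hierarchical Cox model. The
likelihood is the Cox partial likelihood

    pl(β) = Σ_{i: d_i=1} [ η_i − log Σ_{k: t_k ≥ t_i} exp(η_k) ],   η = Xβ,

with Breslow (default) or Efron handling of tied event times. A subject is
at risk at time t when its observed time is ≥ t; event ties are grouped by
exact time equality. Input times need not be sorted; an internal
sort-with-permutation is applied and all results are mapped back.

Each coefficient carries a two-component double-exponential mixture prior
with spike scale `s0` and slab scale `s1` (`0 < s0 ≤ s1`), switched by a
latent indicator; indicators within a group share a Bernoulli probability
`θ_g` with a beta(a, b) hyperprior. The density is parameterized as
`(1/s) exp(−|β|/s)`; the conventional ½ factor cancels from the posterior
odds of spike versus slab, so it is omitted consistently.

Defaults: `s0 = 0.02`, `s1 = 1`, `a = b = 1` (uniform hyperprior),
`β⁰ = 0`, `θ_g⁰ = 0.5`, `eps = 1e−5`, `max_iter = 200`. The slab scale 1
leaves detected effects of order ±1 essentially unshrunk on standardized
predictors; the spike scale grid `{0.01, …, 0.09}` used by the CV path
covers the useful shrinkage range (at `s0 ≥ s1` the model degenerates to a
uniform lasso).

## Overlapping groups

A predictor belonging to several groups is replicated once per group, so
every expanded coefficient has exactly one group and the E-step formulas
are unambiguous. Collapsing back sums the replicate coefficients, which
preserves the fitted linear predictor exactly (verified to 1e−12 in the
tests). Predictors in no group are pooled into one catch-all group by
default (`catch_all=False` disables this). Unpenalized covariates (penalty
factor 0) bypass the spike-and-slab machinery and the θ updates.

## Algorithm and numerical choices

- E-step: `p_j = de(β_j|s1)θ_g / [de(β_j|s0)(1−θ_g) + de(β_j|s1)θ_g]`,
  `E[S_j⁻¹] = (1−p_j)/s0 + p_j/s1`. `θ_g` is clipped to
  `[1e−8, 1−1e−8]` before use so the states 0/1 are not absorbing.
- M-step: `β` maximizes `pl(β) − Σ_j E[S_j⁻¹]|β_j|` via IRLS — the diagonal
  quadratic approximation of −pl (per-subject weights and working
  responses) — with cyclic coordinate descent and soft-thresholding on the
  weighted least-squares subproblem. An active-set strategy is used: after
  the coordinates converge, a vectorized full sweep adds subgradient
  violators until none remain. IRLS weights are floored at 1e−8 so
  subjects carrying no information (censored before every event time) are
  inert. A step-halving guard keeps the penalized objective from
  decreasing (the plain IRLS step is not formally monotone). Penalty
  factors ≥ 1e10 are treated as infinite and pin coefficients at zero.
  `θ_g` then updates in closed form from the E-step probabilities.
- Convergence: inner solver on max absolute coefficient change
  (default 1e−6); EM on the relative deviance change
  `|d(t) − d(t−1)| / (0.1 + |d(t)|) < eps` with `d = −2 pl`.
- Predictors are standardized to mean 0, sample sd 1 (n−1 denominator)
  before fitting; coefficients are reported on the standardized scale with
  `coef_raw_` giving the raw-scale back-transform.
- The EM is deterministic given the data; all randomness lives in the
  simulator and in fold assignment, both driven by explicit seeds.
- The spike-and-slab posterior is multimodal at small `s0`. The CV path
  fits scales from largest to smallest with warm starts, which tracks one
  mode along the path; a cold start at a small `s0` can land in a
  different (typically worse) mode. The monotone EM diagnostic is the
  γ-marginalized log posterior (`log_marginal_posterior`); the expected
  complete-data form (`log_joint_posterior`) differs by the E-step entropy
  and is reported for inspection only.
- The coordinate-descent kernel is JIT-compiled with numba; results are
  identical to the pure-numpy path it replaced.

## Evaluation

- C-index: Harrell's estimator (a pair is usable iff the member with the
  earlier observed time had the event; score ties count ½), computed via
  scikit-survival.
- CVPL: `Σ_k [pl(β̂_(−k)) − pl_(−k)(β̂_(−k))]` — full-data minus
  training-data partial likelihood at each fold-excluded estimate. The
  pre-validation routine additionally reports the partial likelihood of
  the pooled out-of-fold prognostic index, a related but distinct
  likelihood summary; the two can differ by hundreds of units on the same
  data, so reports state which is used.
- Folds are stratified by event status (events and censored subjects dealt
  round-robin after seeded shuffles), so no fold is event-free whenever
  K ≤ number of events. Pre-validated indices never use the subject's own
  outcome; a leakage audit in the tests corrupts one fold's outcomes and
  confirms the other folds' predictions are unchanged.
- Defaults K = 10 with 10 replicates, reducible for desk-scale runs.

## Simulation engine

Six study designs, each with n = 500 subjects per dataset (training and
test generated independently from deterministically spawned sub-seeds) and
m = 1000 zero-mean unit-variance Gaussian predictors in 20 groups of about
50; eight coefficients are nonzero with effects
(0.8, −0.7, 1.0, −0.9, −0.8, 0.9, −1.0, 0.7). True survival times are
exponential with rate `exp(x_i'β)`; censoring times are exponential with
rate `exp(r_i)`, `r_i ~ N(0,1)`, giving exactly 50% expected censoring at
β = 0 and generally just under 50% with signal. Within-block correlation
is r = 0.5 unless swept (0, 0.5, 0.7 in design 5).

Design layouts follow the printed group ranges, including the overlapping
ones whose sizes are 55 rather than the nominal 50 (groups 2–19 start five
positions before the previous group ends; the last group stands alone).
Indices are 1-based in specifications and reports and converted
internally.

One reconstruction choice deserves emphasis: a correlation matrix with
unit diagonal, r for every pair sharing a group and 0 elsewhere is
indefinite under the overlapping layouts (minimum eigenvalue −1.99 at
r = 0.5), so no Gaussian with that structure exists. The engine therefore
defines the correlation blocks by the disjoint partition that assigns each
predictor to the first group containing it; the overlap affects only the
model's group structure, as with real pathways. A consequence is that the
overlapping designs generate data distributionally identical to the
non-overlap design, and their achievable (oracle) test concordance is the
same ≈ 0.849 ceiling; reported concordances above that ceiling for
overlap designs in the literature imply a different, unstated covariance
construction. Blocks are sampled by a shared-factor construction
(`√r·z_g + √(1−r)·e_j`), equivalent in law to the equicorrelated block and
never materializing the m × m matrix; `make_block_covariance` provides the
dense matrix for verification.

What the generator does not emulate: real expression data are nonnegative,
heavy-tailed, and heteroscedastic, with correlation that decays within
pathways rather than being exchangeable, and censoring is rarely
independent of covariates. Passing the simulation benchmarks therefore
demonstrates correctness of the estimator and its evaluation machinery
under the stated Gaussian/exponential conditions, not field performance on
any particular cancer cohort.

## Expression preprocessing

Three rules in order: drop genes whose maximum expression across samples
(configurable to the mean) is below 10; drop genes with more than 30% zero
values; among the remainder, keep genes whose coefficient of variation
(sample sd / mean) exceeds its 20% quantile. Attrition per rule is
reported. Standardization uses the sample sd and errors on constant
columns, naming the offender.

## Problem sizes used in the shipped benchmarks

The test suite and the acceptance script run the full-size designs
(n = 500, m = 1000) at 20 Monte-Carlo replicates for the concordance
benchmarks and 10 replicates for the cross-validated likelihood benchmark;
these counts give two-standard-error bands a few thousandths wide on the
C-index scale while keeping a complete run in a few minutes on one CPU.

## Known limitations

- Posterior-mode estimation only: no MCMC, no uncertainty intervals for β.
- No baseline-hazard estimation or survival-curve prediction; the model
  outputs prognostic indices and selection summaries.
- No time-dependent covariates, left truncation, or competing risks.
- The lasso comparator tunes a single global penalty by CVPL on a
  geometric grid anchored at the data-derived λ_max; its selected model
  size is sensitive to the grid floor, as is inherent to lasso-path CV.
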