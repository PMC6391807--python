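# gsscox — group spike-and-slab lasso Cox models

`gsscox` fits Bayesian hierarchical Cox proportional-hazards models for
high-dimensional survival data in which the predictors (typically gene
expression values) carry known group structure such as biological pathways.
It is aimed at biostatisticians building prognostic models from omics data
who want *bi-level* selection — which pathways matter, and which genes
within them — together with honest cross-validated performance estimates.

## Model

The hazard for subject *i* is `h(t|x_i) = h0(t) exp(x_i'β)`, and `β` is
estimated as a posterior mode under a group-structured spike-and-slab
double-exponential (Laplace) prior:

    β_j | γ_j  ~  de(0, (1−γ_j) s0 + γ_j s1),     de(β|0,s) = (1/s) exp(−|β|/s)
    γ_j | θ_g  ~  Bernoulli(θ_g)                  (j in group g)
    θ_g        ~  beta(a, b)

The spike scale `s0` is small (strong shrinkage of noise coefficients), the
slab scale `s1` is large (detected signals stay essentially unshrunk), and
the group-level probability `θ_g` couples the genes of a pathway: when one
member shows signal, `θ_g` rises and the shrinkage on the rest of the group
weakens. Groups may overlap; overlapping predictors are replicated once per
group (overlap-group-lasso convention) and the replicate coefficients are
summed back afterwards.

Fitting is by an EM coordinate-descent algorithm. The E-step is closed
form: the posterior inclusion probability `p_j` of each coefficient and its
expected inverse prior scale `E[S_j⁻¹] = (1−p_j)/s0 + p_j/s1`. The M-step
maximizes `pl(β) − Σ_j E[S_j⁻¹]|β_j|` — a weighted-L1 penalized Cox partial
likelihood, solved by cyclic coordinate descent with soft-thresholding —
and updates `θ_g = (Σ_{j∈g} p_j + a − 1)/(J_g + a + b − 2)`. Iteration
stops when the relative deviance change `|d(t) − d(t−1)|/(0.1 + |d(t)|)`
drops below `eps` (default 1e−5).

Evaluation machinery includes Harrell's C-index, the cross-validated
partial likelihood, and K-fold pre-validation; a built-in simulation engine
reproduces six block-correlated survival study designs for benchmarking.

## Worked example

```python
import numpy as np
from gsscox import GroupSpikeSlabLassoCox, ScenarioSpec, generate_scenario

# 500 subjects, 1000 predictors in 20 groups of 50, 8 true signals,
# exponential survival with ~50% censoring
spec = ScenarioSpec(scenario=1, seed=7)
train, test = generate_scenario(spec)

model = GroupSpikeSlabLassoCox(s0=0.02, s1=1.0, groups=train.groups,
                               catch_all=False).fit(train.X, train.y)
picked = np.flatnonzero(model.coef_)
print("nonzero predictors (1-based):", list(picked + 1))
print("coefficients:", np.round(model.coef_[picked], 3))
print("test-set C-index: %.3f" % model.score(test.X, test.y))
```

prints

```
nonzero predictors (1-based): [5, 20, 40, 210, 220, 240, 941, 975, 995]
coefficients: [ 0.918 -0.655  1.048 -0.989 -0.707  0.94   0.048 -0.974  0.73 ]
test-set C-index: 0.847
```

The model recovers all eight simulated signals (true effects 0.8, −0.7,
1.0, −0.9, −0.8, 0.9, −1.0, 0.7 at positions 5, 20, 40, 210, 220, 240, 975,
995) with nearly unshrunk estimates, plus one small false positive, and the
prognostic index ranks the independent test subjects with concordance
0.847. `model.theta_` shows the three signal-bearing groups (1, 5, 20) with
elevated inclusion probabilities relative to null groups.

The same functionality is available from the shell:

```bash
gsscox simulate --scenario 1 --seed 7 --out sim/
gsscox fit  --x sim/X.tsv --surv sim/survival.tsv --groups sim/groups.gmt \
            --s0 0.02 --out fit/
gsscox path --x sim/X.tsv --surv sim/survival.tsv --groups sim/groups.gmt \
            --s0-grid 0.01,0.02,0.03,0.04 --k 10 --out path/
```

`GroupSpikeSlabLassoCoxCV` fits a decreasing grid of spike scales with warm
starts and selects `s0` by cross-validated partial likelihood;
`LassoCoxCV` provides the plain lasso Cox comparator (the `s0 = s1`
degenerate case, uniform penalty tuned by CV). Real expression matrices can
be prepared with `gsscox.filter_genes` (low-expression / zero-fraction /
coefficient-of-variation rules) and pathway membership read from GMT files
with `gsscox.read_gmt`.

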