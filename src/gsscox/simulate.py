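"""Synthetic survival data with block-correlated predictors and group layouts.

Six study designs are provided.  Each dataset has n = 500 subjects and
m = 1000 zero-mean Gaussian predictors organized in 20 groups of about 50;
predictors are equicorrelated (r, default 0.5) within a correlation block
and independent across blocks.  Eight coefficients are nonzero with effects
(0.8, -0.7, 1.0, -0.9, -0.8, 0.9, -1.0, 0.7); the rest are zero.  True
survival times are exponential with rate exp(x_i' beta), censoring times
exponential with rate exp(r_i), r_i ~ N(0, 1); the observed time is the
minimum and the event indicator marks which came first.  At beta = 0 this
censoring mechanism censors exactly half the subjects in expectation.

Designs:

1. twenty disjoint groups of 50; signals in groups 1, 5 and 20;
2. consecutive groups overlap by five predictors (x46..x50 sit in groups 1
   and 2, and so on); the last group stands alone; same signals as 1;
3. groups 1 and 11 shrink to size 4, 20 or 50 while holding four signals
   each (x1..x4 and x501..x504);
4. the eight signals are spread over 8, 3 or 1 non-null group(s);
5. as design 2 with within-block correlation r in {0.0, 0.5, 0.7};
6. as design 2 but the effect of x5 is swept over [-2, 2] to trace the
   self-adaptive shrinkage profile.

Overlapping groups cannot all be equicorrelated at r > 0 with zeros
elsewhere (the implied matrix is indefinite), so correlation blocks are the
disjoint partition obtained by assigning each predictor to the first group
containing it; the overlap then lives purely in the model's group
structure, as it does for real pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .groups import GroupStructure
from .survival import SurvivalOutcome

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "make_block_covariance",
    "simulate_predictors",
    "simulate_survival",
    "generate_scenario",
    "scenario_groups",
]

EFFECT_SIZES = np.array([0.8, -0.7, 1.0, -0.9, -0.8, 0.9, -1.0, 0.7])

# 1-based nonzero predictor indices per design / variant
_NONZERO = {
    1: (5, 20, 40, 210, 220, 240, 975, 995),
    2: (5, 20, 40, 210, 220, 240, 975, 995),
    5: (5, 20, 40, 210, 220, 240, 975, 995),
    6: (5, 20, 40, 210, 220, 240, 975, 995),
    (3, 4): (1, 2, 3, 4, 501, 502, 503, 504),
    (3, 20): (1, 2, 3, 4, 501, 502, 503, 504),
    (3, 50): (1, 2, 3, 4, 501, 502, 503, 504),
    (4, 8): (5, 55, 305, 355, 505, 555, 905, 955),
    (4, 3): (5, 15, 25, 355, 365, 375, 905, 915),
    (4, 1): (5, 10, 15, 20, 25, 30, 35, 40),
}


def _ranges_to_groups(ranges, m):
    groups = tuple(np.arange(a - 1, b) for a, b in ranges)
    names = tuple(f"group{i+1}" for i in range(len(groups)))
    return GroupStructure(groups, names, m)


def _disjoint_ranges(m=1000, size=50):
    return [(k * size + 1, (k + 1) * size) for k in range(m // size)]


def _overlap_ranges(m=1000):
    # group 1: x1-x50; groups 2..19 start five before the previous end;
    # group 20 (x951-x1000) stands alone
    ranges = [(1, 50)]
    for g in range(2, 20):
        ranges.append(((g - 1) * 50 - 4, g * 50))
    ranges.append((951, 1000))
    return ranges


def _varying_size_ranges(size, m=1000):
    """Design-3 layouts: groups 1 and 11 have the given size (4, 20 or 50);
    groups 1 and 11 start at x1 and x501, their successors cover the rest of
    the first/ eleventh 100-block (overlapping by five when size is 50)."""
    ranges = [(1, size), (size + 1 - (5 if size == 50 else 0), 100)]
    for g in range(3, 11):
        ranges.append(((g - 1) * 50 - 4, g * 50))
    ranges += [(501, 500 + size), (500 + size + 1 - (5 if size == 50 else 0), 600)]
    for g in range(13, 20):
        ranges.append(((g - 1) * 50 - 4, g * 50))
    ranges.append((951, 1000))
    return ranges


def scenario_groups(scenario: int, variant=None, m: int = 1000) -> GroupStructure:
    """The model group structure of a design (1-based printed ranges)."""
    if scenario == 1:
        return _ranges_to_groups(_disjoint_ranges(m), m)
    if scenario in (2, 4, 5, 6):
        return _ranges_to_groups(_overlap_ranges(m), m)
    if scenario == 3:
        if variant not in (4, 20, 50):
            raise ValueError("design 3 variant must be a group size in {4, 20, 50}")
        return _ranges_to_groups(_varying_size_ranges(variant, m), m)
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the six simulation designs.

    ``variant`` selects the sub-design: the group size (4/20/50) for design
    3, the number of non-null groups (8/3/1) for design 4, the within-block
    correlation for design 5, and the swept effect of x5 for design 6.
    """

    scenario: int = 1
    n: int = 500
    m: int = 1000
    r: float = 0.5
    variant: object = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4, 5, 6):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 <= self.r < 1):
            raise ValueError("within-block correlation must lie in [0, 1)")
        if self.scenario == 5:
            r = 0.5 if self.variant is None else float(self.variant)
            object.__setattr__(self, "r", r)
            object.__setattr__(self, "variant", r)
        if self.scenario == 6 and self.variant is not None:
            if not (-2.0 <= float(self.variant) <= 2.0):
                raise ValueError("design 6 sweeps the x5 effect over [-2, 2]")

    @property
    def groups(self) -> GroupStructure:
        return scenario_groups(self.scenario, self.variant, self.m)

    @property
    def beta_true(self) -> np.ndarray:
        key = self.scenario if self.scenario in (1, 2, 5, 6) else (self.scenario, self.variant)
        if key not in _NONZERO:
            raise ValueError(f"unknown design variant {self.variant!r} for scenario {self.scenario}")
        beta = np.zeros(self.m)
        idx = np.asarray(_NONZERO[key]) - 1
        effects = EFFECT_SIZES.copy()
        if self.scenario == 6 and self.variant is not None:
            effects[0] = float(self.variant)
        beta[idx] = effects
        return beta

    @property
    def nonzero_indices(self) -> np.ndarray:
        """1-based indices of the truly nonzero predictors."""
        key = self.scenario if self.scenario in (1, 2, 5, 6) else (self.scenario, self.variant)
        return np.asarray(_NONZERO[key])


@dataclass(frozen=True)
class SimulatedDataset:
    X: np.ndarray
    y: SurvivalOutcome
    beta_true: np.ndarray
    T: np.ndarray               # true survival times
    C: np.ndarray               # censoring times
    groups: GroupStructure = None

    @property
    def censoring_fraction(self) -> float:
        return 1.0 - float(self.y.status.mean())


def _correlation_blocks(gs: GroupStructure, m: int):
    """Disjoint partition for the covariance: first group wins overlaps."""
    owner = np.full(m, -1, dtype=np.intp)
    for k, g in enumerate(gs.groups):
        fresh = g[owner[g] < 0]
        owner[fresh] = k
    blocks = [np.flatnonzero(owner == k) for k in range(gs.n_groups)]
    blocks = [b for b in blocks if b.size]
    un = np.flatnonzero(owner < 0)
    if un.size:
        blocks.append(un)
    return blocks


def make_block_covariance(m: int, gs: GroupStructure, r: float) -> np.ndarray:
    """Unit-diagonal covariance with r inside each block, 0 across blocks.

    Positive definite for any r in [0, 1).  Overlapping groups are reduced
    to the disjoint first-occurrence partition (see module docstring).
    """
    if not (0 <= r < 1):
        raise ValueError("r must lie in [0, 1)")
    cov = np.eye(m)
    for b in _correlation_blocks(gs, m):
        cov[np.ix_(b, b)] += r * (1.0 - np.eye(b.size))
    return cov


def simulate_predictors(n: int, cov_or_blocks, seed: int, r: float | None = None) -> np.ndarray:
    """Zero-mean Gaussian predictor draws with the given covariance.

    Accepts either a dense covariance matrix, or a block list together with
    ``r`` (sampled per block via a shared-factor construction, equivalent in
    distribution and never materializing the m x m matrix).
    """
    rng = np.random.default_rng(seed)
    if isinstance(cov_or_blocks, np.ndarray) and cov_or_blocks.ndim == 2:
        L = np.linalg.cholesky(cov_or_blocks)
        return rng.standard_normal((n, cov_or_blocks.shape[0])) @ L.T
    blocks = cov_or_blocks
    if r is None:
        raise ValueError("r is required when sampling from blocks")
    m = int(max(int(b.max()) for b in blocks) + 1)
    X = np.empty((n, m))
    for b in blocks:
        z = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, b.size))
        X[:, b] = np.sqrt(r) * z + np.sqrt(1.0 - r) * e
    return X


def simulate_survival(X, beta_true, seed: int):
    """Exponential survival and censoring given the linear predictor.

    T_i ~ Expon(rate = exp(x_i' beta)), C_i ~ Expon(rate = exp(r_i)) with
    r_i ~ N(0, 1); t_i = min(T_i, C_i) and d_i = 1 iff C_i > T_i.
    """
    X = np.asarray(X, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    rng = np.random.default_rng(seed)
    eta = X @ beta_true
    T = rng.exponential(scale=np.exp(-eta))
    ri = rng.standard_normal(X.shape[0])
    C = rng.exponential(scale=np.exp(-ri))
    t = np.minimum(T, C)
    d = (C > T).astype(float)
    return SurvivalOutcome(t, d), T, C


def _simulate_one(spec: ScenarioSpec, seed: int) -> SimulatedDataset:
    gs = spec.groups
    blocks = _correlation_blocks(gs, spec.m)
    X = simulate_predictors(spec.n, blocks, seed, r=spec.r)
    y, T, C = simulate_survival(X, spec.beta_true, seed + 1_000_003)
    return SimulatedDataset(X=X, y=y, beta_true=spec.beta_true, T=T, C=C, groups=gs)


def generate_scenario(spec: ScenarioSpec):
    """Independent training and test datasets from the same design.

    Sub-seeds for the two datasets are derived deterministically from
    ``spec.seed`` via numpy's seed-sequence spawning.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_train, s_test = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    return _simulate_one(spec, s_train), _simulate_one(spec, s_test)
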