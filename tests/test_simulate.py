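import numpy as np
import pytest
from scipy import stats

from gsscox import (
    GroupStructure,
    ScenarioSpec,
    generate_scenario,
    make_block_covariance,
    simulate_predictors,
    simulate_survival,
)
from gsscox.simulate import EFFECT_SIZES, scenario_groups


class TestBlockCovariance:
    def test_two_blocks_of_two(self):
        gs = GroupStructure.from_spec([[0, 1], [2, 3]], 4)
        cov = make_block_covariance(4, gs, 0.5)
        expected = np.array([
            [1.0, 0.5, 0.0, 0.0],
            [0.5, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.5],
            [0.0, 0.0, 0.5, 1.0],
        ])
        assert np.allclose(cov, expected)

    def test_r_zero_is_identity(self):
        gs = GroupStructure.from_spec([[0, 1, 2]], 3)
        assert np.allclose(make_block_covariance(3, gs, 0.0), np.eye(3))

    def test_positive_definite_with_overlap(self):
        gs = scenario_groups(2, m=1000)
        cov = make_block_covariance(1000, gs, 0.7)
        np.linalg.cholesky(cov)  # raises if not PD

    def test_invalid_r(self):
        gs = GroupStructure.from_spec([[0, 1]], 2)
        with pytest.raises(ValueError):
            make_block_covariance(2, gs, 1.0)


class TestPredictorSampling:
    def test_reproducible(self):
        gs = GroupStructure.from_spec([[0, 1, 2], [3, 4]], 5)
        cov = make_block_covariance(5, gs, 0.5)
        X1 = simulate_predictors(100, cov, seed=3)
        X2 = simulate_predictors(100, cov, seed=3)
        assert np.array_equal(X1, X2)

    def test_block_correlation_large_sample(self):
        blocks = [np.arange(0, 5), np.arange(5, 10)]
        X = simulate_predictors(100_000, blocks, seed=1, r=0.5)
        emp = np.corrcoef(X, rowvar=False)
        within = emp[0, 1:5]
        across = emp[0, 5:]
        assert np.all(np.abs(within - 0.5) < 0.01)
        assert np.all(np.abs(across) < 0.01)
        assert np.all(np.abs(X.mean(axis=0)) < 3 / np.sqrt(100_000))

    def test_factor_and_cholesky_samplers_agree_in_law(self):
        gs = GroupStructure.from_spec([[0, 1, 2, 3]], 4)
        cov = make_block_covariance(4, gs, 0.6)
        Xc = simulate_predictors(50_000, cov, seed=5)
        Xb = simulate_predictors(50_000, [np.arange(4)], seed=6, r=0.6)
        assert np.allclose(np.cov(Xc, rowvar=False), np.cov(Xb, rowvar=False), atol=0.02)


class TestSurvivalGeneration:
    def test_censoring_fraction_half_at_null(self):
        X = np.zeros((100_000, 1))
        y, T, C = simulate_survival(X, np.zeros(1), seed=7)
        assert abs((1 - y.status.mean()) - 0.5) < 0.01

    def test_true_times_exponential_at_null(self):
        X = np.zeros((50_000, 1))
        _, T, _ = simulate_survival(X, np.zeros(1), seed=8)
        assert stats.kstest(T, "expon").pvalue > 0.01

    def test_indicator_consistency(self, rng):
        X = rng.normal(size=(500, 3))
        y, T, C = simulate_survival(X, np.array([0.5, -0.5, 0.0]), seed=9)
        assert np.allclose(y.time, np.minimum(T, C))
        assert np.array_equal(y.status == 1.0, T < C)


class TestScenarioLayouts:
    def test_scenario1_disjoint_blocks(self):
        gs = scenario_groups(1)
        assert gs.n_groups == 20
        assert np.all(gs.group_sizes == 50)
        assert list(gs.groups[0][:3]) == [0, 1, 2]
        assert list(gs.groups[19][-1:]) == [999]

    def test_scenario1_signals(self):
        spec = ScenarioSpec(scenario=1)
        assert list(spec.nonzero_indices) == [5, 20, 40, 210, 220, 240, 975, 995]
        nz = spec.beta_true[spec.nonzero_indices - 1]
        assert np.allclose(nz, [0.8, -0.7, 1.0, -0.9, -0.8, 0.9, -1.0, 0.7])

    def test_scenario2_overlap_ranges(self):
        gs = scenario_groups(2)
        assert gs.n_groups == 20
        # group 1: x1-x50; group 2: x46-x100 (overlap of 5); group 20 alone
        assert list(gs.groups[0][[0, -1]]) == [0, 49]
        assert list(gs.groups[1][[0, -1]]) == [45, 99]
        assert list(gs.groups[18][[0, -1]]) == [895, 949]
        assert list(gs.groups[19][[0, -1]]) == [950, 999]
        assert len(np.intersect1d(gs.groups[0], gs.groups[1])) == 5
        assert len(np.intersect1d(gs.groups[18], gs.groups[19])) == 0

    @pytest.mark.parametrize("size", [4, 20, 50])
    def test_scenario3_group_sizes(self, size):
        gs = scenario_groups(3, variant=size)
        assert gs.group_sizes[0] == size
        assert gs.group_sizes[10] == size
        assert gs.groups[10][0] == 500
        spec = ScenarioSpec(scenario=3, variant=size)
        assert list(spec.nonzero_indices) == [1, 2, 3, 4, 501, 502, 503, 504]

    @pytest.mark.parametrize(
        "variant,expected",
        [
            (8, [5, 55, 305, 355, 505, 555, 905, 955]),
            (3, [5, 15, 25, 355, 365, 375, 905, 915]),
            (1, [5, 10, 15, 20, 25, 30, 35, 40]),
        ],
    )
    def test_scenario4_non_null_groups(self, variant, expected):
        spec = ScenarioSpec(scenario=4, variant=variant)
        assert list(spec.nonzero_indices) == expected
        assert np.allclose(spec.beta_true[spec.nonzero_indices - 1], EFFECT_SIZES)

    def test_scenario5_correlation_variants(self):
        for r in (0.0, 0.5, 0.7):
            spec = ScenarioSpec(scenario=5, variant=r)
            assert spec.r == r

    def test_scenario5_empirical_block_correlation(self):
        spec = ScenarioSpec(scenario=5, variant=0.7, n=10_000, seed=3)
        train, _ = generate_scenario(spec)
        block = train.X[:, :50]
        emp = np.corrcoef(block, rowvar=False)
        off = emp[np.triu_indices(50, 1)]
        assert abs(off.mean() - 0.7) < 0.02

    def test_scenario6_sweeps_x5(self):
        spec = ScenarioSpec(scenario=6, variant=-1.5)
        assert spec.beta_true[4] == -1.5
        assert spec.beta_true[19] == -0.7
        with pytest.raises(ValueError):
            ScenarioSpec(scenario=6, variant=3.0)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            ScenarioSpec(scenario=7)


class TestGenerateScenario:
    def test_reproducible_and_independent(self):
        spec = ScenarioSpec(scenario=1, n=80, seed=5)
        tr1, te1 = generate_scenario(spec)
        tr2, te2 = generate_scenario(spec)
        assert np.array_equal(tr1.X, tr2.X)
        assert np.array_equal(te1.X, te2.X)
        assert not np.array_equal(tr1.X, te1.X)

    def test_censoring_generally_below_half(self):
        fracs = [
            generate_scenario(ScenarioSpec(scenario=1, seed=s))[0].censoring_fraction
            for s in range(10)
        ]
        assert np.mean([f < 0.55 for f in fracs]) >= 0.95
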