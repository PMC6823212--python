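"""Unit tests of the individual Gibbs steps against independent oracles,
plus chain-level invariants (determinism, anchors, sign coherence)."""

import numpy as np
import pytest
from scipy.stats import invwishart, norm

from mlmirt import (
    ChainConfig,
    ItemParameters,
    ModelSpec,
    PriorSpec,
    full_random_spec,
    run_chain,
    simulation1_design,
)
from mlmirt.model import HierarchicalDataset, ModelError
from mlmirt.sampler import (
    _Layout,
    conditional_variances,
    sample_abilities,
    sample_augmented_scores,
    sample_fixed_effects,
    sample_item_parameters,
    sample_level2_coefficients,
    sample_level2_covariance,
    sample_level3_covariance,
)


def _items_1d(a, b):
    arr = np.asarray(a, dtype=float)[:, None]
    return ItemParameters(arr, np.asarray(b, dtype=float),
                          np.zeros(len(arr), dtype=bool))


class TestAugmentedScores:
    def test_sign_coherence(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(size=(50, 2))
        items = ItemParameters(rng.uniform(0.5, 2, (8, 2)), rng.normal(size=8))
        Y1 = np.ones((50, 8), dtype=int)
        Z = sample_augmented_scores(Y1, theta, items, rng)
        assert np.all(Z > 0)
        Y0 = np.zeros((50, 8), dtype=int)
        Z = sample_augmented_scores(Y0, theta, items, rng)
        assert np.all(Z < 0)

    def test_truncated_mean_at_zero_predictor(self):
        rng = np.random.default_rng(1)
        theta = np.zeros((100_000, 1))
        items = _items_1d([1.0], [0.0])
        Z = sample_augmented_scores(np.ones((100_000, 1), dtype=int), theta, items, rng)
        assert Z.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)


class TestAbilityStep:
    def test_posterior_matches_grid_oracle(self):
        # one person, two items, Q=1: p(theta | Z) on a dense grid
        a = np.array([1.3, 0.8])
        b = np.array([0.2, -0.5])
        Z_row = np.array([0.9, -0.4])
        mu, s2 = 0.3, 0.7

        grid = np.linspace(-6, 6, 20_001)
        log_post = norm.logpdf(grid, mu, np.sqrt(s2))
        for k in range(2):
            log_post += norm.logpdf(Z_row[k], a[k] * grid - b[k], 1.0)
        w = np.exp(log_post - log_post.max())
        w /= w.sum()
        oracle_mean = float(w @ grid)
        oracle_var = float(w @ (grid - oracle_mean) ** 2)

        n = 100_000
        rng = np.random.default_rng(2)
        items = _items_1d(a, b)
        Z = np.tile(Z_row, (n, 1))
        theta = sample_abilities(
            Z, items, np.full((n, 1), mu), np.array([[s2]]), np.zeros((n, 1)), rng
        )
        assert theta.mean() == pytest.approx(oracle_mean, abs=3e-3)
        assert theta.var() == pytest.approx(oracle_var, abs=3e-3)

    def test_formula_collapse_single_anchor(self):
        # one item with a=1, b=0.4: theta~ = Z + b
        rng = np.random.default_rng(3)
        items = _items_1d([1.0], [0.4])
        Z = np.array([[1.1]])
        # huge prior variance: posterior ~ N(theta~, 1)
        draws = np.array([
            sample_abilities(Z, items, np.zeros((1, 1)), np.array([[1e6]]),
                             np.zeros((1, 1)), rng)[0, 0]
            for _ in range(4000)
        ])
        assert draws.mean() == pytest.approx(1.1 + 0.4, abs=0.08)

    def test_degenerate_prior_pins_to_structural_mean(self):
        rng = np.random.default_rng(4)
        items = _items_1d([1.0], [0.0])
        theta = sample_abilities(
            np.array([[5.0]]), items, np.full((1, 1), -0.7),
            np.array([[1e-12]]), np.zeros((1, 1)), rng,
        )
        assert theta[0, 0] == pytest.approx(-0.7, abs=1e-4)

    def test_unloaded_dimension_rejected(self):
        rng = np.random.default_rng(5)
        items = ItemParameters(np.array([[1.0, 0.0]]), np.zeros(1), np.zeros(1, bool))
        with pytest.raises(ModelError, match="loadings"):
            sample_abilities(np.zeros((1, 1)), items, np.zeros((1, 2)),
                             np.eye(2), np.zeros((1, 2)), rng)


class TestItemStep:
    def test_anchors_never_move(self):
        rng = np.random.default_rng(6)
        theta = rng.normal(size=(200, 2))
        items = ItemParameters(rng.uniform(0.5, 2, (6, 2)), rng.normal(size=6))
        from mlmirt import apply_identification_constraints

        items = apply_identification_constraints(items, 2)
        Z = rng.normal(size=(200, 6))
        out = sample_item_parameters(Z, theta, items, PriorSpec(), rng)
        assert np.array_equal(out.discriminations[:2], np.eye(2))
        assert out.difficulties[0] == out.difficulties[1] == 0.0
        assert not np.array_equal(out.discriminations[2:], items.discriminations[2:])

    def test_tight_prior_collapses_to_prior_mean(self):
        rng = np.random.default_rng(7)
        theta = rng.normal(size=(50, 1))
        items = _items_1d([1.5, 2.0], [0.3, -0.2])
        Z = rng.normal(size=(50, 2))
        priors = PriorSpec(mu_a=1.2, var_a=1e-10, mu_b=-0.4, var_b=1e-10)
        out = sample_item_parameters(Z, theta, items, priors, rng)
        assert np.allclose(out.discriminations, 1.2, atol=1e-3)
        assert np.allclose(out.difficulties, -0.4, atol=1e-3)

    def test_positivity_truncation(self):
        rng = np.random.default_rng(8)
        theta = rng.normal(size=(20, 2))
        items = ItemParameters(np.full((5, 2), 0.1), np.zeros(5))
        Z = -np.abs(rng.normal(size=(20, 5)))  # data pulling loadings negative
        for _ in range(50):
            items = sample_item_parameters(Z, theta, items, PriorSpec(), rng)
            assert np.all(items.discriminations > 0)


def _one_school_layout(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.ones((n, 1))
    W = np.ones((1, 1))
    Y = rng.integers(0, 2, (n, 3))
    data = HierarchicalDataset(Y, np.zeros(n, dtype=int), X, W)
    spec = full_random_spec(1, 1, 1)
    return data, spec, _Ayout(data, spec), rng


def _Ayout(data, spec):
    return _Layout(data, spec)


class TestCoefficientSteps:
    def test_level2_matches_normal_normal_oracle(self):
        # 1 school, intercept-only: posterior N((n/s2 + 1/T)^-1 (sum/s2 + m/T), .)
        data, spec, lay, rng = _one_school_layout()
        theta = rng.normal(0.5, 1.0, size=(data.n_persons, 1))
        T = [np.array([[0.25]])]
        gamma = [np.array([0.2])]
        s2 = 0.5
        prec = data.n_persons / s2 + 1 / 0.25
        mean = (theta.sum() / s2 + 0.2 / 0.25) / prec
        draws = np.array([
            sample_level2_coefficients(
                theta, lay, np.zeros((1, 1, 1)), gamma, np.array([s2]), T,
                rng,
            )[0, 0, 0]
            for _ in range(5000)
        ])
        assert draws.mean() == pytest.approx(mean, abs=4 / np.sqrt(prec * 5000))
        assert draws.var() == pytest.approx(1 / prec, rel=0.1)

    def test_flat_level3_limit_recovers_ols(self):
        data, spec, lay, rng = _one_school_layout()
        theta = rng.normal(1.5, 0.3, size=(data.n_persons, 1))
        T = [np.array([[1e8]])]
        draws = np.array([
            sample_level2_coefficients(
                theta, lay, np.zeros((1, 1, 1)), [np.array([0.0])],
                np.array([0.5]), T, rng,
            )[0, 0, 0]
            for _ in range(2000)
        ])
        assert draws.mean() == pytest.approx(theta.mean(), abs=0.01)

    def test_fixed_effect_variance_scales_inverse_J(self):
        # identical unit school design: posterior variance = T / J
        def post_var(J, seed):
            rng = np.random.default_rng(seed)
            n = 5 * J
            data = HierarchicalDataset(
                np.zeros((n, 2), dtype=int),
                np.repeat(np.arange(J), 5),
                np.ones((n, 1)),
                np.ones((J, 1)),
            )
            spec = full_random_spec(1, 1, 1)
            lay = _Layout(data, spec)
            beta = rng.normal(size=(J, 1, 1))
            T = [np.array([[0.4]])]
            draws = np.array([
                sample_fixed_effects(lay, beta, [np.zeros(1)], T, PriorSpec(), rng)[0][0]
                for _ in range(4000)
            ])
            return draws.var()

        v4, v16 = post_var(4, 0), post_var(16, 1)
        assert v4 == pytest.approx(0.4 / 4, rel=0.15)
        assert v16 == pytest.approx(0.4 / 16, rel=0.15)

    def test_box_prior_respected(self):
        data, spec, lay, rng = _one_school_layout()
        beta = np.full((1, 1, 1), 5.0)  # pulls gamma far outside the box
        T = [np.array([[0.01]])]
        priors = PriorSpec(gamma_bound=2.0)
        for _ in range(50):
            g = sample_fixed_effects(lay, beta, [np.zeros(1)], T, priors, rng)
            assert abs(g[0][0]) <= 2.0


class TestCovarianceSteps:
    def test_level2_zero_residual_moments(self):
        rng = np.random.default_rng(9)
        n, Q = 200, 2
        theta = rng.normal(size=(n, Q))
        priors = PriorSpec(v0=4, Sigma0_scale=1.0)
        draws = np.stack([
            sample_level2_covariance(theta, theta.copy(), priors, rng)
            for _ in range(3000)
        ])
        # zero residuals: IW(v0+n, I) with mean I/(v0+n-Q-1)
        expected = np.eye(Q) / (4 + n - Q - 1)
        assert np.allclose(draws.mean(axis=0), expected, atol=3e-4)
        assert all(np.all(np.linalg.eigvalsh(d) > 0) for d in draws[:100])

    def test_scale_matrix_uses_hand_computed_S(self):
        # two persons with known residuals: S = sum of outer products
        theta = np.array([[1.0, 0.5], [-0.5, 1.0]])
        mu = np.zeros((2, 2))
        S = theta[0][:, None] @ theta[0][None] + theta[1][:, None] @ theta[1][None]
        priors = PriorSpec(v0=10, Sigma0_scale=1.0)
        rng = np.random.default_rng(10)
        draws = np.stack([
            sample_level2_covariance(theta, mu, priors, rng) for _ in range(20_000)
        ])
        expected = (S + np.eye(2)) / (10 + 2 - 2 - 1)
        assert np.allclose(draws.mean(axis=0), expected, atol=0.01)

    def test_level3_blocks_independent_and_spd(self):
        data, truth = simulation1_design(3, n_j=5)
        lay = _Layout(data, truth.spec)
        rng = np.random.default_rng(11)
        T = sample_level3_covariance(lay, truth.beta, truth.gamma, PriorSpec(), rng)
        assert len(T) == 2
        for t in T:
            assert t.shape == (2, 2)
            assert np.all(np.linalg.eigvalsh(t) > 0)

    def test_level3_zero_residual_matches_iw_moments(self):
        J = 12
        data = HierarchicalDataset(
            np.zeros((J, 2), dtype=int), np.arange(J), np.ones((J, 1)), np.ones((J, 1))
        )
        spec = full_random_spec(1, 1, 1)
        lay = _Layout(data, spec)
        beta = np.full((J, 1, 1), 0.7)
        gamma = [np.array([0.7])]  # w_j gamma = beta exactly -> S1 = 0
        priors = PriorSpec(v1=4, Sigma1_scale=1.0)
        rng = np.random.default_rng(12)
        draws = np.array([
            sample_level3_covariance(lay, beta, gamma, priors, rng)[0][0, 0]
            for _ in range(20_000)
        ])
        oracle = invwishart(df=4 + J, scale=1.0)
        assert draws.mean() == pytest.approx(oracle.mean(), rel=0.05)

    def test_improper_prior_needs_enough_schools(self):
        data, truth = simulation1_design(4, n_j=5, J=3)
        lay = _Layout(data, truth.spec)
        rng = np.random.default_rng(13)
        with pytest.raises(ModelError, match="J > r_q"):
            sample_level3_covariance(
                lay, truth.beta, truth.gamma, PriorSpec(improper_T=True), rng
            )


class TestConditionalVariances:
    def test_matches_schur_complement(self):
        S = np.array([[0.3, 0.075], [0.075, 0.5]])
        v = conditional_variances(S)
        assert v[0] == pytest.approx(0.3 - 0.075**2 / 0.5)
        assert v[1] == pytest.approx(0.5 - 0.075**2 / 0.3)


@pytest.fixture(scope="module")
def small_fit():
    data, truth = simulation1_design(17, n_j=15)
    cfg = ChainConfig(iterations=60, burn_in=20, seed=5,
                      store_augmented=True, z_thin=5)
    draws = run_chain(data, truth.spec, PriorSpec(), cfg)
    return data, truth, draws


class TestChainInvariants:
    def test_deterministic_given_seed(self):
        data, truth = simulation1_design(17, n_j=10)
        cfg = ChainConfig(iterations=25, burn_in=5, seed=42)
        d1 = run_chain(data, truth.spec, PriorSpec(), cfg)
        d2 = run_chain(data, truth.spec, PriorSpec(), cfg)
        assert np.array_equal(d1.gamma, d2.gamma)
        assert np.array_equal(d1.sigma_e, d2.sigma_e)
        d3 = run_chain(data, truth.spec, PriorSpec(),
                       ChainConfig(iterations=25, burn_in=5, seed=43))
        assert not np.array_equal(d1.gamma, d3.gamma)

    def test_anchor_immutability(self, small_fit):
        _, _, draws = small_fit
        assert np.all(draws.a[:, :, 0, :] == [1.0, 0.0])
        assert np.all(draws.a[:, :, 1, :] == [0.0, 1.0])
        assert np.all(draws.b[:, :, :2] == 0.0)
        assert np.all(draws.a[:, :, 2:, :] > 0)

    def test_augmented_sign_coherence(self, small_fit):
        data, _, draws = small_fit
        for snap in draws.snapshots:
            assert np.all(snap.Z[data.responses == 1] > 0)
            assert np.all(snap.Z[data.responses == 0] <= 0)

    def test_covariance_draws_spd(self, small_fit):
        _, _, draws = small_fit
        eigs = np.linalg.eigvalsh(draws.sigma_e.reshape(-1, 2, 2))
        assert np.all(eigs > 0)
        for Tq in draws.T:
            assert np.all(np.linalg.eigvalsh(Tq.reshape(-1, 2, 2)) > 0)

    def test_burn_in_validation(self):
        with pytest.raises(ModelError):
            ChainConfig(iterations=100, burn_in=100)
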