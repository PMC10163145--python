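import numpy as np
import pytest

from cpoe.core import compute_local_conditionals, posterior_state
from cpoe.model import CPoEModel
from cpoe.partition import build_graph
from cpoe.prediction import (aggregate, aggregation_weights, local_predict,
                             expert_predictions, posterior_subblock)
from cpoe.synthetic import make_two_se_benchmark, sample_inputs


@pytest.fixture(scope="module")
def fitted():
    ds = make_two_se_benchmark(N=150, D=2, seed=3)
    model = CPoEModel(ds.kernel, B=25, C=3, gamma=0.6, seed=0).fit(ds.X, ds.y)
    return ds, model


class TestPosteriorSubblock:
    def test_full_index_set_densifies_the_inverse(self, fitted):
        _, model = fitted
        post = model.post
        mu, Sigma = posterior_subblock(post, np.arange(post.M))
        np.testing.assert_allclose(mu, post.mu, atol=1e-12)
        dense = np.linalg.inv(post.Lambda.toarray())
        np.testing.assert_allclose(Sigma, dense, atol=1e-8)

    def test_symmetry(self, fitted):
        _, model = fitted
        idx = model.graph.block_indices(model.graph.psi[4])
        _, Sigma = posterior_subblock(model.post, idx)
        np.testing.assert_allclose(Sigma, Sigma.T, atol=1e-10)

    def test_independent_expert_block(self):
        """With C=1 the posterior block of expert j is (Q_j^-1 + T_jj)^-1."""
        ds = make_two_se_benchmark(N=100, D=2, seed=5)
        g = build_graph(ds.X, B=25, C=1, gamma=0.8, seed=0)
        conds = compute_local_conditionals(ds.kernel, g, ds.X)
        post = posterior_state(conds, g, ds.y, ds.kernel.noise_std)
        off = g.offsets
        for j in (0, 2):
            sl = slice(off[j], off[j + 1])
            _, Sigma = posterior_subblock(post, np.arange(off[j], off[j + 1]))
            T_jj = post.T.toarray()[sl, sl]
            expected = np.linalg.inv(np.linalg.inv(
                conds.Q[j] + 1e-12 * np.mean(np.diag(conds.Q[j]))
                * np.eye(g.L[j])) + T_jj)
            np.testing.assert_allclose(Sigma, expected, atol=1e-7)


class TestWeights:
    def test_single_expert(self):
        beta = aggregation_weights(np.array([1.0]), np.array([[0.3]]), N=50, C=2)
        np.testing.assert_allclose(beta, [[1.0]])

    def test_equal_variances_give_uniform_weights(self):
        beta = aggregation_weights(np.array([1.0]), np.full((1, 4), 0.2),
                                   N=100, C=2)
        np.testing.assert_allclose(beta, 0.25, atol=1e-12)

    def test_hand_computed_example(self):
        """v0=1, v=(1/4, 1/2) with exponent Z=1: beta = (2/3, 1/3)."""
        beta = aggregation_weights(np.array([1.0]), np.array([[0.25, 0.5]]),
                                   N=3, C=1, Z=1.0)
        np.testing.assert_allclose(beta, [[2.0 / 3.0, 1.0 / 3.0]], rtol=1e-12)

    def test_rows_sum_to_one_and_nonnegative(self, rng):
        v0 = rng.uniform(0.5, 2.0, size=30)
        v = rng.uniform(0.01, 3.0, size=(30, 5))
        beta = aggregation_weights(v0, v, N=500, C=3)
        assert np.all(beta >= 0)
        np.testing.assert_allclose(beta.sum(axis=1), 1.0, atol=1e-12)

    def test_uninformative_experts_fall_back_to_uniform(self):
        # posterior variances above the prior: all entropy differences clip
        beta = aggregation_weights(np.array([0.5]), np.array([[1.0, 2.0]]),
                                   N=100, C=2)
        np.testing.assert_allclose(beta, 0.5, atol=1e-12)


class TestAggregate:
    def test_identical_experts_fixed_point(self, rng):
        m = np.full((6, 3), 1.7)
        v = np.full((6, 3), 0.4)
        beta = rng.dirichlet(np.ones(3), size=6)
        mean, var = aggregate(m, v, beta)
        np.testing.assert_allclose(mean, 1.7, rtol=1e-12)
        np.testing.assert_allclose(var, 0.4, rtol=1e-12)

    def test_degenerate_weight_selects_one_expert(self):
        m = np.array([[1.0, 5.0]])
        v = np.array([[0.2, 0.9]])
        mean, var = aggregate(m, v, np.array([[1.0, 0.0]]))
        assert mean[0] == pytest.approx(1.0) and var[0] == pytest.approx(0.2)

    def test_precision_is_weighted_harmonic_mean(self, rng):
        m = rng.normal(size=(10, 4))
        v = rng.uniform(0.1, 2.0, size=(10, 4))
        beta = rng.dirichlet(np.ones(4), size=10)
        _, var = aggregate(m, v, beta)
        np.testing.assert_allclose(1.0 / var, np.sum(beta / v, axis=1),
                                   rtol=1e-12)

    def test_fused_variance_within_expert_range(self, rng):
        v = rng.uniform(0.05, 3.0, size=(50, 6))
        m = rng.normal(size=(50, 6))
        beta = rng.dirichlet(np.ones(6), size=50)
        _, var = aggregate(m, v, beta)
        assert np.all(var >= v.min(axis=1) - 1e-12)
        assert np.all(var <= v.max(axis=1) + 1e-12)


class TestLocalPredict:
    def test_no_data_recovers_projected_prior(self, fitted):
        """With y = 0 the local mean vanishes and the variance is the
        prior variance projected through the correlation region."""
        ds, model = fitted
        zero = CPoEModel(ds.kernel, B=25, C=3, gamma=0.6, seed=0)
        zero.fit(ds.X, np.zeros(ds.N))
        x = np.array([4.0, 4.0])
        m, v, v0 = local_predict(x, 3, zero.post, zero.conds, zero.graph,
                                 ds.kernel)
        assert abs(m) < 1e-10
        assert 0 < v <= v0 + 1e-8

    def test_posterior_contracts_projected_prior(self, fitted):
        ds, model = fitted
        Xq = sample_inputs(1000, 2, "uniform", (0, 10), seed=77)
        for j in (2, 4):
            _, v, v0 = expert_predictions(Xq, j, model.post, model.conds,
                                          model.graph, ds.kernel)
            assert np.all(v <= v0 + 1e-6)

    def test_matches_full_gp_at_inducing_input(self):
        """gamma=1, C=J: the fused prediction at a training input is exact."""
        from cpoe.baselines import FullGP
        ds = make_two_se_benchmark(N=100, D=2, seed=5)
        model = CPoEModel(ds.kernel, B=25, C=4, gamma=1.0, seed=0)
        model.fit(ds.X, ds.y)
        gp = FullGP(ds.kernel).fit(ds.X, ds.y)
        x = ds.X[17:18]
        mc, vc, _ = model.predict(x)
        mg, vg, _ = gp.predict(x)
        assert mc[0] == pytest.approx(mg[0], abs=1e-7)
        assert vc[0] == pytest.approx(vg[0], rel=1e-6, abs=1e-9)


class TestPredict:
    def test_shapes_and_noise_floor(self, fitted):
        ds, model = fitted
        Xq = sample_inputs(40, 2, "uniform", (0, 10), seed=8)
        mean, v, vn, detail = model.predict(Xq, return_detail=True)
        assert mean.shape == v.shape == vn.shape == (40,)
        np.testing.assert_allclose(vn - v, ds.kernel.noise_std ** 2,
                                   atol=1e-14)
        assert detail["beta"].shape[1] == model.graph.J - model.graph.C + 1
        np.testing.assert_allclose(detail["beta"].sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch(self, fitted):
        _, model = fitted
        with pytest.raises(ValueError):
            model.predict(np.zeros((3, 5)))
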