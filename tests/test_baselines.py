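import numpy as np
import pytest

from cpoe.baselines import FITC, FullGP, PoEBaseline, poe_predict
from cpoe.kernels import KernelSpec, SEard
from cpoe.model import CPoEModel
from cpoe.synthetic import make_two_se_benchmark, sample_inputs


@pytest.fixture(scope="module")
def se2d():
    return KernelSpec(terms=(SEard(lengthscales=np.array([1.0, 1.0]),
                                   variance=1.0),), noise_std=0.1, input_dim=2)


class TestFullGP:
    def test_two_point_closed_form(self, se1d):
        """N=2 posterior mean/variance match the scalar 2x2 algebra."""
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, -1.0])
        gp = FullGP(se1d).fit(X, y)
        s2 = se1d.noise_std ** 2
        k01 = np.exp(-0.5)
        Ky = np.array([[1 + s2, k01], [k01, 1 + s2]])
        xs = np.array([[0.25]])
        ks = np.array([np.exp(-0.5 * 0.25 ** 2), np.exp(-0.5 * 0.75 ** 2)])
        mean_expected = ks @ np.linalg.solve(Ky, y)
        var_expected = 1.0 - ks @ np.linalg.solve(Ky, ks)
        mean, var, _ = gp.predict(xs)
        assert mean[0] == pytest.approx(mean_expected, rel=1e-12)
        assert var[0] == pytest.approx(var_expected, rel=1e-12)
        # LML against the bivariate normal density
        quad = y @ np.linalg.solve(Ky, y)
        lml = -0.5 * (2 * np.log(2 * np.pi) + np.linalg.slogdet(Ky)[1] + quad)
        assert gp.lml == pytest.approx(lml, rel=1e-12)

    def test_near_interpolation_at_small_noise(self, rng):
        kern = KernelSpec(terms=(SEard(lengthscales=np.array([1.0]),
                                       variance=1.0),),
                          noise_std=1e-3, input_dim=1)
        X = np.linspace(0, 22, 12)[:, None]
        y = rng.normal(size=12)
        gp = FullGP(kern).fit(X, y)
        mean, var, _ = gp.predict(X)
        np.testing.assert_allclose(mean, y, atol=0.01)
        assert var.max() < 1e-4

    def test_lml_equals_chain_of_conditionals(self, se1d, rng):
        """Eq-style chain rule: the joint LML is the sum of one-point
        predictive log densities under the sequentially grown GP."""
        X = np.sort(rng.uniform(0, 8, 25))[:, None]
        _, y = __import__("cpoe").sample_gp(se1d, X, seed=4)
        gp = FullGP(se1d).fit(X, y)
        chain = 0.0
        s2 = se1d.noise_std ** 2
        for i in range(X.shape[0]):
            if i == 0:
                m, v = 0.0, se1d.diag(X[:1])[0] + s2
            else:
                sub = FullGP(se1d).fit(X[:i], y[:i])
                mi, vi, vni = sub.predict(X[i:i + 1])
                m, v = mi[0], vni[0]
            chain += -0.5 * (np.log(2 * np.pi * v) + (y[i] - m) ** 2 / v)
        assert gp.lml == pytest.approx(chain, rel=1e-9)

    def test_dense_guard(self, se1d, rng):
        X = rng.normal(size=(50, 1))
        with pytest.raises(ValueError):
            FullGP(se1d, guard=49).fit(X, np.zeros(50))


class TestFITC:
    def test_all_inputs_as_inducing_recovers_full_gp(self, se2d, rng):
        ds = make_two_se_benchmark(N=80, D=2, seed=9)
        fitc = FITC(ds.kernel, ds.X).fit(ds.X, ds.y)
        gp = FullGP(ds.kernel).fit(ds.X, ds.y)
        Xq = sample_inputs(30, 2, "uniform", (0, 10), seed=10)
        mf, vf, _ = fitc.predict(Xq)
        mg, vg, _ = gp.predict(Xq)
        np.testing.assert_allclose(mf, mg, atol=1e-6)
        np.testing.assert_allclose(vf, vg, atol=1e-6)
        assert fitc.lml == pytest.approx(gp.lml, rel=1e-8)

    def test_rank_one_hand_formula(self, se1d):
        """A single inducing point reduces FITC to scalar algebra."""
        X = np.array([[0.0], [2.0]])
        y = np.array([0.5, -0.2])
        A = np.array([[1.0]])
        fitc = FITC(se1d, A).fit(X, y)
        k_fa = np.exp(-0.5 * np.array([1.0, 1.0]))  # k(x_i, a), K_aa = 1
        q_ff = np.outer(k_fa, k_fa)
        g = 1.0 - k_fa ** 2 + se1d.noise_std ** 2
        Sy = q_ff + np.diag(g)
        xs = np.array([[0.5]])
        k_sa = np.exp(-0.5 * 0.25)
        q_sf = k_sa * k_fa
        mean_expected = q_sf @ np.linalg.solve(Sy, y)
        var_expected = 1.0 - q_sf @ np.linalg.solve(Sy, q_sf)
        mean, var, _ = fitc.predict(xs)
        assert mean[0] == pytest.approx(mean_expected, rel=1e-9)
        assert var[0] == pytest.approx(var_expected, rel=1e-9)

    def test_matches_cpoe_with_pooled_inducing_set(self):
        ds = make_two_se_benchmark(N=120, D=2, seed=13)
        model = CPoEModel(ds.kernel, B=30, C=4, gamma=0.5, seed=0)
        model.fit(ds.X, ds.y)
        A = ds.X[np.concatenate(model.graph.inducing_idx)]
        fitc = FITC(ds.kernel, A).fit(ds.X, ds.y)
        assert model.lml == pytest.approx(fitc.lml, rel=1e-8)
        Xq = sample_inputs(40, 2, "uniform", (0, 10), seed=14)
        mc, vc, _ = model.predict(Xq)
        mf, vf, _ = fitc.predict(Xq)
        np.testing.assert_allclose(mc, mf, atol=1e-7)
        np.testing.assert_allclose(vc, vf, rtol=1e-6, atol=1e-10)


class TestPoE:
    @pytest.mark.parametrize("mode", ["poe", "gpoe", "bcm", "minvar"])
    def test_single_expert_reduces_to_full_gp(self, mode):
        ds = make_two_se_benchmark(N=60, D=2, seed=2)
        poe = PoEBaseline(ds.kernel, partition=[np.arange(60)], mode=mode)
        poe.fit(ds.X, ds.y)
        gp = FullGP(ds.kernel).fit(ds.X, ds.y)
        Xq = sample_inputs(20, 2, "uniform", (0, 10), seed=3)
        mp, vp, _ = poe.predict(Xq)
        mg, vg, _ = gp.predict(Xq)
        np.testing.assert_allclose(mp, mg, atol=1e-8)
        np.testing.assert_allclose(vp, vg, atol=1e-8)

    def test_unknown_mode_rejected(self, se2d):
        with pytest.raises(ValueError):
            PoEBaseline(se2d, B=10, mode="median")

    def test_gpoe_with_unit_exponent_equals_cpoe_1_1(self):
        ds = make_two_se_benchmark(N=120, D=2, seed=13)
        model = CPoEModel(ds.kernel, B=30, C=1, gamma=1.0, seed=0, Z=1.0)
        model.fit(ds.X, ds.y)
        mp, vp, _ = poe_predict(ds.X, ds.y, ds.kernel,
                                sample_inputs(40, 2, "uniform", (0, 10), seed=4),
                                mode="gpoe",
                                partition=list(model.graph.partition), Z=1.0)
        mc, vc, _ = model.predict(
            sample_inputs(40, 2, "uniform", (0, 10), seed=4))
        np.testing.assert_allclose(mc, mp, atol=1e-7)
        np.testing.assert_allclose(vc, vp, rtol=1e-6)

    def test_minvar_jumps_where_cpoe_is_smooth(self):
        """On a 1-D grid the minimum-variance expert switches discontinuously
        while the covariance-intersection fusion stays continuous."""
        kern = KernelSpec(terms=(SEard(lengthscales=np.array([0.8]),
                                       variance=1.0),),
                          noise_std=0.1, input_dim=1)
        rng = np.random.default_rng(31)
        X = np.sort(rng.uniform(0, 12, 240))[:, None]
        from cpoe.synthetic import sample_gp
        _, y = sample_gp(kern, X, seed=32)
        grid = np.linspace(0.5, 11.5, 1200)[:, None]
        model = CPoEModel(kern, B=40, C=2, gamma=1.0, seed=0).fit(X, y)
        mc, _, _ = model.predict(grid)
        mv, _, _ = poe_predict(X, y, kern, grid, mode="minvar", B=40)
        jump_cpoe = np.max(np.abs(np.diff(mc)))
        jump_minvar = np.max(np.abs(np.diff(mv)))
        assert jump_cpoe < 0.2 * jump_minvar
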