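"""ADMM subproblems and full reconstruction behavior."""

import numpy as np
import pytest

import sidedmri as sd
from sidedmri.recon import ReconConfig, update_E, update_multipliers, update_U, update_V
from sidedmri.tv import TVWeights, tv_prox


@pytest.fixture(scope="module")
def small_setup():
    """A tiny consistent problem: 4x4x6 grid, 18 wavevectors."""
    table = sd.make_gradients(((1000.0, 9), (2000.0, 9)), seed=9)
    grid = sd.SpectrumGrid(((2.0e-3, 0.5e-3),), (1.5e-3,))
    dictionary = sd.build_dictionary(table, grid, sh_order=4)
    rng = np.random.default_rng(1)
    v0 = rng.standard_normal((dictionary.p_total, 4 * 4 * 6)) * 0.05
    e = sd.SignalMatrix(np.clip((dictionary.matrix_A @ v0).T, -1, 1.4), (4, 4, 6))
    return dictionary, e


class TestUpdateV:
    def test_recovers_generating_coefficients(self, small_setup, rng):
        table = sd.make_gradients(((1000.0, 30), (2000.0, 30)), seed=2)
        d = sd.build_dictionary(table, sd.SpectrumGrid(((2.0e-3, 0.5e-3),), ()),
                                sh_order=4)
        v0 = rng.standard_normal((d.p_total, 5))
        e = (d.matrix_A @ v0).T
        v = update_V(e, np.zeros((d.n_q, 5)), d, damping=0.0)
        assert np.linalg.norm(v - v0) / np.linalg.norm(v0) < 1e-8

    def test_zero_inputs_give_zero(self, small_setup):
        d, e = small_setup
        v = update_V(np.zeros_like(e.values), np.zeros((d.n_q, e.n_vox)), d, 0.0)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_local_optimality(self, small_setup, rng):
        d, e = small_setup
        phi = rng.standard_normal((d.n_q, e.n_vox)) * 0.01
        v = update_V(e.values, phi, d, damping=0.0)
        base = np.linalg.norm(e.values.T + phi - d.matrix_A @ v)
        for _ in range(100):
            cand = v + rng.standard_normal(v.shape) * 1e-3
            assert np.linalg.norm(e.values.T + phi - d.matrix_A @ cand) >= base - 1e-9


class TestUpdateU:
    def test_zero_lambda_passthrough(self, small_setup, rng):
        d, e = small_setup
        psi = rng.standard_normal(e.values.shape)
        cfg = ReconConfig(lambda_tv=0.0)
        np.testing.assert_array_equal(update_U(e.values, psi, e.dims, cfg),
                                      e.values - psi)

    def test_constant_volumes_unchanged(self):
        cfg = ReconConfig(lambda_tv=0.05)
        e = np.full((24, 3), 0.7)
        psi = np.zeros_like(e)
        np.testing.assert_allclose(update_U(e, psi, (2, 3, 4), cfg), e, atol=1e-10)

    def test_matches_direct_prox_call(self, small_setup, rng):
        d, e = small_setup
        psi = rng.standard_normal(e.values.shape) * 0.1
        cfg = ReconConfig(lambda_tv=0.02, rho1=0.5)
        out = update_U(e.values, psi, e.dims, cfg)
        target = (e.values - psi).T.reshape((-1,) + e.dims)
        direct = tv_prox(target, cfg.weights, cfg.lambda_tv / cfg.rho1,
                         cfg.tv_inner_iters, cfg.tv_tol)
        np.testing.assert_allclose(out, direct.reshape(e.n_q, -1).T, atol=1e-12)


class TestUpdateE:
    def test_data_term_dominates_in_rho_zero_limit(self, small_setup):
        d, e = small_setup
        scheme = sd.plan_side(sd.make_grouping(6, 3), 18, 2)
        obs = sd.acquire(e, scheme, 0.0)
        cfg = ReconConfig(rho1=1e-12, rho2=1e-12)
        out = update_E(obs, np.zeros_like(e.values), np.zeros_like(e.values),
                       np.zeros((18, e.n_vox)), np.zeros((18, e.n_vox)), cfg)
        np.testing.assert_allclose(out[obs.mask], obs.data[obs.mask], rtol=1e-9)

    def test_unacquired_entries_are_penalty_weighted_average(self, small_setup, rng):
        d, e = small_setup
        scheme = sd.plan_side(sd.make_grouping(6, 3), 18, 2)
        obs = sd.acquire(e, scheme, 0.0)
        u = rng.standard_normal(e.values.shape)
        psi = rng.standard_normal(e.values.shape)
        av = rng.standard_normal((18, e.n_vox))
        phi = rng.standard_normal((18, e.n_vox))
        cfg = ReconConfig(rho1=0.3, rho2=0.7)
        out = update_E(obs, u, psi, av, phi, cfg)
        expected = (0.3 * (u + psi) + 0.7 * (av - phi).T) / 1.0
        np.testing.assert_allclose(out[~obs.mask], expected[~obs.mask], rtol=1e-12)

    def test_zeroes_analytic_gradient(self, small_setup, rng):
        # the closed form must satisfy first-order optimality of the quadratic
        d, e = small_setup
        scheme = sd.plan_side(sd.make_grouping(6, 3), 18, 2)
        obs = sd.acquire(e, scheme, 0.0)
        for _ in range(5):
            u = rng.standard_normal(e.values.shape)
            psi = rng.standard_normal(e.values.shape)
            av = rng.standard_normal((18, e.n_vox))
            phi = rng.standard_normal((18, e.n_vox))
            cfg = ReconConfig(rho1=0.5, rho2=0.5)
            out = update_E(obs, u, psi, av, phi, cfg)
            grad = (obs.mask * (out - obs.data)
                    + cfg.rho1 * (out - u - psi)
                    + cfg.rho2 * (out - (av - phi).T))
            assert np.abs(grad).max() < 1e-10


class TestUpdateMultipliers:
    def test_feasible_point_leaves_multipliers_unchanged(self, rng):
        e = rng.standard_normal((10, 4))
        psi = rng.standard_normal((10, 4))
        phi = rng.standard_normal((4, 10))
        av = e.T.copy()
        psi2, phi2 = update_multipliers(psi, phi, e.copy(), e, av)
        np.testing.assert_array_equal(psi2, psi)
        np.testing.assert_array_equal(phi2, phi)

    def test_constant_gap_accumulates(self):
        e = np.zeros((6, 2))
        u = np.full((6, 2), 3.0)
        av = np.zeros((2, 6))
        psi, phi = update_multipliers(np.zeros((6, 2)), np.zeros((2, 6)), u, e, av)
        np.testing.assert_array_equal(psi, 3.0)
        psi, phi = update_multipliers(psi, phi, u, e, av)
        np.testing.assert_array_equal(psi, 6.0)


class TestReconstruct:
    def test_exact_recovery_fully_sampled_noiseless(self, small_setup):
        d, e = small_setup
        scheme = sd.plan_side(sd.make_grouping(6, 3), 18, 1)
        obs = sd.acquire(e, scheme, 0.0)
        cfg = ReconConfig(lambda_tv=0.0, max_iter=200, eps1=1e-12, eps2=1e-12)
        res = sd.reconstruct(obs, d, cfg)
        assert sd.nmse(res.signal, e) <= 1e-6

    def test_undersampled_beats_zero_fill(self, small_setup):
        d, e = small_setup
        scheme = sd.plan_side(sd.make_grouping(6, 3), 18, 2)
        obs = sd.acquire(e, scheme, noise_sigma=1 / 30, seed=8)
        res = sd.reconstruct(obs, d, ReconConfig(max_iter=40))
        assert sd.nmse(res.signal, e) < sd.nmse(sd.adjoint(obs), e)

    def test_history_and_stop_reason_recorded(self, small_setup):
        d, e = small_setup
        scheme = sd.plan_side(sd.make_grouping(6, 3), 18, 2)
        obs = sd.acquire(e, scheme, 0.0)
        res = sd.reconstruct(obs, d, ReconConfig(max_iter=5))
        assert res.n_iter == 5 and res.stop_reason == "max_iter"
        assert len(res.history["psi_change"]) == 5
        assert all(len(v) == 5 for v in res.history.values())

    def test_tolerance_stop_on_feasible_problem(self, small_setup):
        d, e = small_setup
        scheme = sd.plan_side(sd.make_grouping(6, 3), 18, 1)
        obs = sd.acquire(e, scheme, 0.0)
        cfg = ReconConfig(lambda_tv=0.0, max_iter=200, eps1=1e-10, eps2=1e-10)
        res = sd.reconstruct(obs, d, cfg)
        assert res.stop_reason == "tolerance"
        assert res.n_iter < 200

    def test_dimension_mismatch_rejected(self, small_setup, default_dictionary):
        d, e = small_setup
        scheme = sd.plan_side(sd.make_grouping(6, 3), 18, 1)
        obs = sd.acquire(e, scheme, 0.0)
        with pytest.raises(ValueError):
            sd.reconstruct(obs, default_dictionary)


class TestEstimatorInterface:
    def test_fit_sets_trailing_underscore_attributes(self, small_setup):
        d, e = small_setup
        scheme = sd.plan_side(sd.make_grouping(6, 3), 18, 2)
        obs = sd.acquire(e, scheme, 0.0)
        est = sd.SideReconstructor(d, max_iter=5).fit(obs)
        assert est.signal_.values.shape == e.values.shape
        assert est.coefficients_.shape == (d.p_total, e.n_vox)
        assert est.n_iter_ == 5

    def test_get_set_params_sklearn_contract(self, small_setup):
        d, _ = small_setup
        est = sd.SideReconstructor(d, lambda_tv=0.02)
        assert est.get_params()["lambda_tv"] == 0.02
        est.set_params(rho1=0.9, max_iter=7)
        cfg = est._config()
        assert cfg.rho1 == 0.9 and cfg.max_iter == 7

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(rho1=0.0)
        with pytest.raises(ValueError):
            ReconConfig(lambda_tv=-1.0)
        with pytest.raises(ValueError):
            ReconConfig(max_iter=0)
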