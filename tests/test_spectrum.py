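"""Response function, SH basis and spectrum-dictionary fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import sidedmri as sd
from sidedmri.spectrum import sh_basis_size


class TestResponse:
    def test_zero_b_is_unity(self):
        assert sd.response((0, 0, 1), 0.0, (1, 0, 0), 2.5e-3, 0.5e-3) == 1.0

    def test_isotropic_limit_angle_independent(self, rng):
        d = 1.7e-3
        vals = [
            sd.response(v / np.linalg.norm(v), 1000.0, (0, 0, 1), d, d)
            for v in rng.standard_normal((5, 3))
        ]
        np.testing.assert_allclose(vals, np.exp(-1000 * d), rtol=1e-12)

    def test_parallel_fiber_hand_value(self):
        # b=1000, D_L=2.5e-3, D_T=0.5e-3, q parallel v -> exp(-2.5)
        val = sd.response((1, 0, 0), 1000.0, (1, 0, 0), 2.5e-3, 0.5e-3)
        assert val == pytest.approx(np.exp(-2.5), rel=1e-12)
        assert val == pytest.approx(0.08208, abs=5e-6)

    def test_non_unit_vector_normalized_with_warning(self):
        with pytest.warns(UserWarning):
            val = sd.response((2, 0, 0), 1000.0, (1, 0, 0), 2.5e-3, 0.5e-3)
        assert val == pytest.approx(np.exp(-2.5), rel=1e-12)

    def test_rotation_covariance(self, rng):
        q = np.array([0.0, 1.0, 0.0])
        v = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        base = sd.response(q, 2000.0, v, 2.0e-3, 0.3e-3)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            rotated = sd.response(rot @ q, 2000.0, rot @ v, 2.0e-3, 0.3e-3)
            assert rotated == pytest.approx(base, rel=1e-10)


class TestShBasis:
    def test_order0_constant(self):
        tess = sd.hemisphere_tessellation()
        y = sd.sh_basis(tess, 0)
        assert y.shape == (len(tess), 1)
        np.testing.assert_allclose(y, 1 / np.sqrt(4 * np.pi), rtol=1e-12)

    def test_order8_has_45_functions(self):
        tess = sd.hemisphere_tessellation()
        assert sd.sh_basis(tess, 8).shape[1] == 45
        assert sh_basis_size(8) == 45

    def test_antipodal_symmetry(self, rng):
        v = rng.standard_normal((20, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        np.testing.assert_allclose(sd.sh_basis(v, 8), sd.sh_basis(-v, 8),
                                   atol=1e-12)

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError):
            sd.sh_basis(sd.hemisphere_tessellation(), 3)

    def test_orthonormal_under_quadrature(self):
        tess, w = sd.hemisphere_tessellation(return_weights=True)
        y = sd.sh_basis(tess, 8)
        gram = y.T @ (w[:, None] * y)
        np.testing.assert_allclose(gram, np.eye(45), atol=0.02)


class TestBuildDictionary:
    def test_zero_diffusivity_iso_column_is_ones(self, phantom_gradients):
        grid = sd.SpectrumGrid((), (0.0,))
        d = sd.build_dictionary(phantom_gradients, grid)
        np.testing.assert_allclose(d.matrix_A[:, 0], 1.0)

    def test_iso_column_square_law_across_shells(self):
        table = sd.GradientTable(
            [[1, 0, 0], [1, 0, 0]], [1000.0, 2000.0]
        )
        d = sd.build_dictionary(table, sd.SpectrumGrid((), (1.5e-3,)))
        col = d.matrix_A[:, 0]
        assert col[1] == pytest.approx(col[0] ** 2, rel=1e-12)

    def test_delta_fodf_reproduces_response(self, phantom_gradients):
        # fODF = antipodal delta at a tessellation point, via its SH projection
        tess, w = sd.hemisphere_tessellation(return_weights=True)
        grid = sd.SpectrumGrid(((2.0e-3, 0.5e-3),), ())
        d = sd.build_dictionary(phantom_gradients, grid, 8, tess, w)
        basis = sd.sh_basis(tess, 8)
        for idx in (0, 57, 200):
            beta = basis[idx]
            pred = d.matrix_A @ beta
            direct = np.array([
                sd.response(q, b, tess[idx], 2.0e-3, 0.5e-3)
                for q, b in zip(phantom_gradients.directions,
                                phantom_gradients.bvals)
            ])
            err = np.abs(pred - direct).max() / direct.max()
            assert err <= 0.02

    def test_synthesis_is_matrix_product(self, default_dictionary, rng):
        v = rng.standard_normal(default_dictionary.p_total)
        np.testing.assert_array_equal(default_dictionary.synthesize(v),
                                      default_dictionary.matrix_A @ v)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sd.SpectrumGrid((), ())

    def test_k1_grid_reduces_to_plain_spherical_deconvolution(self, phantom_gradients):
        # single (D_L, D_T) atom, no iso: A == R W Y of plain deconvolution
        tess, w = sd.hemisphere_tessellation(return_weights=True)
        grid = sd.SpectrumGrid(((1.7e-3, 0.4e-3),), ())
        d = sd.build_dictionary(phantom_gradients, grid, 8, tess, w)
        ct2 = (phantom_gradients.directions @ tess.T) ** 2
        r = np.exp(-phantom_gradients.bvals[:, None] * ((1.7e-3 - 0.4e-3) * ct2 + 0.4e-3))
        expected = r @ (w[:, None] * sd.sh_basis(tess, 8))
        np.testing.assert_allclose(d.matrix_A, expected, atol=1e-14)

    def test_save_load_roundtrip(self, default_dictionary, tmp_path):
        ap, sp = tmp_path / "dict.npz", tmp_path / "dict.json"
        default_dictionary.save(ap, sp)
        back = sd.SpectrumDictionary.load(ap, sp)
        np.testing.assert_array_equal(back.matrix_A, default_dictionary.matrix_A)
        assert back.sh_order == default_dictionary.sh_order


class TestGridValidation:
    def test_anisotropy_ratio_enforced(self):
        with pytest.raises(ValueError):
            sd.SpectrumGrid(((2.0e-3, 1.95e-3),), ())

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            sd.SpectrumGrid(((0.5e-3, 1.5e-3),), ())

    def test_default_grid_within_stated_ranges(self):
        grid = sd.default_grid()
        for d_l, d_t in grid.aniso_atoms:
            assert 1.5e-3 <= d_l <= 2.5e-3
            assert d_l / d_t >= 1.1 - 1e-12
        for d in grid.iso_atoms:
            assert 0.0 <= d <= 3.0e-3


class TestFitCoefficients:
    def test_exact_recovery_overdetermined(self, rng):
        table = sd.make_gradients(((1000.0, 30), (2000.0, 30)), seed=4)
        grid = sd.SpectrumGrid(((2.0e-3, 0.5e-3),), (1.5e-3,))
        d = sd.build_dictionary(table, grid, sh_order=4)  # P_total = 16 <= 60
        v0 = rng.standard_normal((d.p_total, 3))
        e = sd.SignalMatrix((d.matrix_A @ v0).T, (3, 1, 1))
        v = sd.fit_coefficients(e, d, damping=0.0)
        assert np.linalg.norm(v - v0) / np.linalg.norm(v0) < 1e-8

    def test_zero_signal_gives_zero_coefficients(self, phantom_gradients):
        grid = sd.SpectrumGrid(((2.0e-3, 0.5e-3),), (1.5e-3,))
        d = sd.build_dictionary(phantom_gradients, grid, sh_order=4)
        e = sd.SignalMatrix(np.zeros((4, d.n_q)), (2, 2, 1))
        v = sd.fit_coefficients(e, d, damping=0.0)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_fit_beats_random_candidates(self, phantom_gradients, rng):
        grid = sd.SpectrumGrid(((2.0e-3, 0.5e-3),), (1.5e-3,))
        d = sd.build_dictionary(phantom_gradients, grid, sh_order=4)
        e = rng.random((2, d.n_q))
        v = sd.fit_coefficients(sd.SignalMatrix(e, (2, 1, 1)), d, damping=0.0)
        best = np.linalg.norm(d.matrix_A @ v - e.T)
        for _ in range(100):
            cand = v + rng.standard_normal(v.shape) * 0.01
            assert np.linalg.norm(d.matrix_A @ cand - e.T) >= best - 1e-10

    def test_singular_normal_matrix_raises_with_hint(self, default_dictionary):
        e = sd.SignalMatrix(np.zeros((2, default_dictionary.n_q)), (2, 1, 1))
        with pytest.raises(np.linalg.LinAlgError, match="damping"):
            sd.fit_coefficients(e, default_dictionary, damping=0.0)

    def test_estimator_params_roundtrip(self, default_dictionary):
        est = sd.SpectrumFitter(default_dictionary, damping=0.1)
        params = est.get_params()
        assert params["damping"] == 0.1
        est.set_params(damping=0.2)
        assert est.damping == 0.2
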