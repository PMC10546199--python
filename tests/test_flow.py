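"""The K^2(Db, mu_a, mu_s') forward model, its LUT and the Db inversion."""

import numpy as np
import pytest

from qhi.constants import mua_from_concentrations
from qhi.flow import (PowerLawFit, build_k2_lut, extrapolate_musp,
                      fit_mus_powerlaw, invert_db, k2_forward,
                      mua_at_lsi_wavelength, percent_difference_map)
from qhi.lsi import BetaFactor
from qhi.optics import OpticalProperties, boundary_terms, g1_normalized, DynamicContext
from qhi.sfdi import fit_chromophores

# frozen from an independent log-space regression of the calibration-phantom
# scattering spectrum {1.07, 0.83, 0.72} at {660, 780, 850} nm
PHANTOM_POWERLAW = {"amp": 0.722332, "slope": -1.559675, "musp_633": 1.143929}


class TestK2Forward:
    op = OpticalProperties(0.02, 1.0, 633)

    def test_static_limit_is_beta(self):
        assert abs(np.sqrt(k2_forward(0.0, self.op, beta=1.0)) - 1.0) < 1e-9

    def test_static_limit_random_media(self, rng):
        for _ in range(20):
            op = OpticalProperties(rng.uniform(0.001, 0.3),
                                   rng.uniform(0.1, 3.0), 633)
            beta = rng.uniform(0.1, 1.0)
            exposure = rng.uniform(1e-3, 5e-2)
            k = np.sqrt(k2_forward(0.0, op, beta=beta, exposure=exposure))
            assert k == pytest.approx(np.sqrt(beta), rel=1e-9)

    @pytest.mark.parametrize("c", [0.5, 1.5, 3.0])
    def test_joint_optical_property_scale_invariance(self, c):
        base = k2_forward(1e-6, self.op)
        scaled = k2_forward(1e-6, OpticalProperties(0.02 * c, 1.0 * c, 633))
        assert abs(scaled - base) / base < 1e-9

    def test_beta_is_a_prefactor(self):
        full = k2_forward(1e-6, self.op, beta=1.0)
        half = k2_forward(1e-6, self.op, beta=0.5)
        assert half == pytest.approx(0.5 * full, rel=1e-12)

    def test_monotonicity_in_db_mua_musp(self):
        dbs = [1e-7, 5e-7, 1e-6, 5e-6]
        vals = [k2_forward(d, self.op) for d in dbs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        k_lo = k2_forward(1e-6, OpticalProperties(0.01, 1.0, 633))
        k_hi = k2_forward(1e-6, OpticalProperties(0.04, 1.0, 633))
        assert k_hi > k_lo  # more absorption -> higher contrast
        k_s = k2_forward(1e-6, OpticalProperties(0.01, 2.0, 633))
        assert k_s < k_lo  # more scattering -> lower contrast

    def test_phantom_ordering_matches_optical_property_relations(self):
        """Doubled mu_a raises K, doubled mu_s' lowers it, both leave it."""
        base = (0.019, 1.07)
        k1 = k2_forward(1e-6, OpticalProperties(*base, 660))
        k2_ = k2_forward(1e-6, OpticalProperties(2 * base[0], base[1], 660))
        k3 = k2_forward(1e-6, OpticalProperties(base[0], 2 * base[1], 660))
        k4 = k2_forward(1e-6, OpticalProperties(2 * base[0], 2 * base[1], 660))
        assert k2_ > k1 > k3
        assert k4 == pytest.approx(k1, rel=1e-9)

    def test_quadrature_matches_brute_force_trapezoid(self, rng):
        for _ in range(20):
            op = OpticalProperties(rng.uniform(0.005, 0.3),
                                   rng.uniform(0.2, 3.0), 633)
            db = rng.uniform(1e-8, 2e-5)
            exposure = 0.01
            # cubically graded grid resolves the fast initial decay
            tau = exposure * np.linspace(0.0, 1.0, 100_001) ** 3
            g1 = g1_normalized(op, DynamicContext(db=db, tau=tau,
                                                  wavelength_nm=633, n=1.4))
            integrand = g1**2 * (1 - tau / exposure)
            brute = 2.0 / exposure * np.trapezoid(integrand, tau)
            val = k2_forward(db, op)
            assert abs(val - brute) / brute < 1e-8

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            k2_forward(-1e-6, self.op)
        with pytest.raises(ValueError):
            k2_forward(1e-6, self.op, exposure=0.0)


class TestK2Lut:
    def test_standard_grid_shape_and_axes(self, k2_lut_default):
        assert k2_lut_default.k2_grid.shape == (256, 128, 128)
        assert k2_lut_default.db_axis[0] == 0.0
        assert k2_lut_default.db_axis[-1] == pytest.approx(20e-6)
        assert k2_lut_default.mua_axis[0] == 0.0001
        assert k2_lut_default.mua_axis[-1] == 0.3
        assert k2_lut_default.musp_axis[-1] == 3.0

    def test_static_slice_equals_beta(self, k2_lut_default):
        assert np.allclose(k2_lut_default.k2_grid[0], k2_lut_default.beta)

    def test_every_db_column_strictly_decreasing(self, k2_lut_default):
        assert np.all(np.diff(k2_lut_default.k2_grid, axis=0) < 0)

    def test_nodes_match_scalar_forward_model(self, k2_lut_coarse, rng):
        lut = k2_lut_coarse
        for _ in range(10):
            i = rng.integers(1, lut.db_axis.size)
            j = rng.integers(0, lut.mua_axis.size)
            k = rng.integers(0, lut.musp_axis.size)
            op = OpticalProperties(lut.mua_axis[j], lut.musp_axis[k], 633)
            direct = k2_forward(lut.db_axis[i], op, beta=lut.beta)
            assert lut.k2_grid[i, j, k] == pytest.approx(direct, rel=1e-9)

    def test_serialization_roundtrip(self, k2_lut_coarse, tmp_path):
        from qhi.flow import Lut3D
        p = tmp_path / "lut.npz"
        k2_lut_coarse.save(p)
        back = Lut3D.load(p)
        assert np.array_equal(back.k2_grid, k2_lut_coarse.k2_grid)
        assert back.beta == k2_lut_coarse.beta


class TestInvertDb:
    def test_forward_inverse_roundtrip(self, k2_lut_default, rng):
        lut = k2_lut_default
        for _ in range(50):
            mua = rng.uniform(0.005, 0.28)
            musp = rng.uniform(0.1, 2.9)
            db = rng.uniform(2e-7, 1.8e-5)
            op = OpticalProperties(mua, musp, 633)
            k = np.sqrt(k2_forward(db, op, beta=lut.beta))
            rec = invert_db(float(k), mua, musp, lut)
            assert rec == pytest.approx(db, rel=0.02)

    def test_static_contrast_maps_to_zero(self, k2_lut_coarse):
        assert invert_db(float(np.sqrt(k2_lut_coarse.beta)), 0.02, 1.0,
                         k2_lut_coarse) == 0.0

    def test_super_static_contrast_rejected(self, k2_lut_coarse):
        with pytest.raises(ValueError):
            invert_db(1.05 * float(np.sqrt(k2_lut_coarse.beta)), 0.02, 1.0,
                      k2_lut_coarse)

    def test_map_input_flags_instead_of_raising(self, k2_lut_coarse):
        lut = k2_lut_coarse
        good = np.sqrt(k2_forward(1e-6, OpticalProperties(0.02, 1.0, 633),
                                  beta=lut.beta))
        k = np.array([[good, 1.05 * np.sqrt(lut.beta)]])
        res = invert_db(k, 0.02, 1.0, lut)
        assert not res.invalid[0, 0] and res.invalid[0, 1]
        assert np.isnan(res.values[0, 1])

    def test_out_of_axis_properties_raise(self, k2_lut_coarse):
        with pytest.raises(ValueError):
            invert_db(0.3, 0.5, 1.0, k2_lut_coarse)  # mua beyond axis


class TestScatteringPowerLaw:
    def test_generator_roundtrip(self):
        amp, slope = 1.2, -1.3
        vals = {w: amp * (w / 850.0) ** slope for w in (660.0, 780.0, 850.0)}
        fit = fit_mus_powerlaw(vals)
        assert fit.amp == pytest.approx(amp, rel=1e-10)
        assert fit.slope == pytest.approx(slope, abs=1e-10)

    def test_flat_spectrum(self):
        fit = fit_mus_powerlaw({w: 0.9 for w in (660.0, 780.0, 850.0)})
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.amp == pytest.approx(0.9, rel=1e-12)

    def test_calibration_phantom_against_independent_regression(self):
        fit = fit_mus_powerlaw({660.0: 1.07, 780.0: 0.83, 850.0: 0.72})
        assert fit.amp == pytest.approx(PHANTOM_POWERLAW["amp"], abs=1e-5)
        assert fit.slope == pytest.approx(PHANTOM_POWERLAW["slope"], abs=1e-5)
        assert extrapolate_musp(fit, 633.0) == pytest.approx(
            PHANTOM_POWERLAW["musp_633"], abs=1e-5)

    def test_reference_wavelength_returns_amplitude(self):
        fit = PowerLawFit(amp=1.5, slope=-2.0)
        assert extrapolate_musp(fit, 850.0) == pytest.approx(1.5)
        assert extrapolate_musp(PowerLawFit(1.5, 0.0), 500.0) == 1.5

    def test_nonpositive_musp_rejected(self):
        with pytest.raises(ValueError):
            fit_mus_powerlaw({660.0: 1.0, 850.0: 0.0})

    def test_pixelwise_fit(self, rng):
        amp = rng.uniform(0.5, 2.0, (4, 4))
        slope = rng.uniform(-2.0, -0.5, (4, 4))
        vals = {w: amp * (w / 850.0) ** slope for w in (660.0, 780.0, 850.0)}
        fit = fit_mus_powerlaw(vals)
        assert np.allclose(fit.amp, amp, rtol=1e-9)
        assert np.allclose(extrapolate_musp(fit, 633.0),
                           amp * (633 / 850.0) ** slope, rtol=1e-9)


class TestMuaAtLsiWavelength:
    def test_zero_concentrations(self):
        chrom = fit_chromophores(
            {w: np.zeros((2, 2)) + 1e-12 for w in (660.0, 780.0, 850.0)})
        assert np.allclose(mua_at_lsi_wavelength(chrom), 0.0, atol=1e-10)

    def test_linearity_in_concentration(self):
        maps1 = {w: mua_from_concentrations(w, 50.0, 20.0) * np.ones((2, 2))
                 for w in (660.0, 780.0, 850.0)}
        maps2 = {w: 2 * m for w, m in maps1.items()}
        m1 = mua_at_lsi_wavelength(fit_chromophores(maps1))
        m2 = mua_at_lsi_wavelength(fit_chromophores(maps2))
        assert np.allclose(m2, 2 * m1, rtol=1e-10)

    def test_closed_loop_through_unmixing(self):
        c1, c2 = 70.0, 30.0
        maps = {w: mua_from_concentrations(w, c1, c2) * np.ones((3, 3))
                for w in (660.0, 780.0, 850.0)}
        mua633 = mua_at_lsi_wavelength(fit_chromophores(maps))
        assert np.allclose(mua633, mua_from_concentrations(633.0, c1, c2),
                           rtol=1e-10)


class TestPercentDifference:
    def test_proportional_maps_give_zero(self, rng):
        a = rng.uniform(1, 2, (9, 9))
        assert np.allclose(percent_difference_map(3.7 * a, a), 0.0, atol=1e-9)

    def test_ten_percent_excess(self):
        db = np.ones((3, 3))
        db[0, 0] = 1.1
        out = percent_difference_map(db, np.ones((3, 3)))
        assert out[0, 0] == pytest.approx(10.0)

    def test_formula_asymmetric(self, rng):
        a = rng.uniform(1, 2, (7, 7))
        b = rng.uniform(1, 2, (7, 7))
        assert not np.allclose(percent_difference_map(a, b),
                               -percent_difference_map(b, a))

    def test_zero_center_rejected(self):
        z = np.ones((3, 3))
        z[1, 1] = 0.0
        with pytest.raises(ValueError):
            percent_difference_map(z, np.ones((3, 3)))
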