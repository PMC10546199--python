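"""Synthetic frame generators: statistical and round-trip contracts."""

import numpy as np
import pytest
from scipy import stats

from qhi import constants
from qhi.acquisition import make_schedule
from qhi.flow import k2_forward
from qhi.optics import OpticalProperties, rd_forward
from qhi.sfdi import (PhaseTriplet, build_rd_lut, calibrate, demodulate,
                      demodulate_dc, invert_optical_properties)
from qhi.synthetic import (PhantomScene, SpeckleStackSpec, flow_tube_scene,
                           k2_integrated_discrete, phantom_library,
                           render_sfdi_frames, scene_from_chromophores,
                           simulate_speckle_stack, tau_c_for_k2,
                           tau_c_from_db, tau_c_map_for_scene)


def _homog_scene(mua=0.02, musp=1.1, shape=(24, 24)):
    return PhantomScene(
        name="t", shape=shape,
        mua={w: np.full(shape, mua) for w in (660.0, 780.0, 850.0)},
        musp={w: np.full(shape, musp) for w in (660.0, 780.0, 850.0)},
        db=np.zeros(shape))


class TestRenderSfdi:
    schedule = make_schedule(50.0)

    def test_planar_slots_are_phase_independent(self):
        frames = render_sfdi_frames(_homog_scene(), self.schedule, noise_sd=0)
        by_key = {}
        for slot, frame in frames:
            by_key.setdefault((slot.wavelength_nm, slot.fx), []).append(frame)
        for (wl, fx), imgs in by_key.items():
            if fx == 0.0:
                assert np.array_equal(imgs[0], imgs[1])
                assert np.array_equal(imgs[1], imgs[2])

    def test_illumination_scale_cancels_in_calibration(self):
        scene = _homog_scene()
        phantom_op = OpticalProperties(0.02, 1.1, 660)

        def mac_at(m0):
            frames = render_sfdi_frames(scene, self.schedule, m0=m0, noise_sd=0)
            trip = [(s, f) for s, f in frames
                    if s.wavelength_nm == 660.0 and s.fx == 0.3]
            trip = sorted(trip, key=lambda t: t[0].phase_deg)
            return demodulate(PhaseTriplet(trip[0][1], trip[1][1], trip[2][1],
                                           fx=0.3, wavelength_nm=660.0))

        m1, m2 = mac_at(30000.0), mac_at(60000.0)
        assert np.allclose(m2.mac, 2 * m1.mac, rtol=1e-12)
        rd1 = calibrate(m1, m1, phantom_op)
        rd2 = calibrate(m2, m2, phantom_op)
        assert np.allclose(rd1.rd, rd2.rd)

    def test_noise_free_closed_loop_recovers_scene_properties(self, rd_lut):
        mua_true, musp_true = 0.03, 1.4
        scene = _homog_scene(mua_true, musp_true)
        cal = _homog_scene(constants.CALIBRATION_PHANTOM_MUA[660.0],
                           constants.CALIBRATION_PHANTOM_MUSP[660.0])
        frames = {(s.wavelength_nm, s.fx, s.phase_deg): f
                  for s, f in render_sfdi_frames(scene, self.schedule, noise_sd=0)}
        cal_frames = {(s.wavelength_nm, s.fx, s.phase_deg): f
                      for s, f in render_sfdi_frames(cal, self.schedule, noise_sd=0)}
        phantom_op = OpticalProperties(
            constants.CALIBRATION_PHANTOM_MUA[660.0],
            constants.CALIBRATION_PHANTOM_MUSP[660.0], 660.0)

        def rd_of(fmap, fx, demod):
            trip = PhaseTriplet(fmap[(660.0, fx, 0.0)], fmap[(660.0, fx, 120.0)],
                                fmap[(660.0, fx, 240.0)], fx=fx,
                                wavelength_nm=660.0)
            return demod(trip)

        rd0 = calibrate(rd_of(frames, 0.0, demodulate_dc),
                        rd_of(cal_frames, 0.0, demodulate_dc), phantom_op)
        rd03 = calibrate(rd_of(frames, 0.3, demodulate),
                         rd_of(cal_frames, 0.3, demodulate), phantom_op)
        # renderer and calibration share the forward model: Rd is exact
        assert np.allclose(rd0.rd, rd_forward((scene.mua_map(660.0),
                                               scene.musp_map(660.0)), 0.0),
                           atol=1e-6)
        res = invert_optical_properties(rd0, rd03, rd_lut)
        assert np.nanmedian(res.mua) == pytest.approx(mua_true, rel=0.01)
        assert np.nanmedian(res.musp) == pytest.approx(musp_true, rel=0.01)


class TestSpeckleStack:
    def test_same_seed_bit_identical(self):
        spec = SpeckleStackSpec(shape=(32, 32), n_frames=3, tau_c=1e-3, seed=5)
        a = simulate_speckle_stack(spec)
        b = simulate_speckle_stack(spec)
        assert np.array_equal(a, b)

    def test_static_fully_sampled_unit_contrast(self):
        stack = simulate_speckle_stack(SpeckleStackSpec(
            shape=(200, 200), n_frames=1, tau_c=np.inf, oversample=1,
            substeps=1, bit_depth=None, seed=11))
        k = stack[0].std(ddof=1) / stack[0].mean()
        assert k == pytest.approx(1.0, abs=0.02)

    def test_static_intensity_is_exponential(self):
        stack = simulate_speckle_stack(SpeckleStackSpec(
            shape=(64, 64), n_frames=1, tau_c=np.inf, oversample=1,
            substeps=1, bit_depth=None, mean_counts=1.0, seed=13))
        sample = stack[0].ravel()
        _, p = stats.kstest(sample / sample.mean(), "expon")
        assert p > 0.01

    def test_decorrelation_reduces_contrast_monotonically(self):
        ks = []
        for tau_c in (np.inf, 2e-3, 4e-4, 8e-5):
            stack = simulate_speckle_stack(SpeckleStackSpec(
                shape=(128, 128), n_frames=1, tau_c=tau_c, oversample=1,
                substeps=24, bit_depth=None, seed=17))
            ks.append(stack[0].std(ddof=1) / stack[0].mean())
        assert ks[0] == pytest.approx(1.0, abs=0.03)
        assert all(a > b for a, b in zip(ks, ks[1:]))
        assert ks[-1] < 0.35

    def test_measured_contrast_matches_discrete_model(self):
        tau_c, T, M = 5e-4, 0.01, 32
        stack = simulate_speckle_stack(SpeckleStackSpec(
            shape=(256, 256), n_frames=1, tau_c=tau_c, oversample=1,
            substeps=M, bit_depth=None, seed=19))
        k2_meas = (stack[0].std(ddof=1) / stack[0].mean()) ** 2
        k2_model = k2_integrated_discrete(T / tau_c, M)
        assert k2_meas == pytest.approx(k2_model, rel=0.05)

    def test_oversampling_scales_beta(self):
        stack = simulate_speckle_stack(SpeckleStackSpec(
            shape=(200, 200), n_frames=1, tau_c=np.inf, oversample=2,
            substeps=1, bit_depth=None, seed=23))
        k2 = (stack[0].std(ddof=1) / stack[0].mean()) ** 2
        assert k2 == pytest.approx(0.25, abs=0.02)


class TestContrastTargeting:
    def test_discrete_model_limits(self):
        assert k2_integrated_discrete(1e-12, 32) == pytest.approx(1.0)
        # long-exposure limit approaches the temporal sampling floor 1/M
        assert k2_integrated_discrete(1e9, 32) == pytest.approx(1 / 32, rel=1e-6)
        # converges to the continuous exponential-decay expression
        x = 3.7
        cont = (np.exp(-2 * x) - 1 + 2 * x) / (2 * x**2)
        assert k2_integrated_discrete(x, 4096) == pytest.approx(cont, rel=1e-3)

    def test_tau_c_solver_roundtrip(self):
        for target in (0.9, 0.5, 0.12):
            tc = tau_c_for_k2(target, exposure=0.01, substeps=32)
            assert k2_integrated_discrete(0.01 / tc, 32) == \
                pytest.approx(target, rel=1e-9)

    def test_db_target_realizes_model_contrast(self):
        op = OpticalProperties(0.03, 1.2, 633)
        db = 1.5e-6
        tc = tau_c_from_db(db, op, substeps=32)
        target = k2_forward(db, op, beta=1.0)
        assert k2_integrated_discrete(0.01 / tc, 32) == \
            pytest.approx(target, rel=1e-9)


class TestSceneLibrary:
    def test_phantom_relations(self):
        lib = phantom_library()
        for w in (660.0, 780.0, 850.0):
            p1 = lib["phantom1"]
            assert np.allclose(lib["phantom2"].mua_map(w), 2 * p1.mua_map(w))
            assert np.allclose(lib["phantom2"].musp_map(w), p1.musp_map(w))
            assert np.allclose(lib["phantom3"].musp_map(w), 2 * p1.musp_map(w))
            assert np.allclose(lib["phantom3"].mua_map(w), p1.mua_map(w))
            assert np.allclose(lib["phantom4"].mua_map(w), 2 * p1.mua_map(w))
            assert np.allclose(lib["phantom4"].musp_map(w), 2 * p1.musp_map(w))

    def test_phantoms_within_lut_ranges(self):
        for scene in phantom_library().values():
            for w in (660.0, 780.0, 850.0):
                assert np.all((scene.mua_map(w) > 0.0001)
                              & (scene.mua_map(w) < 0.2))
                assert np.all((scene.musp_map(w) > 0.001)
                              & (scene.musp_map(w) < 3.0))

    def test_flow_tube_scene_geometry(self):
        scene = flow_tube_scene(shape=(64, 64), tube_radius_px=8, db_tube=2e-6)
        db = scene.db_map()
        assert db[32, 10] == 2e-6 and db[0, 10] == 0.0
        assert 633.0 in scene.mua and 633.0 in scene.musp
        tau = tau_c_map_for_scene(scene)
        assert np.isinf(tau[0, 0]) and np.isfinite(tau[32, 10])

    def test_chromophore_scene_consistent_with_extinction_table(self):
        scene = scene_from_chromophores(
            np.full((4, 4), 70.0), np.full((4, 4), 30.0),
            musp_amp=1.0, musp_slope=-1.3, db=1e-6)
        for w in (633.0, 660.0, 780.0, 850.0):
            assert np.allclose(
                scene.mua_map(w),
                constants.mua_from_concentrations(w, 70.0, 30.0))
            assert np.allclose(scene.musp_map(w), (w / 850.0) ** -1.3)
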