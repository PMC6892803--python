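"""Sub-pixel localization: fits, precision law, calibration, repeatability."""

import numpy as np
import pytest

import thermoloc as tl
from thermoloc.localize import fit_peak_single, fit_peak_two_step
from thermoloc.scenes import ParameterError

A_PX = 400.0


def _gauss_frame(xc, yc, amp=2.0, zeta2=9e4, offset=20.0, shape=(12, 16)):
    rows, cols = np.arange(shape[0]), np.arange(shape[1])
    X, Y = np.meshgrid((cols + 0.5) * A_PX, (rows + 0.5) * A_PX)
    return offset + amp * np.exp(-((X - xc) ** 2 + (Y - yc) ** 2) / (2 * zeta2))


class TestTwoStepFit:
    def test_exact_recovery_on_clean_gaussian(self):
        xc, yc = 6.37 * A_PX, 5.81 * A_PX   # off pixel centre
        frame = _gauss_frame(xc, yc)
        loc = fit_peak_two_step(frame, 6, 5, A_PX, (0.0, 0.0), zeta0_sq=9e4,
                                baseline=20.0)
        assert abs(loc.x_c - xc) < 1e-3 * A_PX
        assert abs(loc.y_c - yc) < 1e-3 * A_PX
        assert loc.dT_max == pytest.approx(2.0, abs=1e-3)
        assert loc.zeta2 == pytest.approx(9e4, rel=1e-3)

    def test_unbiased_under_photon_noise(self, single_pulse, small_camera,
                                         ink_sample):
        from thermoloc.forward import photons_per_kelvin

        stack, ev, frame = single_pulse
        dTf = frame - ink_sample.T0
        row, col = np.unravel_index(np.argmax(dTf), dTf.shape)
        z0 = fit_peak_single(frame, int(col), int(row), stack.a, stack.origin,
                             "symmetric",
                             tl.default_zeta0_sq(tl.beam_22um(), ink_sample,
                                                 small_camera, 0.3),
                             baseline=ink_sample.T0).zeta2
        clean = fit_peak_two_step(frame, int(col), int(row), stack.a,
                                  stack.origin, z0, baseline=ink_sample.T0)
        k = photons_per_kelvin(small_camera, ink_sample)
        rng = np.random.default_rng(123)
        xs, ys = [], []
        for _ in range(200):
            noisy = ink_sample.T0 + (rng.poisson(
                small_camera.b + k * np.clip(dTf, 0, None))
                - small_camera.b) / k
            loc = fit_peak_two_step(noisy, int(col), int(row), stack.a,
                                    stack.origin, z0, baseline=ink_sample.T0)
            xs.append(loc.x_c)
            ys.append(loc.y_c)
        for vals, truth in ((xs, clean.x_c), (ys, clean.y_c)):
            bias = abs(np.mean(vals) - truth)
            assert bias < 3 * np.std(vals, ddof=1) / np.sqrt(200)

    def test_center_scatter_shrinks_with_amplitude(self):
        rng = np.random.default_rng(0)
        stds = []
        for amp in (1.0, 2.0):
            centers = []
            for _ in range(80):
                frame = _gauss_frame(6.37 * A_PX, 5.81 * A_PX, amp=amp)
                frame += rng.normal(0, 0.1, frame.shape)
                loc = fit_peak_two_step(frame, 6, 5, A_PX, (0.0, 0.0),
                                        zeta0_sq=9e4, baseline=20.0)
                centers.append(loc.x_c)
            stds.append(np.std(centers, ddof=1))
        assert stds[1] < stds[0]

    def test_small_roi_rejected(self):
        frame = _gauss_frame(6.5 * A_PX, 5.5 * A_PX)
        with pytest.raises(tl.FitError):
            fit_peak_two_step(frame, 0, 0, A_PX, (0.0, 0.0), zeta0_sq=9e4,
                              baseline=20.0, roi_half=5)


class TestSingleStepFits:
    def test_asymmetric_recovers_symmetric_variances(self):
        frame = _gauss_frame(6.2 * A_PX, 5.7 * A_PX)
        loc = fit_peak_single(frame, 6, 5, A_PX, (0.0, 0.0), "asymmetric",
                              zeta0_sq=9e4, baseline=20.0)
        assert loc.zeta2 == pytest.approx(9e4, rel=1e-3)

    def test_skewed_nests_symmetric_at_zero_skew(self):
        frame = _gauss_frame(6.2 * A_PX, 5.7 * A_PX)
        sym = fit_peak_single(frame, 6, 5, A_PX, (0.0, 0.0), "symmetric",
                              zeta0_sq=9e4, baseline=20.0)
        skw = fit_peak_single(frame, 6, 5, A_PX, (0.0, 0.0), "skewed",
                              zeta0_sq=9e4, baseline=20.0)
        assert skw.chi2red <= sym.chi2red + 1e-8

    def test_unknown_model_rejected(self):
        frame = _gauss_frame(6.2 * A_PX, 5.7 * A_PX)
        with pytest.raises(ParameterError):
            fit_peak_single(frame, 6, 5, A_PX, (0.0, 0.0), "lorentzian",
                            zeta0_sq=9e4)


class TestPrecisionLaw:
    def test_background_free_value(self):
        assert tl.predict_sigma(300, 400, 0, 100) == pytest.approx(32.15,
                                                                   abs=0.01)

    def test_with_background_value(self):
        assert tl.predict_sigma(300, 400, 5, 100) == pytest.approx(47.2,
                                                                   abs=0.1)

    def test_limits_and_monotonicity(self):
        assert tl.predict_sigma(300, 400, 5, 1e12) < 1e-3
        s = [tl.predict_sigma(300, 400, 5, n) for n in (50, 100, 200, 400)]
        assert all(a > b for a, b in zip(s, s[1:]))
        b_up = [tl.predict_sigma(300, 400, b, 100) for b in (0, 2, 5, 10)]
        assert all(a < b for a, b in zip(b_up, b_up[1:]))

    def test_zero_photons_rejected(self):
        with pytest.raises(ParameterError):
            tl.predict_sigma(300, 400, 5, 0)

    def test_sigma_vs_deltaT_published_calibration(self):
        assert tl.sigma_vs_deltaT(599, 634, 0.9) == pytest.approx(38.1,
                                                                  abs=0.1)
        assert tl.sigma_vs_deltaT(599, 634, 1.0) == pytest.approx(
            np.sqrt(1233), abs=0.01)
        assert tl.sigma_vs_deltaT(599, 634, 1e9) < 1e-3
        with pytest.raises(ParameterError):
            tl.sigma_vs_deltaT(599, 634, 0.0)

    def test_extrapolation_lands_in_30_50_micron_band(self):
        # amplitudes of the letter-pattern data set; at 0.6 C the curve sits
        # just above the quoted band (52.5 um), within its ~uncertainty
        for dT in (0.7, 0.8, 0.9):
            assert 30 <= tl.sigma_vs_deltaT(599, 634, dT) <= 50
        assert tl.sigma_vs_deltaT(599, 634, 0.6) == pytest.approx(50, rel=0.08)


class TestCalibrateAlphaBeta:
    def test_exact_recovery_noise_free(self):
        dts = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        sig = tl.sigma_vs_deltaT(599, 634, dts)
        um = tl.calibrate_alpha_beta(list(zip(dts, sig)))
        assert um.alpha == pytest.approx(599, rel=1e-6)
        assert um.beta == pytest.approx(634, rel=1e-6)

    def test_recovery_with_noise_within_three_se(self):
        rng = np.random.default_rng(4)
        dts = np.array([0.5, 0.8, 1.2, 2.0, 3.0, 4.0])
        sig = tl.sigma_vs_deltaT(599, 634, dts) * (1 + 0.05 * rng.normal(size=6))
        um = tl.calibrate_alpha_beta(list(zip(dts, sig)))
        assert abs(um.alpha - 599) < 3 * max(um.alpha_se, 1e-6) + 1e-6 \
            or um.alpha == pytest.approx(599, rel=0.3)

    def test_zero_beta_not_spuriously_detected(self):
        dts = np.array([0.5, 1.0, 2.0, 4.0])
        sig = np.sqrt(599 / dts)
        um = tl.calibrate_alpha_beta(list(zip(dts, sig)))
        assert um.beta <= 2 * um.beta_se + 1e-9

    def test_degenerate_design_rejected(self):
        with pytest.raises(ParameterError):
            tl.calibrate_alpha_beta([(1.0, 30), (1.0, 31), (1.0, 29),
                                     (1.0, 30)])
        with pytest.raises(ParameterError):
            tl.calibrate_alpha_beta([(1.0, 30), (2.0, 20)])


class TestRepeatability:
    def test_noise_free_scatter_is_zero(self, uniform_square, ink_sample,
                                        beam22, small_camera):
        res = tl.run_repeatability(uniform_square, ink_sample, beam22,
                                   small_camera, (2000.0, 2000.0),
                                   n_pulses=3, tau_on=0.3, seed=1,
                                   noise_mode="none")
        sx, sy = res.sigma_xy["symmetric_two_step"]
        assert sx < 1e-6 and sy < 1e-6

    def test_overlapping_pulses_rejected(self, uniform_square, ink_sample,
                                         beam22, small_camera):
        with pytest.raises(ParameterError):
            tl.run_repeatability(uniform_square, ink_sample, beam22,
                                 small_camera, (2000.0, 2000.0), n_pulses=10,
                                 tau_on=0.3, seed=1, spacing=0.1)

    def test_fitted_center_tracks_absorber_centroid_at_stripe_edge(self):
        # beam on the edge of a 30 um stripe (56 um spot): the fitted centre
        # shifts toward the absorbing side by the beam-intensity-weighted
        # absorber centroid (numerical oracle)
        amap = tl.make_stripe_grid(30, 120, 1, 5, margin=1000, height=2000)
        beam = tl.beam_56um()
        sample = tl.SampleModel(emissivity=0.8, D=1.0e5, T0=20.0, A=3e4,
                                tau_d=0.2)
        camera = tl.CameraModel(format=(16, 12))
        x0, y0 = 1000.0, 1000.0   # left stripe edge; absorber to the right
        ev = [tl.IlluminationEvent(0, 0, x0, y0, 0.0, 0.3)]
        st = tl.render_stack(amap, sample, beam, ev, camera, duration=0.35,
                             noise_mode="none")
        frame = st.frames[9]
        row, col = np.unravel_index(np.argmax(frame), frame.shape)
        z0 = fit_peak_single(frame, int(col), int(row), st.a, st.origin,
                             "symmetric",
                             tl.default_zeta0_sq(beam, sample, camera, 0.3),
                             baseline=20.0).zeta2
        loc = fit_peak_two_step(frame, int(col), int(row), st.a, st.origin,
                                z0, baseline=20.0, camera=camera,
                                sample=sample)
        # oracle: centroid of map * beam intensity
        h = 0.5
        g = np.arange(-84, 84, h) + h / 2
        X, Y = np.meshgrid(x0 + g, y0 + g)
        W = amap.absorptance_at(X, Y) * beam.intensity(X - x0, Y - y0)
        cx = float((W * X).sum() / W.sum())
        shift = cx - x0
        assert shift > 5.0                      # a real, resolvable shift
        assert loc.x_c - x0 == pytest.approx(shift, abs=1.5)
        assert abs(loc.y_c - y0) < 1.0

    def test_skewed_fit_not_better_than_two_step_on_partial_coverage(self):
        # 30 um stripe under the 56 um spot: symmetric two-step beats the
        # skewed surface in centre repeatability
        amap = tl.make_stripe_grid(30, 120, 1, 5, margin=1000, height=2000)
        beam = tl.beam_56um()
        sample = tl.SampleModel(emissivity=0.8, D=1.0e5, T0=20.0, A=6e4,
                                tau_d=0.2)
        camera = tl.CameraModel(format=(16, 12))
        res = tl.run_repeatability(amap, sample, beam, camera,
                                   (1015.0, 1000.0), n_pulses=60, tau_on=0.3,
                                   seed=9,
                                   models=("symmetric_two_step", "skewed"),
                                   noise_mode="netd")
        two = np.mean(res.sigma_xy["symmetric_two_step"])
        skw = np.mean(res.sigma_xy["skewed"])
        assert two <= skw
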