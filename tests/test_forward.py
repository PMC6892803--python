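"""Forward model: gray-body law, heat kernel closed forms, camera rendering."""

import numpy as np
import pytest
from scipy import ndimage, optimize

import thermoloc as tl
from thermoloc.forward import photons_per_kelvin
from thermoloc.scenes import ParameterError


class TestRadiance:
    def test_blackbody_at_293K(self):
        assert tl.radiance(19.85, 1.0) == pytest.approx(417.9, abs=0.05)

    def test_gray_body_at_310K(self):
        assert tl.radiance(36.85, 0.95) == pytest.approx(497.5, abs=0.1)

    def test_zero_emissivity(self):
        assert tl.radiance(100.0, 0.0) == 0.0

    def test_below_absolute_zero_rejected(self):
        with pytest.raises(ParameterError):
            tl.radiance(-300.0, 0.5)


class TestLinearizationError:
    def test_one_percent_at_2K(self):
        assert tl.photon_linearization_error(293, 2) == pytest.approx(0.0102,
                                                                      abs=5e-4)

    def test_within_five_percent_at_10K(self):
        err = tl.photon_linearization_error(293, 10)
        assert 0.04 < err <= 0.05

    def test_vanishes_for_small_increment(self):
        assert tl.photon_linearization_error(293, 1e-6) == pytest.approx(
            0.0, abs=1e-5)


class TestTemperatureField:
    def test_zero_absorptance_gives_zero(self, ink_sample, beam22):
        empty = tl.AbsorberMap(values=np.zeros((40, 40)), pitch=10.0)
        ev = [tl.IlluminationEvent(0, 0, 200.0, 200.0, 0.0, 0.3)]
        dt = tl.temperature_field(empty, ink_sample, beam22, ev,
                                  200.0, 200.0, 0.3)
        assert dt == 0.0

    def test_query_before_event_is_zero(self, uniform_square, ink_sample,
                                        beam22):
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 5.0, 0.3)]
        dt = tl.temperature_field(uniform_square, ink_sample, beam22, ev,
                                  2000.0, 2000.0, 1.0)
        assert dt == 0.0

    def test_no_diffusion_no_loss_linear_rise(self, uniform_square, beam22):
        s = tl.SampleModel(D=0.0, A=10.0, tau_d=1e9, T0=20.0)
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, 0.3)]
        for tau in (0.1, 0.2, 0.3):
            dt = tl.temperature_field(uniform_square, s, beam22, ev,
                                      2000.0, 2000.0, tau)
            assert dt == pytest.approx(10.0 * tau, rel=1e-5)

    def test_no_diffusion_profile_is_beam_gaussian(self, uniform_square,
                                                   beam22):
        # spatial 1/e^2 diameter equals the beam's
        s = tl.SampleModel(D=0.0, A=10.0, tau_d=1e9, T0=20.0)
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, 0.3)]
        r = np.array([0.0, beam22.w0 / 2, beam22.w0])
        dt = tl.temperature_field(uniform_square, s, beam22, ev,
                                  2000.0 + r, 2000.0, 0.3)
        ratio = dt / dt[0]
        assert ratio == pytest.approx(np.exp(-2 * r ** 2 / beam22.w0 ** 2),
                                      rel=1e-6)

    def test_no_diffusion_exponential_rise_and_decay(self, uniform_square,
                                                     beam22):
        s = tl.SampleModel(D=0.0, A=10.0, tau_d=0.15, T0=20.0)
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, 0.3)]
        rise = tl.temperature_field(uniform_square, s, beam22, ev,
                                    2000.0, 2000.0, 0.3)
        assert rise == pytest.approx(10 * 0.15 * (1 - np.exp(-2)), rel=1e-4)
        decay = tl.temperature_field(uniform_square, s, beam22, ev,
                                     2000.0, 2000.0, 0.45)
        assert decay == pytest.approx(rise * np.exp(-1.0), rel=1e-4)

    def test_diffusive_center_matches_analytic_integral(self, uniform_square,
                                                        beam22):
        from scipy.integrate import quad

        s = tl.SampleModel(D=1.4e5, A=6e4, tau_d=0.2, T0=20.0)
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, 0.3)]
        got = tl.temperature_field(uniform_square, s, beam22, ev,
                                   2000.0, 2000.0, 0.3)
        w0 = beam22.w0
        ref, _ = quad(lambda u: 6e4 * w0 ** 2 / (w0 ** 2 + 8 * 1.4e5 * u)
                      * np.exp(-u / 0.2), 0, 0.3, limit=200)
        assert got == pytest.approx(ref, rel=0.01)

    def test_linear_in_amplitude(self, uniform_square, beam22):
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, 0.3)]
        s1 = tl.SampleModel(D=1e5, A=1e4, tau_d=0.2)
        s2 = tl.SampleModel(D=1e5, A=2e4, tau_d=0.2)
        x = np.array([1900.0, 2000.0, 2100.0])
        d1 = tl.temperature_field(uniform_square, s1, beam22, ev, x, 2000.0, 0.3)
        d2 = tl.temperature_field(uniform_square, s2, beam22, ev, x, 2000.0, 0.3)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_short_pulse_doubling_doubles_amplitude(self, uniform_square,
                                                    beam22):
        # tau_on far below the loss time: amplitude ~ linear in tau_on
        s = tl.SampleModel(D=0.0, A=100.0, tau_d=0.5)
        d = []
        for tau in (0.01, 0.02):
            ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, tau)]
            d.append(tl.temperature_field(uniform_square, s, beam22, ev,
                                          2000.0, 2000.0, tau))
        assert d[1] / d[0] == pytest.approx(2.0, rel=0.05)

    def test_monotone_rise_then_decay(self, uniform_square, ink_sample,
                                      beam22):
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, 0.3)]
        t_rise = np.linspace(0.02, 0.3, 6)
        t_decay = np.linspace(0.3, 1.0, 6)
        for x in (2000.0, 2100.0):
            r = tl.temperature_field(uniform_square, ink_sample, beam22, ev,
                                     x, 2000.0, t_rise)
            d = tl.temperature_field(uniform_square, ink_sample, beam22, ev,
                                     x, 2000.0, t_decay)
            assert np.all(np.diff(np.ravel(r)) > 0)
            assert np.all(np.diff(np.ravel(d)) < 0)

    def test_low_diffusion_frame_is_nearly_gaussian(self, uniform_square,
                                                    beam22):
        # 8*D*tau_on = w0^2: symmetric-Gaussian fit residuals below 2%
        # of the peak in the RMS sense (a narrow central cusp from the
        # youngest heat carries a larger pointwise deviation)
        w0 = beam22.w0
        D = w0 ** 2 / (8 * 0.3)
        s = tl.SampleModel(D=D, A=100.0, tau_d=0.2)
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, 0.3)]
        g = np.linspace(-40, 40, 81)
        X, Y = np.meshgrid(2000.0 + g, 2000.0 + g)
        field = tl.temperature_field(uniform_square, s, beam22, ev, X, Y, 0.3)

        def gauss(xy, amp, z2, off):
            return off + amp * np.exp(-(xy[0] ** 2 + xy[1] ** 2) / (2 * z2))

        popt, _ = optimize.curve_fit(gauss, (X.ravel() - 2000, Y.ravel() - 2000),
                                     field.ravel(),
                                     p0=(field.max(), w0 ** 2 / 4, 0.0),
                                     maxfev=5000)
        resid = field.ravel() - gauss((X.ravel() - 2000, Y.ravel() - 2000),
                                      *popt)
        assert np.sqrt((resid ** 2).mean()) / field.max() < 0.02


class TestRenderStack:
    def test_zero_absorptance_clean_frames_are_baseline(self, ink_sample,
                                                        beam22, small_camera):
        empty = tl.AbsorberMap(values=np.zeros((40, 40)), pitch=10.0)
        ev = [tl.IlluminationEvent(0, 0, 200.0, 200.0, 0.0, 0.3)]
        st = tl.render_stack(empty, ink_sample, beam22, ev, small_camera,
                             noise_mode="none")
        assert np.all(st.frames == ink_sample.T0)

    def test_netd_noise_std_matches_sensitivity(self, ink_sample, beam22,
                                                small_camera):
        empty = tl.AbsorberMap(values=np.zeros((40, 40)), pitch=10.0)
        st = tl.render_stack(empty, ink_sample, beam22, [], small_camera,
                             duration=20.0, noise_mode="netd", seed=5)
        assert st.n_frames >= 500
        per_pixel_std = st.frames.std(axis=0)
        assert np.mean(per_pixel_std) == pytest.approx(small_camera.NETD,
                                                       rel=0.1)

    def test_single_event_peak_pixel_location(self, uniform_square,
                                              ink_sample, beam22,
                                              small_camera):
        ev = [tl.IlluminationEvent(0, 0, 1731.0, 2248.0, 0.0, 0.3)]
        st = tl.render_stack(uniform_square, ink_sample, beam22, ev,
                             small_camera, noise_mode="none")
        k = int(round(0.3 * small_camera.f_rate))
        row, col = np.unravel_index(np.argmax(st.frames[k]),
                                    st.frames[k].shape)
        exp_col = int((1731.0 - st.origin[0]) // st.a)
        exp_row = int((2248.0 - st.origin[1]) // st.a)
        assert (col, row) == (exp_col, exp_row)

    def test_seed_determinism_bit_identical(self, uniform_square, ink_sample,
                                            beam22, small_camera):
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, 0.3)]
        a = tl.render_stack(uniform_square, ink_sample, beam22, ev,
                            small_camera, noise_mode="photon", seed=11)
        b = tl.render_stack(uniform_square, ink_sample, beam22, ev,
                            small_camera, noise_mode="photon", seed=11)
        assert np.array_equal(a.frames, b.frames)

    def test_noise_requires_seed(self, uniform_square, ink_sample, beam22,
                                 small_camera):
        with pytest.raises(ParameterError):
            tl.render_stack(uniform_square, ink_sample, beam22, [],
                            small_camera, duration=1.0, noise_mode="netd")

    def test_short_duration_warns_and_truncates(self, uniform_square,
                                                ink_sample, beam22,
                                                small_camera):
        ev = [tl.IlluminationEvent(0, 0, 2000.0, 2000.0, 0.0, 0.3)]
        with pytest.warns(UserWarning):
            st = tl.render_stack(uniform_square, ink_sample, beam22, ev,
                                 small_camera, duration=0.1,
                                 noise_mode="none")
        assert st.n_frames <= 4

    def test_fast_path_agrees_with_reference_field(self, uniform_square,
                                                   ink_sample, beam22,
                                                   small_camera):
        # table-based rendering vs direct-quadrature field, PSF on
        ev = [tl.IlluminationEvent(0, 0, 1731.0, 2248.0, 0.0, 0.3)]
        st = tl.render_stack(uniform_square, ink_sample, beam22, ev,
                             small_camera, noise_mode="none", supersample=4)
        k = 9
        ss, step = 8, small_camera.a / 8
        n_cols, n_rows = small_camera.format
        sx = st.origin[0] + (np.arange(n_cols * ss) + 0.5) * step
        sy = st.origin[1] + (np.arange(n_rows * ss) + 0.5) * step
        X, Y = np.meshgrid(sx, sy)
        ref = tl.temperature_field(uniform_square, ink_sample, beam22, ev,
                                   X, Y, st.timestamps[k])
        ref = ndimage.gaussian_filter(ref, small_camera.psf_sigma / step,
                                      mode="nearest")
        ref_cam = ref.reshape(n_rows, ss, n_cols, ss).mean(axis=(1, 3))
        got = st.frames[k] - ink_sample.T0
        assert np.abs(ref_cam - got).max() < 0.05
        assert got.max() == pytest.approx(ref_cam.max(), rel=0.03)

    def test_photon_mode_background_noise_level(self, ink_sample, beam22,
                                                small_camera):
        empty = tl.AbsorberMap(values=np.zeros((40, 40)), pitch=10.0)
        st = tl.render_stack(empty, ink_sample, beam22, [], small_camera,
                             duration=20.0, noise_mode="photon", seed=2)
        k = photons_per_kelvin(small_camera, ink_sample)
        expected = np.sqrt(small_camera.b) / k
        assert st.frames.std() == pytest.approx(expected, rel=0.1)
        assert st.frames.mean() == pytest.approx(ink_sample.T0, abs=0.01)
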