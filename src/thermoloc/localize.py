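"""Sub-pixel localization of temperature peaks and its precision model.

The workhorse is the two-step symmetric 2D Gaussian fit: a first fit with
*fixed* spatial variance ζ₀² frees only the centre (and amplitude/offset),
and a second fit with the centre *fixed* recovers the variance ζ² and the
amplitude ΔT_max.  Freezing the variance in step one decouples centre and
width estimates and minimizes the centre scatter — the same reason PALM and
STORM pipelines often fix the PSF width.

The localization uncertainty follows the classic photon-statistics law

    σ_x,y ≈ sqrt( (ζ² + a²/12)/N  +  4·√π·b²·ζ³ / (a·N²) )

with camera pixel size ``a``, background photons ``b`` and detected thermal
photons ``N``; since N ∝ 4εσT₀³·ΔT_max (linearized gray-body law), this is
empirically σ ≈ sqrt(α/ΔT_max + β/ΔT_max²), the form used to extrapolate
the uncertainty of real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .detect import PeakEvent
from .forward import (CameraModel, ThermalStack, photons_per_kelvin,
                      render_stack)
from .scan import IlluminationEvent
from .scenes import AbsorberMap, BeamModel, ParameterError, SampleModel

__all__ = [
    "Localization",
    "UncertaintyModel",
    "FitError",
    "default_zeta0_sq",
    "fit_peak_two_step",
    "fit_peak_single",
    "predict_sigma",
    "sigma_vs_deltaT",
    "calibrate_alpha_beta",
    "run_repeatability",
    "localize_events",
    "RepeatabilityResult",
]


class FitError(RuntimeError):
    """Peak fit failed to converge or returned a non-positive amplitude."""


@dataclass
class Localization:
    """One localized temperature peak (lab-frame μm)."""

    x_c: float
    y_c: float
    sigma_x: float
    sigma_y: float
    dT_max: float          # °C
    zeta2: float           # μm², fitted spatial variance
    offset: float          # °C
    model: str
    chi2red: float         # residual mean square per dof, °C²
    frame: int = -1
    event: PeakEvent | None = None


@dataclass
class UncertaintyModel:
    """Empirical σ-versus-ΔT_max model σ = sqrt(α/ΔT + β/ΔT²)."""

    alpha: float           # °C·μm²
    beta: float            # °C²·μm²
    alpha_se: float = float("nan")
    beta_se: float = float("nan")

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be >= 0")

    def sigma(self, dT):
        return sigma_vs_deltaT(self.alpha, self.beta, dT)


def predict_sigma(zeta: float, a: float, b: float, N: float) -> float:
    """Closed-form localization precision, μm."""
    if N <= 0:
        raise ParameterError("photon number N must be > 0")
    if zeta <= 0 or a <= 0 or b < 0:
        raise ParameterError("zeta, a must be > 0; b >= 0")
    return float(np.sqrt((zeta ** 2 + a ** 2 / 12.0) / N
                         + 4.0 * np.sqrt(np.pi) * b ** 2 * zeta ** 3
                         / (a * N ** 2)))


def sigma_vs_deltaT(alpha: float, beta: float, dT) -> np.ndarray:
    """Extrapolated localization uncertainty at amplitude ΔT_max, μm."""
    dT = np.asarray(dT, dtype=float)
    if np.any(dT <= 0):
        raise ParameterError("dT must be > 0")
    out = np.sqrt(alpha / dT + beta / dT ** 2)
    return float(out) if out.ndim == 0 else out


def calibrate_alpha_beta(pairs) -> UncertaintyModel:
    """Fit (α, β) of σ² = α/ΔT + β/ΔT² by nonnegative least squares.

    ``pairs`` is a sequence of (ΔT_max °C, σ μm).  Requires at least four
    pairs spanning at least a two-fold range in ΔT.  Standard errors come
    from the unconstrained normal-equation covariance.
    """
    pairs = [(float(d), float(s)) for d, s in pairs]
    if len(pairs) < 4:
        raise ParameterError("need at least 4 (dT, sigma) pairs")
    dT = np.array([p[0] for p in pairs])
    sig = np.array([p[1] for p in pairs])
    if dT.max() < 2.0 * dT.min():
        raise ParameterError("dT values must span at least a 2x range")
    X = np.column_stack([1.0 / dT, 1.0 / dT ** 2])
    y = sig ** 2
    res = optimize.lsq_linear(X, y, bounds=(0.0, np.inf))
    dof = max(1, len(pairs) - 2)
    resid = y - X @ res.x
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return UncertaintyModel(alpha=float(res.x[0]), beta=float(res.x[1]),
                            alpha_se=float(np.sqrt(cov[0, 0])),
                            beta_se=float(np.sqrt(cov[1, 1])))


def default_zeta0_sq(beam: BeamModel, sample: SampleModel, camera: CameraModel,
                     tau_on: float) -> float:
    """Fixed prior variance for fit step 1: clean forward-model variance
    (beam ω₀²/4 + diffusive broadening 2Dτ_on + PSF σ²), μm²."""
    return beam.variance + 2.0 * sample.D * tau_on + camera.psf_sigma ** 2


# ---------------------------------------------------------------------------
# 2D surface models
# ---------------------------------------------------------------------------

def _sym(xy, xc, yc, amp, offset, zeta2):
    x, y = xy
    return offset + amp * np.exp(-((x - xc) ** 2 + (y - yc) ** 2) / (2 * zeta2))


def _asym(xy, xc, yc, amp, offset, zx2, zy2):
    x, y = xy
    return offset + amp * np.exp(-(x - xc) ** 2 / (2 * zx2)
                                 - (y - yc) ** 2 / (2 * zy2))


def _skew(xy, xc, yc, amp, offset, zx2, zy2, lx, ly):
    x, y = xy
    zx, zy = np.sqrt(zx2), np.sqrt(zy2)
    g = np.exp(-(x - xc) ** 2 / (2 * zx2) - (y - yc) ** 2 / (2 * zy2))
    fx = 1.0 + special.erf(lx * (x - xc) / (np.sqrt(2) * zx))
    fy = 1.0 + special.erf(ly * (y - yc) / (np.sqrt(2) * zy))
    return offset + amp * g * fx * fy


def _extract_roi(frame: np.ndarray, col: int, row: int, a: float,
                 origin: tuple[float, float], roi_half: int):
    n_rows, n_cols = frame.shape
    c0, c1 = max(0, col - roi_half), min(n_cols, col + roi_half + 1)
    r0, r1 = max(0, row - roi_half), min(n_rows, row + roi_half + 1)
    if (c1 - c0) < 7 or (r1 - r0) < 7:
        raise FitError("fit ROI smaller than 7x7 camera pixels")
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    x = origin[0] + (cols + 0.5) * a
    y = origin[1] + (rows + 0.5) * a
    X, Y = np.meshgrid(x, y)
    Z = frame[r0:r1, c0:c1]
    return X, Y, Z


def _lsq(model, xy, z, p0, bounds):
    try:
        popt, _ = optimize.curve_fit(model, xy, z, p0=p0, bounds=bounds,
                                     xtol=1e-8, ftol=1e-8, maxfev=2000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(str(exc)) from exc
    resid = z - model(xy, *popt)
    dof = max(1, z.size - len(p0))
    return popt, float(resid @ resid / dof)


def fit_peak_two_step(frame: np.ndarray, col: int, row: int, a: float,
                      origin: tuple[float, float], zeta0_sq: float,
                      roi_half: int = 5, baseline: float = 0.0,
                      camera: CameraModel | None = None,
                      sample: SampleModel | None = None,
                      uncertainty: UncertaintyModel | None = None,
                      ) -> Localization:
    """Two-step symmetric Gaussian fit of a temperature frame.

    Step 1 fits centre, amplitude and offset with the variance fixed at
    ``zeta0_sq``; step 2 fixes the centre and frees variance, amplitude and
    offset.  The reported σ_x,y come from :func:`predict_sigma` when
    ``camera`` and ``sample`` provide the photon calibration, from the
    empirical ``uncertainty`` model otherwise, NaN when neither is given.
    ``baseline`` (usually T₀) is subtracted before fitting.
    """
    if zeta0_sq <= 0:
        raise ParameterError("zeta0_sq must be > 0")
    X, Y, Z = _extract_roi(frame, col, row, a, origin, roi_half)
    z = (Z - baseline).ravel()
    xy = (X.ravel(), Y.ravel())
    med = float(np.median(z))
    amp0 = max(float(z.max() - med), 1e-6)
    xc0 = origin[0] + (col + 0.5) * a
    yc0 = origin[1] + (row + 0.5) * a
    span = roi_half * a

    def step1(p, xc, yc, amp, off):
        return _sym(p, xc, yc, amp, off, zeta0_sq)

    p1, _ = _lsq(step1, xy, z, [xc0, yc0, amp0, med],
                 ([xc0 - span, yc0 - span, 0.0, -np.inf],
                  [xc0 + span, yc0 + span, np.inf, np.inf]))
    xc, yc = float(p1[0]), float(p1[1])

    def step2(p, zeta2, amp, off):
        return _sym(p, xc, yc, amp, off, zeta2)

    p2, chi2 = _lsq(step2, xy, z, [zeta0_sq, p1[2], p1[3]],
                    ([1e-6, 0.0, -np.inf], [np.inf, np.inf, np.inf]))
    zeta2, dT, off = float(p2[0]), float(p2[1]), float(p2[2])
    if dT <= 0:
        raise FitError("non-positive fitted amplitude")
    sx = sy = float("nan")
    if camera is not None and sample is not None:
        zeta = np.sqrt(zeta2)
        N = photons_per_kelvin(camera, sample) * dT \
            * 2.0 * np.pi * zeta2 / camera.a ** 2
        sx = sy = predict_sigma(zeta, camera.a, camera.b, N)
    elif uncertainty is not None:
        sx = sy = float(uncertainty.sigma(dT))
    return Localization(x_c=xc, y_c=yc, sigma_x=sx, sigma_y=sy, dT_max=dT,
                        zeta2=zeta2, offset=off, model="symmetric_two_step",
                        chi2red=chi2)


def fit_peak_single(frame: np.ndarray, col: int, row: int, a: float,
                    origin: tuple[float, float], model: str,
                    zeta0_sq: float, roi_half: int = 5,
                    baseline: float = 0.0) -> Localization:
    """Single-step fit with a symmetric, asymmetric or skewed Gaussian."""
    X, Y, Z = _extract_roi(frame, col, row, a, origin, roi_half)
    z = (Z - baseline).ravel()
    xy = (X.ravel(), Y.ravel())
    med = float(np.median(z))
    amp0 = max(float(z.max() - med), 1e-6)
    xc0 = origin[0] + (col + 0.5) * a
    yc0 = origin[1] + (row + 0.5) * a
    span = roi_half * a
    lo_c = [xc0 - span, yc0 - span]
    hi_c = [xc0 + span, yc0 + span]
    if model == "symmetric":
        p, chi2 = _lsq(lambda p_, xc, yc, amp, off, z2:
                       _sym(p_, xc, yc, amp, off, z2),
                       xy, z, [xc0, yc0, amp0, med, zeta0_sq],
                       (lo_c + [0.0, -np.inf, 1e-6],
                        hi_c + [np.inf, np.inf, np.inf]))
        xc, yc, dT, off, zeta2 = p
        zx2 = zy2 = zeta2
    elif model == "asymmetric":
        p, chi2 = _lsq(lambda p_, xc, yc, amp, off, zx2_, zy2_:
                       _asym(p_, xc, yc, amp, off, zx2_, zy2_),
                       xy, z, [xc0, yc0, amp0, med, zeta0_sq, zeta0_sq],
                       (lo_c + [0.0, -np.inf, 1e-6, 1e-6],
                        hi_c + [np.inf, np.inf, np.inf, np.inf]))
        xc, yc, dT, off, zx2, zy2 = p
    elif model == "skewed":
        p, chi2 = _lsq(lambda p_, xc, yc, amp, off, zx2_, zy2_, lx, ly:
                       _skew(p_, xc, yc, amp, off, zx2_, zy2_, lx, ly),
                       xy, z, [xc0, yc0, amp0, med, zeta0_sq, zeta0_sq, 0.0, 0.0],
                       (lo_c + [0.0, -np.inf, 1e-6, 1e-6, -5.0, -5.0],
                        hi_c + [np.inf, np.inf, np.inf, np.inf, 5.0, 5.0]))
        xc, yc, dT, off, zx2, zy2 = p[0], p[1], p[2], p[3], p[4], p[5]
    else:
        raise ParameterError(f"unknown model {model!r}")
    if dT <= 0:
        raise FitError("non-positive fitted amplitude")
    return Localization(x_c=float(xc), y_c=float(yc), sigma_x=float("nan"),
                        sigma_y=float("nan"), dT_max=float(dT),
                        zeta2=float((zx2 + zy2) / 2.0), offset=float(off),
                        model=model, chi2red=chi2)


def localize_events(stack: ThermalStack, events: list[PeakEvent],
                    zeta0_sq: float, roi_half: int = 5,
                    camera: CameraModel | None = None,
                    sample: SampleModel | None = None,
                    uncertainty: UncertaintyModel | None = None,
                    ) -> tuple[list[Localization], int]:
    """Two-step localization of every detected event; returns (locs, n_failed)."""
    baseline = stack.T0 if stack.T0 is not None else float(np.median(stack.frames))
    locs, failed = [], 0
    for e in events:
        try:
            loc = fit_peak_two_step(stack.frames[e.frame], e.col, e.row,
                                    stack.a, stack.origin, zeta0_sq,
                                    roi_half=roi_half, baseline=baseline,
                                    camera=camera, sample=sample,
                                    uncertainty=uncertainty)
        except FitError:
            failed += 1
            continue
        loc.frame = e.frame
        loc.event = e
        locs.append(loc)
    return locs, failed


# ---------------------------------------------------------------------------
# Repeatability Monte-Carlo
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    mean_dTmax: float
    mean_zeta2: float
    sigma_xy: dict[str, tuple[float, float]]     # model -> (std_x, std_y)
    localizations: dict[str, list[Localization]] = field(default_factory=dict)


def run_repeatability(amap: AbsorberMap, sample: SampleModel, beam: BeamModel,
                      camera: CameraModel, location: tuple[float, float],
                      n_pulses: int, tau_on: float, seed: int,
                      models=("symmetric_two_step",),
                      noise_mode: str = "photon",
                      spacing: float | None = None,
                      roi_half: int = 5,
                      zeta0_sq: float | None = None) -> RepeatabilityResult:
    """Repeatedly pulse one location and measure localization scatter.

    Pulses must be separated enough to be independent; if ``spacing`` is
    given it must be at least 3·max(τ_on, τ_d).  Because well-separated
    frame-aligned pulses yield identical clean peak frames, the clean frame
    is rendered once and per-pulse noise is drawn independently — exactly
    equivalent to simulating the full pulse train.  Every requested model
    is fitted to the *same* noisy frames, so model comparisons are paired.
    """
    min_spacing = 3.0 * max(tau_on, sample.tau_d)
    if spacing is not None and spacing < min_spacing:
        raise ParameterError("pulses would overlap: spacing < 3*max(tau_on, tau_d)")
    ev = [IlluminationEvent(0, 0, location[0], location[1], 0.0, tau_on)]
    clean = render_stack(amap, sample, beam, ev, camera,
                         duration=tau_on + 1.5 / camera.f_rate,
                         noise_mode="none")
    peak_idx = int(round(tau_on * camera.f_rate))
    peak_frame = clean.frames[min(peak_idx, clean.n_frames - 1)]
    dT_frame = peak_frame - sample.T0
    # event pixel = hottest camera pixel
    row, col = np.unravel_index(np.argmax(dT_frame), dT_frame.shape)
    if zeta0_sq is None:
        # calibrate the fixed step-1 variance on the clean forward model:
        # a free symmetric fit of the noiseless peak frame measures the
        # actual rendered spot variance (the analytic default_zeta0_sq is
        # an upper-bound approximation of it)
        zeta0_sq = fit_peak_single(
            peak_frame, int(col), int(row), clean.a, clean.origin,
            "symmetric", default_zeta0_sq(beam, sample, camera, tau_on),
            roi_half=roi_half, baseline=sample.T0).zeta2
    k_phot = photons_per_kelvin(camera, sample)
    rng = np.random.default_rng(seed)

    locs: dict[str, list[Localization]] = {m: [] for m in models}
    for _ in range(n_pulses):
        if noise_mode == "photon":
            n_exp = camera.b + k_phot * np.clip(dT_frame, 0.0, None)
            noisy = sample.T0 + (rng.poisson(n_exp) - camera.b) / k_phot
        elif noise_mode == "netd":
            noisy = peak_frame + rng.normal(0.0, camera.NETD, peak_frame.shape)
        elif noise_mode == "none":
            noisy = peak_frame.copy()
        else:
            raise ParameterError(f"unknown noise_mode {noise_mode!r}")
        for m in models:
            try:
                if m == "symmetric_two_step":
                    loc = fit_peak_two_step(noisy, int(col), int(row),
                                            clean.a, clean.origin, zeta0_sq,
                                            roi_half=roi_half,
                                            baseline=sample.T0,
                                            camera=camera, sample=sample)
                else:
                    loc = fit_peak_single(noisy, int(col), int(row), clean.a,
                                          clean.origin, m, zeta0_sq,
                                          roi_half=roi_half,
                                          baseline=sample.T0)
            except FitError:
                continue
            locs[m].append(loc)

    sigma_xy = {}
    for m in models:
        xs = np.array([l.x_c for l in locs[m]])
        ys = np.array([l.y_c for l in locs[m]])
        sigma_xy[m] = (float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0,
                       float(np.std(ys, ddof=1)) if len(ys) > 1 else 0.0)
    ref = models[0]
    dts = [l.dT_max for l in locs[ref]]
    z2s = [l.zeta2 for l in locs[ref]]
    return RepeatabilityResult(
        mean_dTmax=float(np.mean(dts)) if dts else float("nan"),
        mean_zeta2=float(np.mean(z2s)) if z2s else float("nan"),
        sigma_xy=sigma_xy, localizations=locs)
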