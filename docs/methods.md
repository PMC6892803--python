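# Methods

## Physical model

A focused Gaussian beam of 1/e² intensity diameter 2ω₀ delivers a square
pulse of duration τ_on at position r₀. The heat source density is

    f(r') = A · m(r') · exp(−2|r'−r₀|²/ω₀²)        [°C/s]

where m ∈ [0, 1] is the local absorptance of the scene and A lumps absorbed
power, heat capacity and sample thickness into a single heating amplitude
(°C/s of temperature rise at the beam center on a full absorber in the
no-diffusion limit; absolute absorbed watts are never needed, only the
resulting ΔT). Heat released at pulse age u spreads in-plane by the 2D
diffusion Green's function (per-axis variance 2Ds after a delay s) and
relaxes to the environment as exp(−s/τ_d) (lumped Newton cooling):

    ΔT(r, t) = ∫ e^{−s/τ_d} (f ∗ G_s)(r) ds,   s ∈ [max(0, t−t₀−τ_on), t−t₀].

For uniform absorptance this reduces exactly to
A·ā·∫ [ω₀²/(ω₀²+8Ds)]·exp(−2|r−r₀|²/(ω₀²+8Ds))·e^{−s/τ_d} ds with ā the
beam-weighted mean absorptance: a Gaussian spot whose amplitude rises
during the pulse, peaks at τ_on and decays exponentially afterwards. For
structured absorbers the field centroid is the beam-intensity-weighted
centroid of the absorber — exactly the quantity the sub-pixel localization
estimates, which is why a stripe edge pulls the fitted center into the
stripe (tested against a numerical centroid oracle).

Assumptions: in-plane (2D) conduction only; temperature-independent
properties; the camera firmware has already applied emissivity,
atmospheric, and reflected-ambient corrections, so frames are temperatures
in °C; frame exposure is instantaneous sampling at the timestamp.

## Camera model

Frames are produced by convolving the physical field with a Gaussian
optical PSF (FWHM 345 μm by default, the diffraction-limited optics
resolution), box-averaging over the a×a pixel footprint (a = 400 μm,
supersampling factor ≥ 4), adding the baseline T₀, and degrading with one
of:

* `netd` — i.i.d. Gaussian noise of std NETD (0.1 °C), the spec sheet
  noise floor of an uncooled microbolometer camera;
* `photon` — per-pixel expected counts b + c_N·4εσT₀³ΔT (the linearized
  gray-body increment; at T₀ = 293 K the linearization underestimates the
  exact (T₀+ΔT)⁴−T₀⁴ by 1% at ΔT = 2 K and stays within 5% up to 10 K),
  Poisson-sampled and mapped back to temperature. This makes localization
  error scale with photon number exactly as the σ_x,y law assumes.

`c_N = 10` photons/(W m⁻²)/frame and `b = 6` background photons were fixed
once so that the resulting α, β of the σ-versus-ΔT_max law land on the
scale of the published calibration for this kind of setup (α ≈ 600 °C μm²,
β ≈ 600 °C² μm²); they are camera-calibration surrogates, config-exposed.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| ε | 0.8 ink / 0.95 biopsy | – | black-tape-method values for these sample types |
| D | 1.0e5 ink / 1.4e5 biopsy | μm²/s | polymer-film / water-like diffusivity |
| T₀ | 19.85 (293 K) | °C | typical lab equilibrium temperature |
| A | 2.5e4–6e4 | °C/s | places camera-observed ΔT_max in the 0.3–5 °C operating range |
| τ_d | 0.2 | s | sub-second thermal relaxation; sets decay of each peak |
| beam 2ω₀ | 22 or 56 | μm | with / without the Keplerian beam reducer |
| a, f_rate | 400 μm, 30 Hz | | thermo-camera pixel pitch on sample and frame rate |
| NETD | 0.1 | °C | camera sensitivity |
| psf_fwhm | 345 | μm | diffraction-limited optics resolution |
| δx | 10–40 | μm | scan pixel; oversamples the camera pixel |
| τ_off | 0.002 | s | shutter-closed dwell |
| ΔT_min | 0.3 (0.1) | °C | rendering threshold, treated (control) setting |

## Scan protocol

Scan s of Δx·Δy activates pixels with (i mod Δx, j mod Δy) equal to the
s-th lattice offset, offsets enumerated row-major (ox fastest); within a
scan all pixels are visited in raster order, advancing time by τ_on at
activated and τ_off at silent pixels. Every pixel is activated exactly
once over the full schedule (a property test draws random protocols), and
the closed form t_tot = N_xN_y τ_on + N_xN_y τ_off(ΔxΔy−1) equals the
schedule walk. `min_separation` is a documented heuristic — a diffusion
length rule Δx_min = k·√(ω₀²/4 + 4Dτ_on) and Δt_min = k·max(τ_on, τ_d)
with safety factor k = 3 — and the validator reports violations rather
than refusing to run. Mirror fly-back and settling times are ignored.

When consecutive activations land in the same camera pixel (small fields
of view), their temporal pitch must exceed the detection fit window; the
examples achieve this through the lattice spacing and, where needed, a
larger τ_off, just as a real acquisition would slow the silent dwell.

## Numerical evaluation

The time integral is evaluated by trapezoid quadrature with ≥ 64 nodes
placed uniformly in log(v), v = v₀ + 2Ds, an exact substitution that
resolves both the near-singular small-s behaviour (where the kernel is a
narrow spike) and the slow tail — a uniform-in-s rule at the same node
count misintegrates the small-s spike badly for realistic D. The source is
discretized at spacing h = min(pitch, ω₀/3) with per-cell regularization
variance h²/12. `temperature_field` is the direct reference
implementation (exact in the D = 0 limit, where the field is evaluated in
closed form). `render_stack` uses a precomputed (age × distance) kernel
table with linear interpolation, the source deposited bilinearly on the
supersampled camera grid (mass and first moment preserved); the kernel
carries an extra step²/12 per-axis variance so grid samples represent cell
means and the later block average reproduces the pixel box integral. A
test pins the two paths to each other to < 0.05 °C. Because of the
amplitude-weighted mixture of diffusion ages, the instantaneous spot is
Gaussian only approximately: at 8Dτ_on = ω₀² a symmetric-Gaussian fit
leaves RMS residuals < 2% of the peak, with a larger pointwise deviation
in a narrow central cusp.

Fits use unweighted nonlinear least squares (`scipy.optimize`), matching
standard practice for temperature frames: initialization at the event
pixel center with amplitude = peak − ROI median and offset = ROI median,
parameter tolerance 1e-8, ROI 11×11 camera pixels (≥ 7×7 after edge
clipping). The step-2 refit frees the offset. The skewed surface
multiplies each axis by 1 + erf(λ(x−x_c)/(√2 ζ)); near λ = 0 its location
and skew parameters are nearly degenerate, which is what makes its center
scatter large in the model-comparison study.

The fixed step-1 variance ζ₀² defaults to the analytic
ω₀²/4 + 2Dτ_on + σ_psf² for blind analysis; simulation-backed studies
calibrate it from a free symmetric fit of the clean rendered peak (the
analytic form overestimates the rendered width, since the amplitude
weighting favours young, narrow diffusion ages, and a mismatched template
inflates center scatter).

Peak detection slides a 1D Gaussian fit window (default
max(5, 2·τ_on·f_rate) frames) over each trace; only windows centered on
smoothed local maxima rising 0.8× the threshold above the trace median are
fitted, a shortcut that cannot change the accepted set because flat
windows cannot produce an amplitude above threshold. Acceptance requires
the fitted center in the central third of the window and amplitude ≥ 3·NETD
(0.3 °C); candidates closer than half a window merge keeping the larger
amplitude. Cross-pixel deduplication groups 8-connected detections whose
peak frames differ by ≤ τ_on·f_rate/2 — heat reaches neighbouring camera
pixels with a diffusion delay of a few frames (~a²/4D), so a one-frame
tolerance would split single pulses into duplicates.

Rendering bins are half-open, zero-based and origin-anchored; a boundary
coordinate belongs to the higher-index bin, making co-localization tests
exact. Rendered values are temperature increments (an absolute mode adds
T₀).

The Rayleigh threshold is computed from first principles: two equal
incoherent Airy intensities (2J₁(v)/v)² separated by the first zero
v₀ = 3.8317, contrast = (mean peak − saddle)/mean peak, sampled at
≤ v₀/400. This definition reproduces the classic 26.4%; the symmetric
alternative (max−min)/(max+min) gives ≈ 15% and is rejected.

## What the synthetic generator does and does not emulate

It reproduces: Gaussian temperature spots with exponential-like rise and
decay on a 400 μm/30 Hz camera grid, the 0.1 °C noise floor, shot noise
scaling with ΔT, the modulated square-lattice schedule, binary ink-like
patterns, sparse nanoparticle-like clusters, and uniform calibration
squares. It does not emulate: emissivity heterogeneity (supported as an
optional per-position map but defaulted uniform), 3D conduction into the
substrate, radiative transport in tissue, camera vignetting or
fixed-pattern noise, mirror settling, or pulse-to-pulse laser power drift.
Passing tests therefore validate the analysis chain under the stated noise
and transport model, not the behaviour of any particular real camera or
tissue; on real data the α/β calibration route replaces the photon-model
σ attachment.

## Statistical design choices

Repeatability simulations exploit that well-separated frame-aligned pulses
at one location produce identical clean peak frames: the clean frame is
rendered once and per-pulse noise is drawn independently, which is exactly
equivalent to the full pulse train and lets every fit model see the same
noisy frames (paired comparisons). The model-comparison study runs at the
NETD noise floor, where the fixed-template two-step fit shows its
advantage most clearly; under pure shot noise the adaptive single-step
fits close most of the gap. The precision-law study uses the photon mode,
whose noise the law describes, pooling three independent 150-pulse runs
per amplitude for a stable scatter estimate; the fixed-template estimator
can beat the free-fit law at low ΔT (its center is less sensitive to
background noise), so the law is enforced as an upper bound on σ together
with a < 20% per-point residual check of the α/β trend.

Problem sizes in tests and examples (scan grids of ~10²–10³ pixels, camera
formats of 16×12–20×16, 150-pulse repeatability runs) are chosen to
exercise every pathway of the method at full physical fidelity while
keeping each study in the seconds-to-minutes range; all sizes scale up by
configuration only.

## Known limitations

* The heat kernel is an idealized 2D model with a single lumped loss time;
  real layered samples show multi-exponential relaxation.
* Localization assumes one isolated peak per fitted frame; overlapping
  pulses are flagged by the schedule validator, not unmixed.
* `predict_sigma` is the classic free-fit law; for the two-step estimator
  it is an upper bound rather than an equality at low signal.
* The CSV camera-export reader assumes one frame per file with a fixed
  header-line count and comma separators.
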