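# thermoloc

Sub-diffraction photo-thermal imaging by localization of laser-induced
temperature peaks.

Far-infrared thermal cameras quantify temperature through the gray-body law
R = εσT⁴, but diffraction at their low-NA optics limits resolution to
~345 μm (and heat diffusion degrades it to ~1 mm in practice). `thermoloc`
implements — and simulates end to end — an imaging scheme that breaks this
limit the way PALM/STORM do in fluorescence microscopy: a focused visible
laser beam (1/e² diameter 22–56 μm) raster-scans the sample while a shutter
restricts activation to a sparse square lattice of scan pixels, so each
laser-induced temperature peak appears isolated in the camera stack. Each
peak is then localized far below the camera's diffraction limit, and the
localized centers, color-coded by peak amplitude, are binned back onto the
scan grid to form the super-resolved map of the light-absorbing centers
(ink patterns, photothermal nanoparticles in tissue, ...).

The package covers the full workflow, usable from Python or the thin
`thermoloc` CLI:

* **Scenes & physics** (`scenes`, `forward`) — ground-truth absorber maps;
  a heat-diffusion forward model (2D Green's-function convolution of the
  beam-weighted source with Newton-cooling losses); camera rendering with
  optical PSF, pixel integration, and NETD or shot-noise (photon) models in
  which counts follow the linearized radiance increment 4εσT₀³ΔT.
* **Scan protocol** (`scan`) — the modulated lattice schedule; every pixel
  activated exactly once in Δx·Δy passes; the timing model
  t_tot = N_xN_y·τ_on + N_xN_y·τ_off(ΔxΔy − 1); spacing rules that keep
  concurrent peaks isolated.
* **Analysis** (`detect`, `localize`, `reconstruct`, `assess`) — sliding
  1D-Gaussian peak detection in per-pixel traces; the two-step symmetric 2D
  Gaussian fit (center first with fixed variance ζ₀², then ζ² and ΔT_max
  with the center fixed) plus asymmetric/skewed alternatives; the precision
  law σ_x,y ≈ √((ζ² + a²/12)/N + 4√π b²ζ³/(aN²)) ≈ √(α/ΔT + β/ΔT²) and its
  α/β calibration; per-bin max-ΔT_max rendering with a ΔT_min threshold;
  line profiles, adjacent-peak contrast, and the Rayleigh 26.4% criterion
  computed from first principles.

## Worked example

`examples/04_stripe_superresolution.py` simulates the flagship experiment:
five 60 μm ink stripes with 60 μm gaps (120 μm period — three times below
the 345 μm diffraction limit), scanned with a 22 μm beam on a 40×20 grid of
15 μm pixels, imaged by a 400 μm/pixel, 30 Hz camera with photon noise:

```
simulating 800 pulses, 556 s of acquisition at 30 Hz ...
400 peaks detected, 400 localized (pulses on the gaps stay below the 0.3 degC threshold)
mean dT_max = 1.91 degC, mean sigma = 24 um
super-res stripe contrasts: ['83%', '93%', '92%', '87%'] (Rayleigh needs 26.5%)
max-projection contrasts: none — a single unresolved blob
resolution gain at 60 um vs the 345 um diffraction limit: 5.8x
```

Every adjacent stripe pair clears the Rayleigh 26.4% contrast threshold in
the reconstruction, while the conventional image (temporal maximum
projection of the same raw stack) shows a single unresolved blob — the
super-resolution claim in one run. The other examples cover schedule
timing (~88 min for a 3.7×1.8 mm field, ~22 min with doubled pixels), the
single-pulse physics, the σ-versus-ΔT_max precision law (α ≈ 700 °C μm²,
β ≈ 600 °C² μm² under the default camera calibration), and nanoparticle
cluster mapping with a 100% co-localization score and an empty control.

The CLI mirrors the library:

```sh
thermoloc pipeline --config examples/stripe_config.yaml --out run_demo
```

writes the stack (TIFF + JSON sidecar), schedule/events/localizations
(CSV), the super-res image and a stage-by-stage log. Real camera exports
(per-frame CSV matrices) are ingested with `thermoloc.io.read_stack`.

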