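# Demo pipeline configuration: two-stripe ink scene, modulated lattice
# scan, NETD camera noise.  Run with:
#   thermoloc pipeline --config examples/stripe_config.yaml --out run_demo
scene:
  kind: stripes
  stripe_width: 60.0      # um
  gap: 60.0               # um
  n_stripes: 2
  pitch: 5.0              # ground-truth grid cell, um
  margin: 60.0            # empty border, um
  height: 240.0           # um
sample:
  preset: ink             # emissivity 0.8, film-like diffusivity
  A: 4.0e4                # heating amplitude, degC/s at unit absorptance
beam:
  diameter_1e2: 22.0      # 1/e^2 intensity diameter, um
  power_mw: 15.0
protocol:
  N_x: 16
  N_y: 8
  dx: 18.75               # scan pixel, um
  lattice_dx: 16          # activated-pixel lattice spacing (scan pixels)
  lattice_dy: 2
  tau_on: 0.3             # s
  tau_off: 0.01           # s, silent dwell
  origin: [0.0, 45.0]     # lab-frame corner of scan pixel (0,0), um
camera:
  format: [16, 12]        # (cols, rows); the full 320x240 is unnecessary here
detection:
  amp_threshold: 0.3      # degC, = 3x NETD
rendering:
  noise_mode: netd
  dT_min: 0.3             # degC rendering threshold
seed: 1
outdir: thermoloc_run
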