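"""End-to-end sub-diffraction imaging of a 60 um stripe grid.

Simulates the full experiment — modulated lattice scan, thermo-camera
stack with photon noise, temporal peak detection, two-step localization,
super-resolution rendering — and quantifies the resolution gain over the
conventional maximum-projection image via the Rayleigh 26.4% contrast.
"""

import numpy as np

import thermoloc as tl

# five 60-um stripes with 60-um gaps: a 120-um period, ~3x below the
# 345-um diffraction limit of the far-infrared optics
amap = tl.make_stripe_grid(60, 60, 5, pitch=5.0, margin=30, height=300)
protocol = tl.ScanProtocol(N_x=40, N_y=20, dx=15.0, lattice_dx=40,
                           lattice_dy=2, tau_on=0.3, tau_off=0.005)
events = tl.build_schedule(protocol)
sample = tl.ink_sample_model(A=2.5e4)
beam = tl.beam_22um()
camera = tl.CameraModel(format=(16, 12))

print(f"simulating {len(events)} pulses, "
      f"{tl.total_time(protocol):.0f} s of acquisition at 30 Hz ...")
stack = tl.render_stack(amap, sample, beam, events, camera,
                        noise_mode="photon", seed=1)

events_found = tl.detect_stack_events(stack, amp_threshold=0.3, tau_on=0.3)
z0 = tl.default_zeta0_sq(beam, sample, camera, 0.3)
locs, n_failed = tl.localize_events(stack, events_found, z0,
                                    camera=camera, sample=sample)
print(f"{len(events_found)} peaks detected, {len(locs)} localized "
      f"(pulses on the gaps stay below the 0.3 degC threshold)")
print(f"mean dT_max = {np.mean([l.dT_max for l in locs]):.2f} degC, "
      f"mean sigma = {np.nanmean([l.sigma_x for l in locs]):.0f} um")

sr = tl.bin_localizations(locs, protocol, dT_min=0.3)
col_mean = sr.values.mean(axis=0)
x = (np.arange(40) + 0.5) * 15.0
# contrast between each pair of adjacent stripes (peaks at the known
# stripe positions, dip at the gap centre between them)
peaks = [col_mean[np.abs(x - (60 + 120 * k)) <= 30].max() for k in range(5)]
dips = [col_mean[np.abs(x - (120 + 120 * k)) <= 30].min() for k in range(4)]
contrasts = [100 * ((peaks[k] + peaks[k + 1]) / 2 - dips[k])
             / ((peaks[k] + peaks[k + 1]) / 2) for k in range(4)]
thr = tl.rayleigh_contrast_threshold()
print(f"super-res stripe contrasts: "
      f"{[f'{c:.0f}%' for c in contrasts]} (Rayleigh needs {thr:.1f}%)")

proj = tl.max_projection(stack) - sample.T0
p_low = tl.extract_profile(proj, stack.a, stack.origin,
                           (-400, 150.0), (1000, 150.0), width=1200.0)
low = tl.adjacent_peak_contrast(p_low)
print(f"max-projection contrasts: {low or 'none — a single unresolved blob'}")
print(f"resolution gain at 60 um vs the 345 um diffraction limit: "
      f"{tl.resolution_gain(345, 60):.1f}x")
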