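"""Modulated raster-scan schedules and the acquisition-time model.

Builds the square-lattice illumination schedule for a millimetre-sized
field of view and prints the closed-form total acquisition time, plus the
minimum spacing rule that keeps concurrent temperature peaks isolated.
"""

import thermoloc as tl

# the 100 x 48 pixel, 37.6 um scan of a 3.7 x 1.8 mm biopsy region:
# tau_on = 1 s activation, 2 ms silent dwell, one activated pixel per
# 50-pixel row stretch per pass
protocol = tl.ScanProtocol(N_x=100, N_y=48, dx=37.6, lattice_dx=50,
                           lattice_dy=1, tau_on=1.0, tau_off=0.002)
events = tl.build_schedule(protocol)
t_tot = tl.total_time(protocol)
print(f"schedule: {len(events)} laser pulses over {protocol.n_scans} scans")
print(f"total acquisition time: {t_tot:.1f} s = {t_tot / 60:.1f} min")
# ~88 min: the price of keeping every temperature peak isolated; halving
# the grid and doubling the pixel cuts it to ~22 min
fast = tl.ScanProtocol(N_x=50, N_y=24, dx=75.3, lattice_dx=25,
                       lattice_dy=2, tau_on=1.0, tau_off=0.002)
print(f"doubled pixel size: {tl.total_time(fast) / 60:.1f} min")

# spacing rule: with water-like diffusivity, concurrent peaks need ~1 mm
# of separation (or ~1 s of temporal separation) to stay isolated
sample = tl.SampleModel(D=1.4e5, tau_d=0.2)
dx_min, dt_min = tl.min_separation(sample, tau_on=0.3, beam=tl.beam_56um())
print(f"min spacing for simultaneous peaks: {dx_min:.0f} um "
      f"(or {dt_min:.1f} s apart in time)")
violations = tl.validate_schedule(events, dx_min, dt_min)
print(f"schedule violations of the spacing rule: {len(violations)}")
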