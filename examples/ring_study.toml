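# Three-group degradation study on a generated single-ring stent.
# Units: mm, MPa, hours, mmHg.

group = "E2"          # overridden per group by `stentdamage compare`
dt = 0.005            # hours
t_max = 40.0          # hours
snapshot_interval = 5.0
rng_seed = 7

[mesh]
kind = "ring"
radius = 1.5          # mm
strut_width = 0.1     # mm
strut_thickness = 0.1 # mm
n_crowns = 6
elements_per_segment = 6

[stress]
kind = "crown"        # analytic post-deployment residual field
peak_stress = 230.0   # MPa at the crown bends
decay = 0.5           # geometric decay per element of graph distance

# material and corrosion blocks omitted: zinc-alloy defaults apply
# (density 8.5 g/cm^3, E 74500 MPa, yield 220 MPa; delta_U 0.1 mm,
#  k_U 0.05/h, delta_SC 0.07 mm, S 0.005 mm^2 h/N, R 2, sigma_th 66 MPa,
#  beta 0.8, unit Weibull pitting)

[fatigue]
A = 1e12              # Basquin coefficient, MPa^k cycles (placeholder, not alloy-calibrated)
k = 3.0
frequency = 4320.0    # cycles/h (1.2 Hz ~ 72 bpm)

[waveform]
base_pressure = 100.0 # mmHg
amplitude = 20.0      # mmHg -> 80-120 mmHg cycle
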