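"""Generate the protocol's ramp-and-hold perturbation and check its shape.

The impedance protocols rotate the platform by 3 degrees over 125 ms with
a minimum-jerk velocity profile — the smoothest point-to-point motion,
with zero velocity and acceleration at both ends.  Its peak velocity has
the closed form 1.875*A/T, which for the protocol values is 45 deg/s.
"""

import numpy as np

from twinplat import PerturbationSpec, five_point_derivative, minimum_jerk_ramp

spec = PerturbationSpec(amplitude_deg=3.0, duration_s=0.125, direction="DP")
ramp = minimum_jerk_ramp(spec, fs=2000.0)
velocity = five_point_derivative(ramp)

print(f"ramp: {spec.amplitude_deg} deg over {spec.duration_s*1000:.0f} ms "
      f"at {ramp.fs:.0f} Hz ({len(ramp)} samples incl. hold)")
print(f"closed-form peak velocity : {spec.peak_velocity_deg_s:.3f} deg/s")
print(f"numeric peak velocity     : {velocity.values.max():.3f} deg/s")
print(f"end position              : {ramp.values[-1]:.3f} deg (holds at A)")

# The two peak velocities agree to numerical precision; a mismatch would
# mean the generated trajectory is not the quintic minimum-jerk profile.
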