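"""Intralimb and postural kinematics.

Generates smooth hindlimb angle traces over one stride (three-segment,
two-angle model: proximal angle at the hip, distal at the ankle), then
reports range of motion, proximal-distal peak timing, the base-of-support
paw-rotation angle, and the swim trunk angle.
"""

import numpy as np

from quadgait import (base_of_support_angle, peak_timing_phase, range_of_motion,
                      trunk_angle)
from quadgait.synth import simulate_angle_traces

trace = simulate_angle_traces([(0.0, 0.4)], frame_rate=500.0,
                              proximal_amp=20.0, distal_amp=35.0, lag=0.12)[0]
prox, dist = range_of_motion(trace)
print(f"range of motion: proximal {prox.excursion_deg:.1f}°, "
      f"distal {dist.excursion_deg:.1f}° (peak-to-trough)")
phase = peak_timing_phase(trace, 0.4)
print(f"proximal-distal peak timing phase: {phase:.3f} of a stride "
      f"(0 = in-phase)")

bos = base_of_support_angle(shoulder_mid=[0, 10], groin=[0, 5],
                            paw_at_contact=[np.sin(np.radians(20.0)),
                                            5 - np.cos(np.radians(20.0))])
print(f"base-of-support paw rotation at contact: {bos:.1f}°")

trunk = trunk_angle(surface_left=[0, 0], surface_right=[100, 0],
                    iliac_crest=[40, 6], hip=[48, 4.5])
print(f"swim trunk angle vs water surface: {trunk:.1f}°")

# Peak angular excursions normally occur at the end of stance just before
# lift-off; the small peak-timing phase shows the distal angle trailing the
# proximal one by the imposed lag.
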