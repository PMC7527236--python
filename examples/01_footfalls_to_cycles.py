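"""From raw footfall events to step cycles.

Builds a minimal right-hindlimb event series (contacts and lifts in
seconds), extracts the complete stride cycles, and prints their
spatiotemporal decomposition.
"""

import numpy as np

from quadgait import Limb, LimbEventSeries, extract_step_cycles

series = LimbEventSeries(
    animal_id="A1", timepoint="BL", pass_id="P1", limb=Limb.RH,
    contacts=np.array([0.00, 0.50, 1.00, 1.48]),
    lifts=np.array([0.30, 0.82, 1.31]),
)

cycles = extract_step_cycles(series)
print(f"{len(cycles)} complete strides (terminal partial cycle dropped):")
for i, c in enumerate(cycles):
    print(f"  stride {i}: duration {c.stride_duration:.2f} s = "
          f"stance {c.stance_duration:.2f} + swing {c.swing_duration:.2f} s, "
          f"frequency {c.frequency:.2f} Hz, duty cycle {c.duty_cycle:.2f}")

# A stride runs contact-to-next-contact of the same paw; the stance fraction
# (duty cycle) shrinks as animals speed up.
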