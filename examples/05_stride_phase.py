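"""Extract the peristaltic phase clock from a tracked trajectory.

Uses the phantom's true brain path (plus tracking-scale noise) and heading
to compute the smoothed forward velocity, its Hilbert phase, the stride
segmentation and the warp-refined clock, and compares against the phantom's
known phase.
"""

import numpy as np

from pongscope.behavior import phase_clock_for_bout
from pongscope.phantom import BoutSpec, PhantomConfig, build_phantom

phantom = build_phantom(
    PhantomConfig(bouts=(BoutSpec("forward", n_strides=8),), start_pause=1.0)
)
state, b0, b1 = phantom.behavior.bouts[0]
t = np.arange(b0, b1, 0.01)
rng = np.random.default_rng(0)
path = phantom.reference_path(t)[:, :2] + rng.normal(0, 0.3, (t.size, 2))

clock, strides, template = phase_clock_for_bout(
    t, path, phantom.heading_at(t), mode=state
)
print(f"bout                 : {state}, {b1 - b0:.1f} s")
print(f"strides retained     : {len(strides)} "
      "(8 pulses -> 7 peak-to-peak strides, last one excluded)")
print("stride durations (s) :",
      np.round((strides['end_s'] - strides['start_s']).to_numpy(), 3))

phi_true = phantom.phi_true(t)
ok = np.isfinite(phi_true)
d = (clock.phi - phi_true)[ok]
d = np.angle(np.exp(1j * (d - np.angle(np.mean(np.exp(1j * d))))))
print(f"phase error vs truth : {np.degrees(np.sqrt((d ** 2).mean())):.1f}° RMS "
      "(offset removed) — the clock that phase-bins the fluorescence is "
      "accurate to a fraction of one 15° bin.")
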