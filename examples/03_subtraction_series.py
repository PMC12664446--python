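"""Digital subtraction radiography of a simulated contrast bolus.

A kinematic bolus fills the cavity along the long axis over a few frames;
each frame is normalized (counts/N0), subtracted from the contrast-free
baseline, and the difference series is cleaned with the 5x5x5
spatio-temporal median filter.
"""

import numpy as np

from shuntscope import (AttenuationTable, PhantomSpec, ProjectionGeometry,
                        bolus_series, build_valve_phantom, median_filter_xyt,
                        render_frame, subtract_baseline)

volume = build_valve_phantom(PhantomSpec())
attenuation = AttenuationTable()
geometry = ProjectionGeometry.ml_default()

n_frames = 8
frames = bolus_series(volume, concentration=2.0, n_frames=n_frames,
                      fill_profile=lambda k: min(1.0, k / 5))

rads = []
for k, scene in enumerate(frames):
    scene.pose_angle = 0.0
    rad, _ = render_frame(scene, attenuation, geometry, n0=400, seed=100 + k,
                          frame_index=k)
    rads.append(rad)

subs = [subtract_baseline(rad, rads[0]) for rad in rads]
stack = np.stack([s.difference for s in subs])
filtered = median_filter_xyt(stack, kernel=(5, 5, 5))

for k in range(n_frames):
    raw = stack[k]
    print(f"frame {k}: fill {frames[k].metadata['fill_fraction']:.2f}  "
          f"mean absorption diff {raw.mean():+.4f}  "
          f"p99 {np.quantile(raw, 0.99):.3f}  "
          f"filtered p99 {np.quantile(filtered[k], 0.99):.3f}")
# The absorption difference grows as the contrast front advances (positive
# where contrast absorbs); static structures cancel in the subtraction, and
# the median filter suppresses the binomial noise while keeping the front.
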