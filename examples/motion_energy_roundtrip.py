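"""Motion-energy analysis on a rendered synthetic frame stack.

Plants a movement series in a rectangular region of interest, renders a
grayscale frame stack around it, and recovers the series as mean absolute
pixel change per frame — the motion-energy measure used for the body
channel.
"""

import numpy as np
from scipy import stats

import dyadsync as ds

rng = np.random.default_rng(0)
planted = np.abs(rng.normal(size=120))
planted[0] = 0.0

roi = ds.ROISpec("body", x0=8, y0=8, x1=40, y1=40)
frames = ds.render_motion_frames(ds.ChannelSeries("body", planted, 30), roi, (48, 48), seed=0)
recovered = ds.motion_energy_series(frames, [roi], noise_threshold=0.0)[0]

rho = stats.spearmanr(planted[1:], recovered.values[1:]).statistic
print(f"frames: {len(frames)}, ROI {roi.x1 - roi.x0}x{roi.y1 - roi.y0} px")
print(f"recovered-vs-planted Spearman rho = {rho:.3f} (1.0 = perfect rank agreement)")
print(f"max abs error = {np.max(np.abs(recovered.values - planted)):.2e} "
      "(identity scaling for this fixture)")
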