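"""The curve similarity distance on the bundled example templates.

A detection window of four force samples extends to the 10-element
curve L (four values + six lagged differences). The distance to a
status template is d = 10 - sum_j exp(-(x_j - mu_j)^2 / (2 delta_j^2)):
0 at the template center, approaching 10 far away; d <= epsilon = 2
declares the window similar.
"""

import numpy as np

from gaitcsm import build_curve, load_example_model, similarity_distance

model = load_example_model()
on, off = model.on_template, model.off_template

print("curve of window [10, 20, 30, 40] (oldest -> newest):")
print(" ", build_curve([10.0, 20.0, 30.0, 40.0]))

print(f"\nself-distance of the off-ground template: "
      f"{similarity_distance(off.mu, off):.3f} (exactly 0 at the center)")

offset = off.mu + np.sqrt(2 * np.log(2)) * off.delta
print(f"one half-width away on every element:      "
      f"{similarity_distance(offset, off):.3f} (ten terms of 0.5)")

rng = np.random.default_rng(0)
far = rng.normal(scale=500.0, size=10)
print(f"a random far-away curve:                   "
      f"{similarity_distance(far, off):.3f} (approaches the maximum of 10)")
print(f"\nsimilarity threshold epsilon = {model.epsilon} "
      f"(preferable bound: 0 < epsilon/10 <= 0.2)")
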