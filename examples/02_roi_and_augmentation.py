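"""Dish ROI detection and the augmentation chain.

Detects the petri-dish circle with the Hough transform + rim refinement,
crops it, and expands one dish to a batch of augmented 224 px images via the
acquisition-protocol augmentations (gated rotation, mirroring, gated
brightness jitter).
"""

import numpy as np

from mincenet.preprocess import AugmentationConfig, augment_to_count, extract_roi
from mincenet.synthetic import RenderConfig, SampleMeta, render_sample_image

cfg = RenderConfig()  # full 672 px render
img = render_sample_image(SampleMeta("back", 0.3, 1, "demo"), cfg, seed=7)

crop, circle = extract_roi(img)
true_r = cfg.dish_radius_px
print(f"detected circle: centre ({circle.center_x:.1f}, {circle.center_y:.1f}), "
      f"radius {circle.radius:.1f} px (truth {true_r:.1f} px, "
      f"error {100 * abs(circle.radius - true_r) / true_r:.2f}%)")
print(f"ROI crop: {crop.shape[0]} x {crop.shape[1]} px, outside set to black")

acfg = AugmentationConfig(target_size=224)
batch = augment_to_count([crop], 12, acfg, np.random.default_rng(0))
means = [b[b.sum(axis=2) > 0].mean() for b in batch]
print(f"\naugmented {len(batch)} images at {batch[0].shape[0]} px; "
      f"mean dish brightness ranges {min(means):.1f}-{max(means):.1f} "
      "(the gated brightness jitter at work)")
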