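"""Export last-stage feature maps as images (qualitative inspection only)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .architectures import RegressionModel

__all__ = ["export_feature_maps", "last_stage_feature_maps"]


def last_stage_feature_maps(model: RegressionModel, image: np.ndarray) -> np.ndarray:
    """(C, h, w) activations after the final stage for one (3, H, W) image."""
    x = np.asarray(image, dtype=np.float32)
    if x.ndim != 3 or x.shape[0] != 3:
        raise ValueError(f"expected a (3,H,W) image, got {x.shape}")
    h = model.stem.forward(x[None])
    for stage in model.stages:
        h = stage.forward(h)
    return h[0]


def export_feature_maps(model: RegressionModel, image: np.ndarray, out_dir,
                        max_maps: int = 16) -> list:
    """Write the strongest ``max_maps`` feature maps as normalised PNGs.

    Maps are ranked by mean activation; each is min-max scaled to 8 bit.
    Returns the written paths.
    """
    maps = last_stage_feature_maps(model, image)
    order = np.argsort(-maps.mean(axis=(1, 2)))[:max_maps]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rank, ch in enumerate(order):
        m = maps[ch]
        span = m.max() - m.min()
        norm = (m - m.min()) / span if span > 0 else np.zeros_like(m)
        arr = (norm * 255).astype(np.uint8)
        path = out_dir / f"feature_{rank:02d}_ch{int(ch):04d}.png"
        Image.fromarray(arr).resize((112, 112), Image.Resampling.NEAREST).save(path)
        paths.append(path)
    return paths
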