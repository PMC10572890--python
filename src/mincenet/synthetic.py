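"""Synthetic minced-meat dish images with a known adulteration fraction.

The study design this emulates: minced pork (soaked in mutton-flavour
essence and red colorant to mask it) mixed into minced mutton at mass
fractions 0.10/0.20/0.30/0.40, pressed flat into a 6 cm petri dish and
photographed from above.  Eight replicate dishes per (part, ratio) over
three pork cuts gives 8 x 4 x 3 = 96 samples.

The renderer draws a circular dish of granules (3-5 mm mince particles ~
6-12 px at the default 672 px frame) on a dark background.  Each granule is
pork with probability ``ratio`` and otherwise mutton; granule colours are
i.i.d. Gaussian around the component mean.  The essence/colorant treatment
is a single ``tint_strength`` knob that moves the pork mean toward the
mutton mean, shrinking the visual separation; ``tint_strength=1`` collapses
the two components (a null control where no image model can recover the
ratio).  A linear illumination gradient and pixel noise emulate uneven
lighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PARTS",
    "STUDY_RATIOS",
    "SampleMeta",
    "RenderConfig",
    "generate_sample_metadata",
    "render_sample_image",
    "render_study",
    "generate_study",
    "pork_axis_projection",
    "dish_mask",
]

PARTS = ("back", "front_leg", "hind_leg")
STUDY_RATIOS = (0.10, 0.20, 0.30, 0.40)


@dataclass(frozen=True)
class SampleMeta:
    """Ground-truth descriptor of one dish sample."""

    part: str
    ratio: float
    replicate: int
    sample_id: str

    def __post_init__(self):
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError(f"ratio must be in [0,1], got {self.ratio}")
        if self.replicate < 1:
            raise ValueError("replicate numbering starts at 1")


def _default_pork_colors():
    # raw pork is paler/pinker than mutton, with a mild cut-to-cut offset
    return {
        "back": ((205.0, 132.0, 126.0), (8.0, 6.0, 6.0)),
        "front_leg": ((196.0, 117.0, 110.0), (8.0, 6.0, 6.0)),
        "hind_leg": ((187.0, 103.0, 96.0), (8.0, 6.0, 6.0)),
    }


@dataclass
class RenderConfig:
    """Everything the renderer needs; defaults emulate the study's dishes."""

    image_size: int = 672
    dish_radius_frac: float = 0.85
    granule_radius_px: tuple = (6.0, 12.0)
    mutton_color: tuple = ((158.0, 62.0, 58.0), (8.0, 6.0, 6.0))
    pork_color_by_part: dict = field(default_factory=_default_pork_colors)
    tint_strength: float = 0.35
    illumination_gradient_amp: float = 0.08
    background_color: tuple = (30.0, 28.0, 26.0)
    noise_std: float = 3.0

    def __post_init__(self):
        r0, r1 = self.granule_radius_px
        if not 0 < r0 <= r1:
            raise ValueError("granule radii must be positive and ordered")
        if r1 >= self.dish_radius_px:
            raise ValueError("granules must be smaller than the dish")
        if not 0.0 <= self.tint_strength <= 1.0:
            raise ValueError("tint_strength must be in [0,1]")
        for part in PARTS:
            if part in self.pork_color_by_part and self.tint_strength < 1.0:
                if np.allclose(self.tinted_pork_mean(part), np.asarray(self.mutton_color[0])):
                    raise ValueError("pork and mutton means coincide; no signal to learn")

    @property
    def dish_radius_px(self) -> float:
        return self.dish_radius_frac * self.image_size / 2.0

    def tinted_pork_mean(self, part: str) -> np.ndarray:
        """Pork mean after the essence/colorant tint (convex shift toward mutton)."""
        pork = np.asarray(self.pork_color_by_part[part][0], dtype=float)
        mutton = np.asarray(self.mutton_color[0], dtype=float)
        return pork + self.tint_strength * (mutton - pork)

    def desk_scale(self, image_size: int = 224) -> "RenderConfig":
        """Same dish, rendered smaller (granule scale kept at ~5-8% of dish radius)."""
        scale = image_size / self.image_size
        r0, r1 = self.granule_radius_px
        return replace(self, image_size=image_size,
                       granule_radius_px=(max(1.5, r0 * scale), max(2.5, r1 * scale)))


def generate_sample_metadata(n_replicates: int, ratios=STUDY_RATIOS, parts=PARTS,
                             seed: int = 42) -> list:
    """The full-factorial sample table: n_replicates x |ratios| x |parts| records."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ratios = tuple(ratios)
    parts = tuple(parts)
    if not ratios or not parts:
        raise ValueError("ratios and parts must be non-empty")
    if any(not 0.0 <= r <= 1.0 for r in ratios):
        raise ValueError("ratios must lie in [0,1]")
    metas = []
    for part in parts:
        for ratio in ratios:
            for rep in range(1, n_replicates + 1):
                sid = f"{part}_r{int(round(ratio * 100)):03d}_{rep:02d}"
                metas.append(SampleMeta(part=part, ratio=float(ratio), replicate=rep,
                                        sample_id=sid))
    if len({m.sample_id for m in metas}) != len(metas):
        raise ValueError("ratios too close to distinguish at 0.1% resolution")
    return metas


def _place_granules(rng: np.random.Generator, cfg: RenderConfig):
    """Dart-throwing with a neighbour grid; granules may touch but not pile up."""
    size = cfg.image_size
    center = size / 2.0
    R = cfg.dish_radius_px
    r0, r1 = cfg.granule_radius_px
    cell = r1
    grid: dict = {}
    granules = []
    consecutive_fails = 0
    max_granules = int(3.0 * (R / r0) ** 2)
    while consecutive_fails < 250 and len(granules) < max_granules:
        r = rng.uniform(r0, r1)
        ang = rng.uniform(0, 2 * np.pi)
        # meat is pressed flat to the rim: granules may overhang and are
        # clipped to the dish circle when painted
        rad = (R - 0.2 * r) * np.sqrt(rng.uniform())
        x = center + rad * np.cos(ang)
        y = center + rad * np.sin(ang)
        gi, gj = int(x // cell), int(y // cell)
        ok = True
        for di in (-2, -1, 0, 1, 2):
            for dj in (-2, -1, 0, 1, 2):
                for (ox, oy, orad) in grid.get((gi + di, gj + dj), ()):
                    if (x - ox) ** 2 + (y - oy) ** 2 < (0.75 * (r + orad)) ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            granules.append((x, y, r))
            grid.setdefault((gi, gj), []).append((x, y, r))
            consecutive_fails = 0
        else:
            consecutive_fails += 1
    return granules


def dish_mask(cfg: RenderConfig) -> np.ndarray:
    size = cfg.image_size
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2.0
    return (xx - c) ** 2 + (yy - c) ** 2 <= cfg.dish_radius_px ** 2


def render_sample_image(meta: SampleMeta, cfg: RenderConfig, seed: int) -> np.ndarray:
    """Render one dish as an (H, W, 3) uint8 array; bit-identical for equal inputs."""
    if meta.part not in cfg.pork_color_by_part:
        raise ValueError(f"no pork colour configured for part {meta.part!r}")
    rng = np.random.default_rng(seed)
    size = cfg.image_size
    img = np.empty((size, size, 3), dtype=np.float32)
    img[:] = np.asarray(cfg.background_color, dtype=np.float32)

    mutton_mean = np.asarray(cfg.mutton_color[0], dtype=np.float32)
    mutton_std = np.asarray(cfg.mutton_color[1], dtype=np.float32)
    pork_mean = cfg.tinted_pork_mean(meta.part).astype(np.float32)
    pork_std = np.asarray(cfg.pork_color_by_part[meta.part][1], dtype=np.float32)

    # darkened base fills the crevices between granules
    mask = dish_mask(cfg)
    img[mask] = 0.55 * mutton_mean

    granules = _place_granules(rng, cfg)
    is_pork = rng.random(len(granules)) < meta.ratio
    if meta.ratio <= 0.0:
        is_pork[:] = False
    colors = np.where(
        is_pork[:, None],
        rng.normal(pork_mean, pork_std, (len(granules), 3)),
        rng.normal(mutton_mean, mutton_std, (len(granules), 3)),
    ).astype(np.float32)
    np.clip(colors, 0, 255, out=colors)

    center = size / 2.0
    R2 = cfg.dish_radius_px ** 2
    for (x, y, r), color in zip(granules, colors):
        x0, x1 = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
        y0, y1 = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, size), min(y1, size)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = ((xx - x) ** 2 + (yy - y) ** 2) / (r * r)
        gmask = (d2 <= 1.0) & ((xx - center) ** 2 + (yy - center) ** 2 <= R2)
        shade = (1.0 - 0.18 * d2)[gmask][:, None].astype(np.float32)
        img[y0:y1, x0:x1][gmask] = color * shade

    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    plane = ((xx - size / 2) * np.cos(theta) + (yy - size / 2) * np.sin(theta)) / size
    img *= (1.0 + cfg.illumination_gradient_amp * plane)[:, :, None].astype(np.float32)
    img += rng.normal(0.0, cfg.noise_std, img.shape).astype(np.float32)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _per_sample_seeds(seed: int, n: int) -> list:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def render_study(metas, cfg: RenderConfig, seed: int = 42) -> dict:
    """In-memory study: ``{sample_id: image array}`` with per-sample derived seeds."""
    seeds = _per_sample_seeds(seed, len(metas))
    return {m.sample_id: render_sample_image(m, cfg, s) for m, s in zip(metas, seeds)}


def generate_study(cfg: RenderConfig, n_replicates: int = 8, seed: int = 42,
                   out_dir=None, ratios=STUDY_RATIOS, parts=PARTS) -> pd.DataFrame:
    """Render the full factorial study to ``out_dir`` and return the metadata table.

    Writes one PNG per sample plus ``metadata.csv`` with columns
    sample_id, part, ratio, replicate, path.
    """
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    metas = generate_sample_metadata(n_replicates, ratios, parts, seed)
    seeds = _per_sample_seeds(seed, len(metas))
    rows = []
    for m, s in zip(metas, seeds):
        img = render_sample_image(m, cfg, s)
        path = out_dir / f"{m.sample_id}.png"
        Image.fromarray(img).save(path)
        rows.append({"sample_id": m.sample_id, "part": m.part, "ratio": m.ratio,
                     "replicate": m.replicate, "path": str(path)})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "metadata.csv", index=False)
    return table


def pork_axis_projection(image: np.ndarray, cfg: RenderConfig, part: str) -> float:
    """Mean projection of dish pixels onto the tinted pork - mutton colour axis.

    A scalar "pork-likeness" statistic: zero-mean around pure mutton,
    increasing with the pork fraction as long as the tint has not collapsed
    the two colour distributions.
    """
    mutton = np.asarray(cfg.mutton_color[0], dtype=np.float64)
    # untinted axis: the tint moves pork along this same line, so the
    # direction is valid for every tint and non-degenerate at tint = 1
    axis = np.asarray(cfg.pork_color_by_part[part][0], dtype=np.float64) - mutton
    axis = axis / np.linalg.norm(axis)
    mask = dish_mask(cfg)
    pixels = image[mask].astype(np.float64)
    return float(((pixels - mutton) @ axis).mean())
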