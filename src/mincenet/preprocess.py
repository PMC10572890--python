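"""ROI extraction and image augmentation.

The dish is isolated with a circular Hough transform (Canny edges, peak
circle vote), refined at full resolution with an algebraic least-squares
circle fit, cropped to the circle's bounding square with the outside set to
black.  Augmentation mirrors the acquisition protocol: threshold-gated
random rotation (two uniform draws: a 0.3 gate and an angle fraction of
360 deg), mirroring, and threshold-gated multiplicative brightness jitter;
all augmented outputs are resized (area averaging) to the network input
size, 224 px by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks, resize as sk_resize

__all__ = [
    "AugmentationConfig",
    "RoiCircle",
    "RoiDetectionError",
    "augment_to_count",
    "extract_roi",
    "jitter_brightness",
    "mirror",
    "random_rotate",
    "resize_image",
]


class RoiDetectionError(RuntimeError):
    """No circular dish could be detected in the image."""


@dataclass(frozen=True)
class RoiCircle:
    center_x: float
    center_y: float
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class AugmentationConfig:
    rotation_threshold: float = 0.3
    brightness_threshold: float = 0.3
    brightness_factor_range: tuple = (0.7, 1.3)
    mirror_axes: tuple = ("horizontal", "vertical")
    target_size: int = 224

    def __post_init__(self):
        if not 0.0 <= self.rotation_threshold <= 1.0:
            raise ValueError("rotation_threshold must be in [0,1]")
        if not 0.0 <= self.brightness_threshold <= 1.0:
            raise ValueError("brightness_threshold must be in [0,1]")
        lo, hi = self.brightness_factor_range
        if not 0 < lo < hi:
            raise ValueError("brightness factor range must be positive with lower < upper")
        if not set(self.mirror_axes) <= {"horizontal", "vertical"} or not self.mirror_axes:
            raise ValueError("mirror_axes must be a non-empty subset of {horizontal, vertical}")


def _kasa_circle_fit(xs: np.ndarray, ys: np.ndarray):
    """Algebraic least-squares circle through edge points."""
    a = np.column_stack([xs, ys, np.ones_like(xs)])
    b = xs ** 2 + ys ** 2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx ** 2 + cy ** 2
    if r2 <= 0:
        return None
    return cx, cy, float(np.sqrt(r2))


def _rim_refine(gray: np.ndarray, cx: float, cy: float, r: float,
                window: float = 0.15, n_angles: int = 256):
    """Refine a coarse circle against the dish rim.

    Along each of ``n_angles`` rays the rim is the steepest intensity drop
    within ``(1 +/- window) * r``; a least-squares circle through those rim
    points updates centre and radius.  Intensity-profile based, so interior
    granule texture does not pull the fit the way raw edge maps do.
    """
    h, w = gray.shape
    r_grid = np.arange(max(2.0, (1 - window) * r), (1 + window) * r + 1.0, 0.5)
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    xs = cx + r_grid[:, None] * np.cos(theta)[None, :]
    ys = cy + r_grid[:, None] * np.sin(theta)[None, :]
    xi = np.clip(np.rint(xs).astype(int), 0, w - 1)
    yi = np.clip(np.rint(ys).astype(int), 0, h - 1)
    samples = gray[yi, xi]
    # 3-tap box smoothing along the radial axis, then per-angle steepest drop
    sm = samples.copy()
    sm[1:-1] = (samples[:-2] + samples[1:-1] + samples[2:]) / 3.0
    grad = np.gradient(sm, axis=0)
    k = grad.argmin(axis=0).astype(float)
    inner = (k > 0) & (k < len(r_grid) - 1)
    ki = k[inner].astype(int)
    cols = np.nonzero(inner)[0]
    denom = grad[ki - 1, cols] - 2 * grad[ki, cols] + grad[ki + 1, cols]
    shift = np.where(np.abs(denom) > 1e-12,
                     0.5 * (grad[ki - 1, cols] - grad[ki + 1, cols]) / np.where(denom == 0, 1, denom),
                     0.0)
    k[inner] = ki + np.clip(shift, -0.5, 0.5)
    r_theta = np.interp(k, np.arange(len(r_grid)), r_grid)
    # trim rays that locked onto interior crevices instead of the rim
    med = np.median(r_theta)
    mad = np.median(np.abs(r_theta - med)) + 1e-9
    keep = np.abs(r_theta - med) < max(3.0 * mad, 1.0)
    if keep.sum() < 16:
        return cx, cy, r
    fit = _kasa_circle_fit(cx + r_theta[keep] * np.cos(theta[keep]),
                           cy + r_theta[keep] * np.sin(theta[keep]))
    if fit is None:
        return cx, cy, r
    return fit


def _ring_mean(gray: np.ndarray, cx: float, cy: float, radii, n_angles: int = 128) -> float:
    h, w = gray.shape
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    rr = np.asarray(radii)[:, None]
    xi = np.clip(np.rint(cx + rr * np.cos(theta)).astype(int), 0, w - 1)
    yi = np.clip(np.rint(cy + rr * np.sin(theta)).astype(int), 0, h - 1)
    return float(gray[yi, xi].mean())


def _rim_contrast(gray: np.ndarray, cx: float, cy: float, r: float) -> float:
    """Mean intensity just inside the circle minus just outside it."""
    inner = _ring_mean(gray, cx, cy, np.linspace(0.88 * r, 0.96 * r, 5))
    outer = _ring_mean(gray, cx, cy, np.linspace(1.04 * r, 1.15 * r, 5))
    return inner - outer


def extract_roi(image: np.ndarray, min_radius_frac: float = 0.25,
                max_radius_frac: float = 0.5, detect_size: int = 160,
                canny_sigma: float = 2.0, min_accum: float = 0.2,
                n_radii: int = 24):
    """Detect the dish circle, crop its bounding square, black out the outside.

    Returns ``(cropped_image, RoiCircle)`` with the circle in original image
    coordinates.  Raises :class:`RoiDetectionError` when no circle scores at
    least ``min_accum`` (fraction of perimeter supported by edges); callers
    may fall back to a centre crop.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    h, w = image.shape[:2]
    gray = image.mean(axis=2) / 255.0

    scale = min(1.0, detect_size / max(h, w))
    if scale < 1.0:
        small = sk_resize(gray, (int(round(h * scale)), int(round(w * scale))),
                          anti_aliasing=True)
    else:
        small = gray
    edges = canny(small, sigma=canny_sigma)
    if edges.sum() < 16:
        raise RoiDetectionError("no edge structure in image")
    min_dim = min(small.shape)
    radii = np.unique(np.linspace(min_radius_frac * min_dim, max_radius_frac * min_dim,
                                  n_radii).astype(int))
    radii = radii[radii >= 3]
    accum = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(accum, radii, total_num_peaks=5)
    keep = [k for k in range(len(accums)) if accums[k] >= min_accum]
    if not keep:
        raise RoiDetectionError("no circular region with sufficient support")

    # refine every surviving peak at full resolution and keep the candidate
    # whose rim shows the strongest inside-vs-outside intensity step; texture
    # inside the dish can out-vote the true rim in the raw accumulator
    best, best_score = None, -np.inf
    for k in keep:
        cx, cy, r = cxs[k] / scale, cys[k] / scale, rads[k] / scale
        for window in (0.15, 0.05):
            cx, cy, r = _rim_refine(gray, cx, cy, r, window=window)
        score = _rim_contrast(gray, cx, cy, r)
        if score > best_score:
            best, best_score = (cx, cy, r), score
    if best_score < 0.02:  # gray units in [0,1]: no real inside/outside step
        raise RoiDetectionError("no circular region with a convincing rim")
    cx, cy, r = best

    r = float(min(r, cx, cy, w - 1 - cx, h - 1 - cy))
    if r <= 0:
        raise RoiDetectionError("detected circle lies outside the image")
    circle = RoiCircle(float(cx), float(cy), r)

    side = int(round(2 * r))
    x0 = min(max(int(round(cx - r)), 0), w - side)
    y0 = min(max(int(round(cy - r)), 0), h - side)
    x1, y1 = x0 + side, y0 + side
    crop = image[y0:y1, x0:x1].copy()
    ch, cw = crop.shape[:2]
    yy, xx = np.mgrid[0:ch, 0:cw]
    outside = (xx - (cx - x0)) ** 2 + (yy - (cy - y0)) ** 2 > r * r
    crop[outside] = 0
    return crop, circle


def random_rotate(image: np.ndarray, cfg: AugmentationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Gate on u1 > threshold, then rotate about the centre by 360*u2 degrees.

    Both uniforms are always drawn so the consumed randomness is independent
    of the outcome.  Exact quarter-turn angles take the lossless ``rot90``
    path; everything else is bilinear with black fill.
    """
    if image.shape[0] != image.shape[1]:
        raise ValueError("random_rotate expects a square image")
    u1, u2 = rng.random(), rng.random()
    if u1 <= cfg.rotation_threshold:
        return image.copy()
    angle = 360.0 * u2
    quarter, rem = divmod(angle, 90.0)
    if rem == 0.0:
        return np.ascontiguousarray(np.rot90(image, int(quarter) % 4))
    out = Image.fromarray(image).rotate(angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    return np.asarray(out)


def mirror(image: np.ndarray, axis: str) -> np.ndarray:
    if axis == "horizontal":
        return np.ascontiguousarray(image[:, ::-1])
    if axis == "vertical":
        return np.ascontiguousarray(image[::-1])
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def jitter_brightness(image: np.ndarray, cfg: AugmentationConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Gate on u1 > threshold, then scale all channels by a factor from the range."""
    u1, u2 = rng.random(), rng.random()
    if u1 <= cfg.brightness_threshold:
        return image.copy()
    lo, hi = cfg.brightness_factor_range
    factor = lo + u2 * (hi - lo)
    return np.clip(np.rint(image.astype(np.float32) * factor), 0, 255).astype(np.uint8)


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Area-averaging downscale to ``size x size`` (PIL BOX filter)."""
    if image.shape[0] == size and image.shape[1] == size:
        return image.copy()
    return np.asarray(Image.fromarray(image).resize((size, size), Image.Resampling.BOX))


def _augment_chain(image: np.ndarray, cfg: AugmentationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    out = jitter_brightness(image, cfg, rng)
    out = random_rotate(out, cfg, rng)
    axis = cfg.mirror_axes[int(rng.integers(len(cfg.mirror_axes)))]
    return mirror(out, axis)


def augment_to_count(images, target_count: int, cfg: AugmentationConfig,
                     rng: np.random.Generator, with_provenance: bool = False):
    """Expand a batch to exactly ``target_count`` resized images.

    The originals come first (resized only); augmented copies are produced by
    cycling over the originals and applying brightness jitter, gated rotation
    and a random mirror, in that order.  With ``with_provenance=True`` also
    returns the source index of every output image.
    """
    images = list(images)
    if not images:
        raise ValueError("images must be non-empty")
    if target_count < len(images):
        raise ValueError(f"target_count {target_count} < number of originals {len(images)}")
    out = [resize_image(im, cfg.target_size) for im in images]
    sources = list(range(len(images)))
    i = 0
    while len(out) < target_count:
        src = i % len(images)
        out.append(resize_image(_augment_chain(images[src], cfg, rng), cfg.target_size))
        sources.append(src)
        i += 1
    if with_provenance:
        return out, sources
    return out
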