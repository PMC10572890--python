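"""ROI extraction and the augmentation chain."""

import numpy as np
import pytest

from mincenet.preprocess import (
    AugmentationConfig,
    RoiDetectionError,
    augment_to_count,
    extract_roi,
    jitter_brightness,
    mirror,
    random_rotate,
    resize_image,
)
from mincenet.synthetic import RenderConfig, SampleMeta, render_sample_image


class FakeRng:
    """Feeds a scripted sequence of uniforms / integer draws."""

    def __init__(self, uniforms, integers=()):
        self._u = list(uniforms)
        self._i = list(integers)

    def random(self):
        return self._u.pop(0)

    def integers(self, n):
        return self._i.pop(0) % n


@pytest.fixture(scope="module")
def dish_672():
    cfg = RenderConfig()  # full-resolution study default
    img = render_sample_image(SampleMeta("back", 0.2, 1, "s"), cfg, seed=3)
    return img, cfg


# ---------------------------------------------------------------------------
# ROI


def test_roi_recovers_known_circle_at_full_resolution(dish_672):
    img, cfg = dish_672
    crop, circle = extract_roi(img)
    true_center = cfg.image_size / 2
    assert abs(circle.center_x - true_center) <= 2.0
    assert abs(circle.center_y - true_center) <= 2.0
    assert abs(circle.radius - cfg.dish_radius_px) / cfg.dish_radius_px <= 0.03
    # crop is the bounding square of the circle
    assert crop.shape[0] == crop.shape[1]
    assert abs(crop.shape[0] - 2 * circle.radius) <= 1.0
    # pixels outside the circle are blacked out
    assert crop[0, 0].sum() == 0 and crop[-1, -1].sum() == 0


def test_roi_uniform_image_fails():
    with pytest.raises(RoiDetectionError):
        extract_roi(np.full((300, 300, 3), 128, dtype=np.uint8))


def test_roi_rejects_non_rgb():
    with pytest.raises(ValueError):
        extract_roi(np.zeros((64, 64), dtype=np.uint8))


def test_roi_recovers_circles_for_random_render_configs(rng):
    """Property: detection within tolerance over 100 randomised dish configs."""
    failures = []
    for i in range(100):
        size = int(rng.integers(140, 200))
        frac = float(rng.uniform(0.55, 0.92))
        cfg = RenderConfig(
            image_size=size,
            dish_radius_frac=frac,
            granule_radius_px=(float(rng.uniform(1.5, 2.5)), float(rng.uniform(3.0, 5.0))),
            tint_strength=float(rng.uniform(0.0, 0.8)),
            illumination_gradient_amp=float(rng.uniform(0.0, 0.12)),
            noise_std=float(rng.uniform(0.5, 4.0)),
        )
        ratio = float(rng.choice([0.1, 0.2, 0.3, 0.4]))
        img = render_sample_image(SampleMeta("back", ratio, 1, "p"), cfg, seed=int(i))
        try:
            _, c = extract_roi(img, min_radius_frac=0.2, max_radius_frac=0.5)
        except RoiDetectionError:
            failures.append((i, "not detected"))
            continue
        if (abs(c.center_x - size / 2) > 2 or abs(c.center_y - size / 2) > 2
                or abs(c.radius - cfg.dish_radius_px) / cfg.dish_radius_px > 0.03):
            failures.append((i, c))
    assert not failures, failures[:5]


# ---------------------------------------------------------------------------
# rotation


def test_rotation_gate_below_threshold_is_identity(rng):
    img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
    out = random_rotate(img, AugmentationConfig(), FakeRng([0.2, 0.77]))
    assert np.array_equal(out, img)
    # ties do not rotate: the gate is strictly greater-than
    out = random_rotate(img, AugmentationConfig(), FakeRng([0.3, 0.77]))
    assert np.array_equal(out, img)


def test_rotation_by_half_turn_equals_double_mirror(rng):
    img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
    out = random_rotate(img, AugmentationConfig(), FakeRng([0.9, 0.5]))  # 180 deg
    assert np.array_equal(out, mirror(mirror(img, "horizontal"), "vertical"))


def test_rotation_by_full_turn_is_identity(dish_672):
    img = resize_image(dish_672[0], 128)
    out = random_rotate(img, AugmentationConfig(), FakeRng([0.9, 1.0 - 1e-12]))
    assert np.abs(out.astype(int) - img.astype(int)).max() <= 2


def test_rotation_requires_square():
    with pytest.raises(ValueError):
        random_rotate(np.zeros((4, 6, 3), dtype=np.uint8), AugmentationConfig(),
                      FakeRng([0.9, 0.3]))


# ---------------------------------------------------------------------------
# mirroring


def test_mirror_involution_and_histogram(rng):
    img = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
    for axis in ("horizontal", "vertical"):
        assert np.array_equal(mirror(mirror(img, axis), axis), img)
        for ch in range(3):
            assert np.array_equal(np.bincount(img[..., ch].ravel(), minlength=256),
                                  np.bincount(mirror(img, axis)[..., ch].ravel(),
                                              minlength=256))


def test_mirror_2x2_example():
    img = np.array([[[1], [2]], [[3], [4]]], dtype=np.uint8).repeat(3, axis=2)
    assert np.array_equal(mirror(img, "horizontal")[..., 0], [[2, 1], [4, 3]])
    assert np.array_equal(mirror(img, "vertical")[..., 0], [[3, 4], [1, 2]])


def test_mirror_invalid_axis():
    with pytest.raises(ValueError):
        mirror(np.zeros((2, 2, 3), dtype=np.uint8), "diagonal")


# ---------------------------------------------------------------------------
# brightness


def test_brightness_gate_and_identity_factor(rng):
    img = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
    cfg = AugmentationConfig()
    assert np.array_equal(jitter_brightness(img, cfg, FakeRng([0.1, 0.9])), img)
    # u2 at the midpoint of [0.7, 1.3] gives factor exactly 1.0
    assert np.array_equal(jitter_brightness(img, cfg, FakeRng([0.9, 0.5])), img)


def test_brightness_factor_arithmetic():
    img = np.full((8, 8, 3), 128, dtype=np.uint8)
    out = jitter_brightness(img, AugmentationConfig(), FakeRng([0.9, 1.0]))  # factor 1.3
    assert np.all(out == 166)  # round(128 * 1.3)


def test_brightness_clips_to_8bit():
    img = np.full((4, 4, 3), 250, dtype=np.uint8)
    out = jitter_brightness(img, AugmentationConfig(), FakeRng([0.9, 1.0]))
    assert out.max() == 255 and out.dtype == np.uint8


# ---------------------------------------------------------------------------
# count-driven expansion


def test_augment_to_count_reaches_exact_target(rng):
    imgs = [(rng.random((50, 50, 3)) * 255).astype(np.uint8) for _ in range(16)]
    cfg = AugmentationConfig(target_size=64)
    out = augment_to_count(imgs, 100, cfg, np.random.default_rng(0))
    assert len(out) == 100
    assert all(o.shape == (64, 64, 3) and o.dtype == np.uint8 for o in out)


def test_augment_to_count_originals_only(rng):
    imgs = [(rng.random((40, 40, 3)) * 255).astype(np.uint8) for _ in range(5)]
    cfg = AugmentationConfig(target_size=32)
    out = augment_to_count(imgs, 5, cfg, np.random.default_rng(0))
    assert len(out) == 5
    for src, o in zip(imgs, out):
        assert np.array_equal(o, resize_image(src, 32))


def test_augment_to_count_deterministic(rng):
    imgs = [(rng.random((40, 40, 3)) * 255).astype(np.uint8) for _ in range(3)]
    cfg = AugmentationConfig(target_size=32)
    a = augment_to_count(imgs, 20, cfg, np.random.default_rng(7))
    b = augment_to_count(imgs, 20, cfg, np.random.default_rng(7))
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_augment_to_count_errors(rng):
    cfg = AugmentationConfig(target_size=32)
    with pytest.raises(ValueError):
        augment_to_count([], 5, cfg, np.random.default_rng(0))
    img = (rng.random((40, 40, 3)) * 255).astype(np.uint8)
    with pytest.raises(ValueError):
        augment_to_count([img, img], 1, cfg, np.random.default_rng(0))


def test_augmentation_config_validation():
    with pytest.raises(ValueError):
        AugmentationConfig(rotation_threshold=1.2)
    with pytest.raises(ValueError):
        AugmentationConfig(brightness_factor_range=(1.3, 0.7))
    with pytest.raises(ValueError):
        AugmentationConfig(mirror_axes=("diagonal",))
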