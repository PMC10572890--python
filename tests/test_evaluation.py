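"""Metric and boxplot statistics, pinned against hand-computed oracles.

The R^2 here is the study's ratio-of-sums form and the RMSE divides by n-1;
the worked examples below were computed by hand from those definitions.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mincenet.evaluation import (
    BoxplotStats,
    UndefinedMetricError,
    boxplot_stats,
    evaluate_model,
    r_squared,
    rmse,
)
from mincenet.pipeline import ImageDataset


# ---------------------------------------------------------------------------
# R^2 (ratio-of-sums form)


def hand_r_squared(pred, actual):
    """Independent oracle: literal sum-by-sum evaluation with math.fsum."""
    xbar = math.fsum(actual) / len(actual)
    num = math.fsum((p - xbar) ** 2 for p in pred)
    den = math.fsum((a - xbar) ** 2 for a in actual)
    return num / den


@pytest.mark.parametrize(
    "pred, actual, expected",
    [
        ([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4], 1.0),
        ([0.25, 0.25, 0.25, 0.25], [0.1, 0.2, 0.3, 0.4], 0.0),
        ([0.15, 0.25, 0.25, 0.35], [0.1, 0.2, 0.3, 0.4], 0.4),  # 0.02 / 0.05
    ],
)
def test_r_squared_worked_examples(pred, actual, expected):
    assert r_squared(pred, actual) == pytest.approx(expected, abs=1e-9)


def test_r_squared_matches_hand_oracle_on_random_vectors(rng):
    for _ in range(100):
        n = int(rng.integers(3, 40))
        actual = rng.random(n)
        pred = rng.random(n)
        assert r_squared(pred, actual) == pytest.approx(
            hand_r_squared(pred, actual), rel=1e-9)


def test_r_squared_is_not_one_minus_ssres(rng):
    # the ratio-of-sums form rewards matching the spread, not the residuals:
    # overdispersed predictions can exceed 1
    actual = np.array([0.1, 0.2, 0.3, 0.4])
    wild = np.array([-0.5, 0.9, -0.3, 1.2])
    assert r_squared(wild, actual) > 1.0


def test_r_squared_errors():
    with pytest.raises(UndefinedMetricError):
        r_squared([0.1, 0.2], [0.3, 0.3])
    with pytest.raises(ValueError):
        r_squared([0.1], [0.2])


# ---------------------------------------------------------------------------
# RMSE with n-1 divisor


def test_rmse_worked_examples():
    assert rmse([0.1, 0.2], [0.1, 0.2]) == 0.0
    assert rmse([0.15, 0.25, 0.25, 0.35], [0.1, 0.2, 0.3, 0.4]) == pytest.approx(
        math.sqrt(0.01 / 3), abs=1e-9)


@pytest.mark.parametrize("e,n", [(0.05, 4), (0.2, 7), (-0.1, 3)])
def test_rmse_constant_error_closed_form(e, n):
    actual = np.linspace(0.1, 0.4, n)
    assert rmse(actual + e, actual) == pytest.approx(
        abs(e) * math.sqrt(n / (n - 1)), rel=1e-9)


def test_rmse_scales_linearly_with_error(rng):
    actual = rng.random(10)
    err = rng.standard_normal(10)
    base = rmse(actual + err, actual)
    assert rmse(actual + 3 * err, actual) == pytest.approx(3 * base, rel=1e-9)


def test_rmse_needs_two_points():
    with pytest.raises(ValueError):
        rmse([0.1], [0.2])


# ---------------------------------------------------------------------------
# boxplot statistics (1 x IQR whiskers)


def hand_boxplot(values, whisker=1.0):
    """Brute-force oracle: quartiles by linear interpolation of order statistics."""
    v = sorted(values)
    n = len(v)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return v[lo] * (1 - frac) + v[hi] * frac

    q1, q2, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    iqr = q3 - q1
    return q1, q2, q3, iqr, q1 - whisker * iqr, q3 + whisker * iqr


def test_boxplot_worked_example():
    s = boxplot_stats([0.1, 0.2, 0.3, 0.4])
    assert s.q1 == pytest.approx(0.175, abs=1e-9)
    assert s.q2 == pytest.approx(0.25, abs=1e-9)
    assert s.q3 == pytest.approx(0.325, abs=1e-9)
    assert s.iqr == pytest.approx(0.15, abs=1e-9)
    assert s.whisker_min == pytest.approx(0.025, abs=1e-9)
    assert s.whisker_max == pytest.approx(0.475, abs=1e-9)
    assert s.outliers == ()


def test_boxplot_constant_values():
    s = boxplot_stats([0.3] * 6)
    assert (s.q1, s.q2, s.q3, s.iqr) == (0.3, 0.3, 0.3, 0.0)
    assert s.whisker_min == s.whisker_max == 0.3
    assert s.outliers == ()


def test_boxplot_matches_bruteforce_on_all_small_subsets():
    base = [0.12, 0.18, 0.22, 0.25, 0.31, 0.33, 0.40, 0.55]
    for size in range(4, 9):
        for subset in itertools.combinations(base, size):
            s = boxplot_stats(subset)
            q1, q2, q3, iqr, wmin, wmax = hand_boxplot(subset)
            for got, want in [(s.q1, q1), (s.q2, q2), (s.q3, q3), (s.iqr, iqr),
                              (s.whisker_min, wmin), (s.whisker_max, wmax)]:
                assert got == pytest.approx(want, abs=1e-12)


@given(st.lists(st.floats(-100, 100), min_size=4, max_size=20),
       st.floats(0.1, 5.0), st.floats(-50, 50))
def test_boxplot_affine_equivariance(values, a, b):
    s = boxplot_stats(values)
    t = boxplot_stats([a * v + b for v in values])
    for got, want in [(t.q1, a * s.q1 + b), (t.q2, a * s.q2 + b), (t.q3, a * s.q3 + b),
                      (t.whisker_min, a * s.whisker_min + b),
                      (t.whisker_max, a * s.whisker_max + b)]:
        assert got == pytest.approx(want, abs=1e-7 * (1 + abs(want)))


def test_boxplot_outliers_outside_one_iqr():
    s = boxplot_stats([0.1, 0.2, 0.21, 0.22, 0.23, 0.9])
    assert 0.9 in s.outliers and 0.1 in s.outliers


def test_boxplot_order_invariant():
    with pytest.raises(ValueError):
        boxplot_stats([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        BoxplotStats(q1=1, q2=0, q3=2, iqr=1, whisker_min=0, whisker_max=3, outliers=())


# ---------------------------------------------------------------------------
# report generation


class MeanBrightnessModel:
    """Predicts the mean pixel value; perfect on constant-valued images."""

    def forward(self, x, training=False):
        return x.mean(axis=(1, 2, 3))


def _constant_image_dataset():
    ratios = np.repeat([0.1, 0.2, 0.3, 0.4], 5)
    images = np.stack([np.full((3, 8, 8), r, dtype=np.float32) for r in ratios])
    return ImageDataset(images, ratios, name="constant")


def test_evaluate_model_perfect_predictor(tmp_path):
    ds = _constant_image_dataset()
    report = evaluate_model(MeanBrightnessModel(), ds, dataset_name="constant",
                            split="validation", out_json=tmp_path / "report.json",
                            out_figure=tmp_path / "box.png")
    assert report.r_squared == pytest.approx(1.0, abs=1e-6)
    assert report.rmse == pytest.approx(0.0, abs=1e-6)
    assert report.n == len(ds)
    assert len(report.per_ratio) == 4
    for ratio, stats in report.per_ratio.items():
        assert stats.q2 == pytest.approx(ratio, abs=1e-6)
    assert (tmp_path / "report.json").exists()
    assert (tmp_path / "box.png").exists()


def test_evaluate_model_empty_split_rejected():
    ds = _constant_image_dataset()
    ds.images = ds.images[:0]
    ds.labels = ds.labels[:0]
    ds.sample_ids = []
    with pytest.raises(ValueError):
        evaluate_model(MeanBrightnessModel(), ds)
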