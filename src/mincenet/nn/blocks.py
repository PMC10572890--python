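"""Composite blocks: ResNet bottleneck, inverted residual, and CBAM attention."""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    Layer,
    Parameter,
    ReLU,
    ReLU6,
    Sequential,
    he_normal,
)

__all__ = ["BottleneckBlock", "InvertedResidualBlock", "CBAM"]


class BottleneckBlock(Layer):
    """ResNet50 bottleneck: 1x1 reduce -> 3x3 -> 1x1 expand to 4*c_mid, additive skip.

    A 1x1 projection shortcut is used whenever the skip shapes mismatch (or when
    ``projection_shortcut=True`` forces one, as in the first block of a stage).
    """

    def __init__(self, c_in, c_mid, stride=1, projection_shortcut=None,
                 rng: np.random.Generator | None = None):
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        if c_in <= 0 or c_mid <= 0:
            raise ValueError("channel counts must be positive")
        rng = rng or np.random.default_rng(0)
        c_out = 4 * c_mid
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.branch = Sequential(
            Conv2d(c_in, c_mid, 1, rng=rng), BatchNorm2d(c_mid), ReLU(),
            Conv2d(c_mid, c_mid, 3, stride=stride, padding=1, rng=rng), BatchNorm2d(c_mid), ReLU(),
            Conv2d(c_mid, c_out, 1, rng=rng), BatchNorm2d(c_out),
        )
        if projection_shortcut is None:
            projection_shortcut = stride != 1 or c_in != c_out
        self.shortcut = (
            Sequential(Conv2d(c_in, c_out, 1, stride=stride, rng=rng), BatchNorm2d(c_out))
            if projection_shortcut
            else None
        )

    def sublayers(self):
        subs = [("branch", self.branch)]
        if self.shortcut is not None:
            subs.append(("shortcut", self.shortcut))
        return subs

    def forward(self, x, training=False):
        b = self.branch.forward(x, training=training)
        s = self.shortcut.forward(x, training=training) if self.shortcut is not None else x
        pre = b + s
        self._mask = pre > 0 if training else None
        return np.maximum(pre, 0)

    def backward(self, dy):
        dpre = dy * self._mask
        dx = self.branch.backward(dpre)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(dpre)
        else:
            dx = dx + dpre
        return dx


class InvertedResidualBlock(Layer):
    """Expand -> depthwise -> linear project, the wide layer in the middle.

    ``hidden`` defaults to ``t * c_in`` (the MobileNetV2 convention).  The
    network builder instead passes ``hidden = t * c_out`` so that the wide
    width mirrors the 4x-expanded output width of the bottleneck it replaces,
    and requests an explicit projection shortcut on stage-leading blocks.

    skip: "auto" (identity iff stride 1 and c_in == c_out), "projection",
    "identity", or "none".
    """

    def __init__(self, c_in, c_out, t=4, stride=1, hidden=None, skip="auto",
                 dw_bias=False, rng: np.random.Generator | None = None):
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        if t < 1:
            raise ValueError("expansion factor must be >= 1")
        rng = rng or np.random.default_rng(0)
        hidden = int(hidden) if hidden is not None else t * c_in
        self.c_in, self.c_out, self.stride, self.hidden = c_in, c_out, stride, hidden
        if skip == "auto":
            skip = "identity" if (stride == 1 and c_in == c_out) else "none"
        if skip == "identity" and (stride != 1 or c_in != c_out):
            raise ValueError("identity skip requires stride 1 and matching channels")
        self.skip = skip
        self.branch = Sequential(
            Conv2d(c_in, hidden, 1, rng=rng), BatchNorm2d(hidden), ReLU6(),
            DepthwiseConv2d(hidden, 3, stride=stride, padding=1, bias=dw_bias, rng=rng),
            BatchNorm2d(hidden), ReLU6(),
            Conv2d(hidden, c_out, 1, rng=rng), BatchNorm2d(c_out),
        )
        self.shortcut = (
            Sequential(Conv2d(c_in, c_out, 1, stride=stride, rng=rng), BatchNorm2d(c_out))
            if skip == "projection"
            else None
        )

    def sublayers(self):
        subs = [("branch", self.branch)]
        if self.shortcut is not None:
            subs.append(("shortcut", self.shortcut))
        return subs

    def forward(self, x, training=False):
        y = self.branch.forward(x, training=training)
        if self.skip == "identity":
            y = y + x
        elif self.skip == "projection":
            y = y + self.shortcut.forward(x, training=training)
        return y

    def backward(self, dy):
        dx = self.branch.backward(dy)
        if self.skip == "identity":
            dx = dx + dy
        elif self.skip == "projection":
            dx = dx + self.shortcut.backward(dy)
        return dx


class CBAM(Layer):
    """Convolutional block attention: channel gate then spatial gate.

    Channel attention pushes both the spatial-average and spatial-max pooled
    descriptors through one shared biased bottleneck MLP (reduction ``r``) and
    gates channels with the sigmoid of their sum.  Spatial attention convolves
    the channelwise average/max maps with a ``k x k`` kernel and gates pixels.
    Output shape always equals input shape.
    """

    def __init__(self, channels, reduction=16, spatial_kernel=7,
                 rng: np.random.Generator | None = None):
        if channels % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide channels {channels}")
        if spatial_kernel % 2 != 1:
            raise ValueError("spatial kernel must be odd")
        rng = rng or np.random.default_rng(0)
        c, mid = int(channels), int(channels // reduction)
        self.channels, self.reduction, self.spatial_kernel = c, int(reduction), int(spatial_kernel)
        self.w1 = Parameter("cbam.mlp1.weight", he_normal(rng, (mid, c), c))
        self.b1 = Parameter("cbam.mlp1.bias", np.zeros(mid, dtype=np.float32))
        self.w2 = Parameter("cbam.mlp2.weight", he_normal(rng, (c, mid), mid))
        self.b2 = Parameter("cbam.mlp2.bias", np.zeros(c, dtype=np.float32))
        self.spatial = Conv2d(2, 1, spatial_kernel, padding=spatial_kernel // 2, rng=rng,
                              name="cbam.spatial")
        self._cache = None

    def own_parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def sublayers(self):
        return [("spatial", self.spatial)]

    def _mlp(self, s):
        h = np.maximum(s @ self.w1.value.T + self.b1.value, 0)
        return h, h @ self.w2.value.T + self.b2.value

    def forward(self, x, training=False):
        n, c, hh, ww = x.shape
        s_avg = x.mean(axis=(2, 3))
        flat = x.reshape(n, c, -1)
        arg_sp = flat.argmax(axis=2)
        s_max = np.take_along_axis(flat, arg_sp[:, :, None], axis=2)[:, :, 0]
        h_a, z_a = self._mlp(s_avg)
        h_m, z_m = self._mlp(s_max)
        a = 1.0 / (1.0 + np.exp(-(z_a + z_m)))
        y = x * a[:, :, None, None]

        c_avg = y.mean(axis=1, keepdims=True)
        arg_ch = y.argmax(axis=1)
        c_max = np.take_along_axis(y, arg_ch[:, None], axis=1)
        u = np.concatenate([c_avg, c_max], axis=1)
        mlogit = self.spatial.forward(u, training=training)
        m = 1.0 / (1.0 + np.exp(-mlogit))
        z = y * m
        if training:
            self._cache = (x, s_avg, s_max, arg_sp, h_a, h_m, a, y, arg_ch, m)
        return z

    def backward(self, dz):
        x, s_avg, s_max, arg_sp, h_a, h_m, a, y, arg_ch, m = self._cache
        n, c, hh, ww = x.shape
        dy = dz * m
        dm = (dz * y).sum(axis=1, keepdims=True)
        dmlogit = dm * m * (1 - m)
        du = self.spatial.backward(dmlogit)
        # channel-average map: spread over channels; channel-max map: scatter to argmax
        dy += du[:, 0:1] / c
        dcmax = du[:, 1:2]
        np.put_along_axis(
            dy, arg_ch[:, None], np.take_along_axis(dy, arg_ch[:, None], axis=1) + dcmax, axis=1
        )

        dx = dy * a[:, :, None, None]
        da = (dy * x).sum(axis=(2, 3))
        dzsum = da * a * (1 - a)  # same gradient flows to both MLP branch outputs

        for h, s, s_name in ((h_a, s_avg, "avg"), (h_m, s_max, "max")):
            self.w2.grad += dzsum.T @ h
            self.b2.grad += dzsum.sum(axis=0)
            dh = (dzsum @ self.w2.value) * (h > 0)
            self.w1.grad += dh.T @ s
            self.b1.grad += dh.sum(axis=0)
            ds = dh @ self.w1.value
            if s_name == "avg":
                dx += ds[:, :, None, None] / (hh * ww)
            else:
                dflat = dx.reshape(n, c, -1)
                np.put_along_axis(
                    dflat, arg_sp[:, :, None],
                    np.take_along_axis(dflat, arg_sp[:, :, None], axis=2) + ds[:, :, None],
                    axis=2,
                )
        return dx
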