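"""The four regression backbones and their exact parameter accounting.

Variants
--------
``resnet50``
    Standard bottleneck backbone (stage widths 256/512/1024/2048) with a
    global-average-pooled single-output regression head.
``invert_resnet50``
    The same skeleton with every bottleneck replaced by an inverted residual
    block: 1x1 expand -> 3x3 depthwise -> 1x1 linear projection.  The wide
    (hidden) width of each block is ``expansion_factor * stage_width``, so it
    mirrors the 4x-expanded width of the bottleneck it replaces, and the first
    block of every stage keeps the skeleton's 1x1 projection shortcut.
``cbam_resnet50`` / ``cbam_invert_resnet50``
    One CBAM attention module (shared biased channel MLP, reduction 16; 7x7
    spatial kernel) immediately after every block, sized to that block's
    output channels.

Parameter accounting follows the Keras ``model.summary()`` convention:
pointwise/full convolutions carry biases, depthwise convolutions do not, and
each batch-norm contributes 2c trainable parameters plus 2c moving statistics
(reported as non-trainable).  ``count_parameters`` recounts everything from
the actual weight array shapes; ``spec_parameter_count`` is the closed-form
companion used by the parameter-budget search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import (
    CBAM,
    Adam,  # noqa: F401  (re-exported convenience)
    BatchNorm2d,
    BottleneckBlock,
    Conv2d,
    Dense,
    GlobalAvgPool,
    InvertedResidualBlock,
    Layer,
    MaxPool2d,
    ReLU,
    Sequential,
)

__all__ = [
    "VARIANTS",
    "ArchitectureSpec",
    "ModelSummary",
    "RegressionModel",
    "build_model",
    "count_parameters",
    "make_bottleneck_block",
    "make_cbam",
    "make_inverted_residual_block",
    "resolve_invert_config",
    "spec_parameter_count",
    "weights_checksum",
]

VARIANTS = ("resnet50", "invert_resnet50", "cbam_resnet50", "cbam_invert_resnet50")

_RESNET_WIDTHS = (256, 512, 1024, 2048)
_INVERT_WIDTHS = (64, 128, 256, 512)


@dataclass
class ArchitectureSpec:
    """Fully determines a variant's structure and therefore its parameter count."""

    variant: str
    input_size: int = 224
    stage_block_counts: tuple = (3, 4, 6, 3)
    stage_output_channels: tuple | None = None
    expansion_factor: int = 4
    cbam_reduction: int = 16
    spatial_kernel: int = 7
    output_dim: int = 1
    stem_channels: int = 64

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.stage_output_channels is None:
            self.stage_output_channels = (
                _RESNET_WIDTHS if self.is_resnet_family else _INVERT_WIDTHS
            )
        self.stage_block_counts = tuple(int(n) for n in self.stage_block_counts)
        self.stage_output_channels = tuple(int(c) for c in self.stage_output_channels)
        if len(self.stage_block_counts) != 4 or len(self.stage_output_channels) != 4:
            raise ValueError("expected exactly 4 stages")
        if any(n < 1 for n in self.stage_block_counts):
            raise ValueError("stage block counts must be >= 1")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if self.has_cbam and any(c % self.cbam_reduction for c in self.stage_output_channels):
            raise ValueError("cbam_reduction must divide every stage output channel count")
        if self.is_resnet_family and any(c % 4 for c in self.stage_output_channels):
            raise ValueError("resnet-family stage widths must be divisible by 4")

    @property
    def is_resnet_family(self) -> bool:
        return self.variant in ("resnet50", "cbam_resnet50")

    @property
    def has_cbam(self) -> bool:
        return self.variant.startswith("cbam")

    @property
    def feature_dim(self) -> int:
        """Length of the pooled last-layer feature vector."""
        return self.stage_output_channels[-1]

    @classmethod
    def tiny(cls, variant: str = "cbam_invert_resnet50", width_divisor: int = 8,
             blocks: tuple = (1, 1, 1, 1), input_size: int = 56,
             cbam_reduction: int = 4) -> "ArchitectureSpec":
        """A narrow, shallow desk-scale variant for CPU-budget experiments."""
        base = _RESNET_WIDTHS if variant in ("resnet50", "cbam_resnet50") else _INVERT_WIDTHS
        widths = tuple(max(cbam_reduction, c // width_divisor) for c in base)
        return cls(variant=variant, input_size=input_size, stage_block_counts=blocks,
                   stage_output_channels=widths, cbam_reduction=cbam_reduction,
                   stem_channels=widths[0])

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        d["stage_block_counts"] = tuple(d["stage_block_counts"])
        d["stage_output_channels"] = tuple(d["stage_output_channels"])
        return cls(**d)


# ---------------------------------------------------------------------------
# block constructors


def make_bottleneck_block(c_in: int, c_mid: int, stride: int = 1,
                          projection_shortcut: bool | None = None,
                          rng: np.random.Generator | None = None) -> BottleneckBlock:
    """Standard ResNet bottleneck; output channels are ``4 * c_mid``."""
    return BottleneckBlock(c_in, c_mid, stride=stride,
                           projection_shortcut=projection_shortcut, rng=rng)


def make_inverted_residual_block(c_in: int, c_out: int, t: int = 4, stride: int = 1,
                                 hidden: int | None = None, skip: str = "auto",
                                 dw_bias: bool = False,
                                 rng: np.random.Generator | None = None) -> InvertedResidualBlock:
    return InvertedResidualBlock(c_in, c_out, t=t, stride=stride, hidden=hidden,
                                 skip=skip, dw_bias=dw_bias, rng=rng)


def make_cbam(c: int, r: int = 16, k: int = 7,
              rng: np.random.Generator | None = None) -> CBAM:
    return CBAM(c, reduction=r, spatial_kernel=k, rng=rng)


# ---------------------------------------------------------------------------
# model


class RegressionModel(Layer):
    """Stem -> 4 stages -> global average pooling -> linear head (one output)."""

    STAGE_NAMES = ("stem", "stage1", "stage2", "stage3", "stage4", "head")

    def __init__(self, spec: ArchitectureSpec, stem: Sequential, stages, head: Dense):
        self.spec = spec
        self.stem = stem
        self.stages = list(stages)
        self.gap = GlobalAvgPool()
        self.head = head
        self.feature_dim = spec.feature_dim

    def sublayers(self):
        subs = [("stem", self.stem)]
        subs += [(f"stage{i + 1}", s) for i, s in enumerate(self.stages)]
        subs += [("gap", self.gap), ("head", self.head)]
        return subs

    def _stage(self, name: str) -> Layer:
        mapping = {"stem": self.stem, "head": self.head}
        mapping.update({f"stage{i + 1}": s for i, s in enumerate(self.stages)})
        if name not in mapping:
            raise ValueError(f"unknown stage {name!r}; expected one of {self.STAGE_NAMES}")
        return mapping[name]

    def freeze(self, stage_names) -> None:
        for name in stage_names:
            self._stage(name).set_frozen(True)

    def stage_parameters(self, stage_names):
        params = []
        for name in stage_names:
            params.extend(self._stage(name).parameters())
        return params

    def forward_features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Pooled pre-head representation, one vector of length feature_dim per image."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N,3,H,W) input, got {x.shape}")
        h = self.stem.forward(x, training=training)
        for stage in self.stages:
            h = stage.forward(h, training=training)
        return self.gap.forward(h, training=training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        feats = self.forward_features(x, training=training)
        return self.head.forward(feats, training=training)[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.head.backward(dy[:, None])
        d = self.gap.backward(d)
        for stage in reversed(self.stages):
            d = stage.backward(d)
        return self.stem.backward(d)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> RegressionModel:
    """Construct a variant from its spec with seeded He-normal initialisation."""
    rng = np.random.default_rng(seed)
    c0 = spec.stem_channels
    stem = Sequential(
        Conv2d(3, c0, 7, stride=2, padding=3, rng=rng),
        BatchNorm2d(c0),
        ReLU(),
        MaxPool2d(3, 2, 1),
    )
    stages = []
    c_in = c0
    for si, (w, n_blocks) in enumerate(zip(spec.stage_output_channels, spec.stage_block_counts)):
        layers = []
        for bi in range(n_blocks):
            stride = 2 if (bi == 0 and si > 0) else 1
            if spec.is_resnet_family:
                # stage-leading blocks always use a projection shortcut,
                # as in the original skeleton
                block = make_bottleneck_block(c_in, w // 4, stride=stride, rng=rng,
                                              projection_shortcut=True if bi == 0 else None)
            else:
                # first block of every stage keeps the skeleton's projection shortcut
                block = make_inverted_residual_block(
                    c_in, w, t=spec.expansion_factor, stride=stride,
                    hidden=spec.expansion_factor * w,
                    skip="projection" if bi == 0 else "identity", rng=rng)
            layers.append(block)
            if spec.has_cbam:
                layers.append(make_cbam(w, spec.cbam_reduction, spec.spatial_kernel, rng=rng))
            c_in = w
        stages.append(Sequential(*layers))
    head = Dense(spec.feature_dim, spec.output_dim, rng=rng, name="head")
    return RegressionModel(spec, stem, stages, head)


# ---------------------------------------------------------------------------
# parameter accounting


@dataclass
class LayerRecord:
    name: str
    output_shape: tuple | None
    trainable: int
    non_trainable: int


@dataclass
class ModelSummary:
    rows: list
    total_trainable: int
    total_non_trainable: int
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        """Trainable + non-trainable, the convention of printed framework summaries."""
        return self.total_trainable + self.total_non_trainable

    def to_json(self) -> str:
        return json.dumps(
            {
                "metadata": self.metadata,
                "total_trainable": self.total_trainable,
                "total_non_trainable": self.total_non_trainable,
                "total": self.total,
                "layers": [r.__dict__ for r in self.rows],
            },
            default=list, indent=2,
        )

    def to_text(self) -> str:
        width = max((len(r.name) for r in self.rows), default=10) + 2
        lines = [f"{'layer':<{width}}{'output':<18}{'trainable':>12}{'frozen/stats':>14}"]
        lines.append("-" * (width + 44))
        for r in self.rows:
            shape = "x".join(map(str, r.output_shape)) if r.output_shape else "-"
            lines.append(f"{r.name:<{width}}{shape:<18}{r.trainable:>12,}{r.non_trainable:>14,}")
        lines.append("-" * (width + 44))
        lines.append(f"total trainable: {self.total_trainable:,}")
        lines.append(f"total non-trainable: {self.total_non_trainable:,}")
        lines.append(f"total: {self.total:,}")
        return "\n".join(lines)


def _capture_output_shapes(model: Layer, input_size: int) -> dict:
    """Run one forward pass, recording each parameterised layer's output shape."""
    records: dict = {}
    patched = []
    for name, layer in model.walk():
        if not (layer.own_parameters() or layer.own_buffers() or not layer.sublayers()):
            continue
        orig = layer.forward

        def wrapped(x, training=False, _orig=orig, _name=name):
            y = _orig(x, training=training)
            records[_name] = tuple(y.shape[1:])
            return y

        layer.forward = wrapped  # instance attribute shadows the bound method
        patched.append((layer, orig))
    try:
        model.forward(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
    finally:
        for layer, orig in patched:
            layer.forward = orig
    return records


def count_parameters(model: Layer, input_size: int | None = None,
                     metadata: dict | None = None) -> ModelSummary:
    """Exact accounting recounted from the weight/buffer array shapes."""
    shapes = _capture_output_shapes(model, input_size) if input_size else {}
    rows = []
    for name, layer in model.walk():
        own = layer.own_parameters()
        bufs = layer.own_buffers()
        if not own and not bufs and layer.sublayers():
            continue
        trainable = sum(p.size for p in own if p.trainable)
        frozen = sum(p.size for p in own if not p.trainable)
        stats = sum(int(np.asarray(b).size) for _, b in bufs)
        rows.append(LayerRecord(name, shapes.get(name), trainable, frozen + stats))
    meta = {"bn_momentum": 0.9, "bn_eps": 1e-5}
    if isinstance(getattr(model, "spec", None), ArchitectureSpec):
        meta["variant"] = model.spec.variant
    if metadata:
        meta.update(metadata)
    return ModelSummary(
        rows=rows,
        total_trainable=sum(r.trainable for r in rows),
        total_non_trainable=sum(r.non_trainable for r in rows),
        metadata=meta,
    )


def _conv_params(c_in, c_out, k, bias=True):
    return k * k * c_in * c_out + (c_out if bias else 0)


def _bn_params(c):
    return 4 * c  # 2c trainable + 2c moving statistics


def spec_parameter_count(spec: ArchitectureSpec) -> int:
    """Closed-form total (trainable + statistics) for a spec, no model built."""
    total = _conv_params(3, spec.stem_channels, 7) + _bn_params(spec.stem_channels)
    c_in = spec.stem_channels
    for si, (w, n_blocks) in enumerate(zip(spec.stage_output_channels, spec.stage_block_counts)):
        for bi in range(n_blocks):
            if spec.is_resnet_family:
                mid = w // 4
                total += (_conv_params(c_in, mid, 1) + _bn_params(mid)
                          + _conv_params(mid, mid, 3) + _bn_params(mid)
                          + _conv_params(mid, w, 1) + _bn_params(w))
                if bi == 0:
                    total += _conv_params(c_in, w, 1) + _bn_params(w)
            else:
                hidden = spec.expansion_factor * w
                total += (_conv_params(c_in, hidden, 1) + _bn_params(hidden)
                          + 9 * hidden + _bn_params(hidden)  # bias-free 3x3 depthwise
                          + _conv_params(hidden, w, 1) + _bn_params(w))
                if bi == 0:
                    total += _conv_params(c_in, w, 1) + _bn_params(w)
            if spec.has_cbam:
                mid = w // spec.cbam_reduction
                k = spec.spatial_kernel
                total += (w * mid + mid) + (mid * w + w) + (k * k * 2 + 1)
            c_in = w
    total += spec.feature_dim * spec.output_dim + spec.output_dim
    return total


@dataclass
class ResolvedInvertConfig:
    spec: ArchitectureSpec
    achieved: dict
    relative_errors: dict
    objective: float


_WIDTH_LADDERS = ((64, 128, 256, 512), (128, 256, 512, 1024), (256, 512, 1024, 2048))


def resolve_invert_config(targets: dict) -> ResolvedInvertConfig:
    """Exhaustive parameter-budget search for the inverted family.

    ``targets`` maps variant name (``invert_resnet50`` and/or
    ``cbam_invert_resnet50``) to a desired total parameter count.  The search
    covers expansion factors 1..6 and three stage-width ladders and returns the
    configuration minimising the summed relative count error.
    """
    allowed = {"invert_resnet50", "cbam_invert_resnet50"}
    if not targets:
        raise ValueError("targets must not be empty")
    unknown = set(targets) - allowed
    if unknown:
        raise ValueError(f"unknown target variants: {sorted(unknown)}")
    best = None
    for widths in _WIDTH_LADDERS:
        for t in range(1, 7):
            achieved, rel = {}, {}
            for variant in sorted(targets):
                spec = ArchitectureSpec(variant=variant, stage_output_channels=widths,
                                        expansion_factor=t)
                achieved[variant] = spec_parameter_count(spec)
                rel[variant] = abs(achieved[variant] - targets[variant]) / targets[variant]
            objective = sum(rel.values())
            if best is None or objective < best.objective:
                base_variant = ("invert_resnet50" if "invert_resnet50" in targets
                                else "cbam_invert_resnet50")
                best = ResolvedInvertConfig(
                    spec=ArchitectureSpec(variant=base_variant, stage_output_channels=widths,
                                          expansion_factor=t),
                    achieved=achieved, relative_errors=rel, objective=objective)
    return best


def weights_checksum(model: Layer, stage_names=None) -> str:
    """Hex digest over weights (and batch-norm statistics) for determinism checks."""
    import hashlib

    if stage_names is not None:
        params = model.stage_parameters(stage_names)
        layers = [model._stage(n) for n in stage_names]
    else:
        params = model.parameters()
        layers = [model]
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    for layer in layers:
        for _, sub in layer.walk():
            for _, buf in sub.own_buffers():
                h.update(np.ascontiguousarray(buf).tobytes())
    return h.hexdigest()


def cbam_increment(spec: ArchitectureSpec) -> int:
    """Total CBAM parameters a cbam_* variant adds over its base variant."""
    base = replace(spec, variant=spec.variant.replace("cbam_", ""),
                   stage_output_channels=spec.stage_output_channels)
    return spec_parameter_count(spec) - spec_parameter_count(base)
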