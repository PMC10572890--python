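"""Training, feature extraction, series feature fusion and transfer fine-tuning.

The mixed-part detector is built in two stages, mirroring the study design:

1. one regression backbone per pork cut (back / front_leg / hind_leg),
   trained on that cut's dataset;
2. a fusion model in which the three pretrained backbones run side by side
   on the same image, their pooled last-layer features are concatenated in
   fixed (back, front_leg, hind_leg) order, and a small trainable head maps
   the fused vector to the adulteration ratio.  Fine-tuning freezes the
   input-proximal stages (stem + stages 1-2 by default) and retrains the
   later stages together with the head on the mixed-part dataset.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .architectures import ArchitectureSpec, RegressionModel, build_model
from .evaluation import r_squared
from .nn import Adam, Dense, Layer, ReLU, Sequential
from .synthetic import PARTS

__all__ = [
    "DEFAULT_FREEZE",
    "FeatureVector",
    "FusedFeature",
    "FusionModel",
    "ImageDataset",
    "TrainConfig",
    "extract_features",
    "fuse_features",
    "predict_content",
    "train_regressor",
    "transfer_finetune",
]

DEFAULT_FREEZE = ("stem", "stage1", "stage2")


# ---------------------------------------------------------------------------
# data container


class ImageDataset:
    """Images as (N, 3, H, W) float32 in [0, 1] with ratio labels and sample ids."""

    def __init__(self, images: np.ndarray, labels, sample_ids=None, name: str = ""):
        images = np.asarray(images, dtype=np.float32)
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError(f"expected (N,3,H,W) images, got {images.shape}")
        self.images = images
        self.labels = np.asarray(labels, dtype=np.float32).ravel()
        if len(self.labels) != len(images):
            raise ValueError("labels and images disagree in length")
        self.sample_ids = list(sample_ids) if sample_ids is not None else [
            str(i) for i in range(len(images))]
        self.name = name

    def __len__(self) -> int:
        return len(self.images)

    @staticmethod
    def _to_chw(arr: np.ndarray) -> np.ndarray:
        return arr.astype(np.float32).transpose(2, 0, 1) / 255.0

    @classmethod
    def from_arrays(cls, images_hwc, labels, sample_ids=None, name: str = "") -> "ImageDataset":
        """From a list of uint8 (H, W, 3) arrays (e.g. augment_to_count output)."""
        x = np.stack([cls._to_chw(np.asarray(a)) for a in images_hwc])
        return cls(x, labels, sample_ids, name)

    @classmethod
    def from_manifest(cls, table: pd.DataFrame, split: str | None = None,
                      size: int | None = None, name: str = "") -> "ImageDataset":
        """Load a materialized split from its manifest (path/ratio/sample_id columns)."""
        if split is not None:
            table = table[table["split"] == split]
        if len(table) == 0:
            raise ValueError(f"manifest has no rows for split {split!r}")
        arrays, labels, ids = [], [], []
        for row in table.itertuples():
            img = Image.open(row.path).convert("RGB")
            if size is not None and img.size != (size, size):
                img = img.resize((size, size), Image.Resampling.BOX)
            arrays.append(np.asarray(img))
            labels.append(row.ratio)
            ids.append(row.sample_id)
        return cls.from_arrays(arrays, labels, ids, name=name or (split or ""))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    lr_decay: float = 1.0  # per-epoch multiplicative decay
    weight_decay: float = 0.0
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    freeze_spec: tuple = ()

    def __post_init__(self):
        if self.loss != "mse":
            raise ValueError("only mean-squared-error loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size must be >= 1 and learning_rate > 0")


def _forward_batched(forward, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    outs = [forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def _run_training(model: Layer, dataset: ImageDataset, cfg: TrainConfig,
                  test_dataset: ImageDataset | None,
                  val_dataset: ImageDataset | None,
                  stop_at_val_r2: float | None,
                  stop_at_val_r2_sums: float | None = None) -> pd.DataFrame:
    opt = Adam(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = []
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.learning_rate * cfg.lr_decay ** (epoch - 1)
        perm = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = dataset.images[idx], dataset.labels[idx]
            pred = model.forward(xb, training=True)
            err = pred - yb
            losses.append(float((err ** 2).mean()))
            opt.zero_grad()
            model.backward((2.0 / len(idx)) * err)
            opt.step()
        row = {"epoch": epoch, "train_mse": float(np.mean(losses)),
               "train_rmse": float(np.sqrt(np.mean(losses)))}
        if test_dataset is not None:
            tp = _forward_batched(model.forward, test_dataset.images)
            row["test_mse"] = float(((tp - test_dataset.labels) ** 2).mean())
        if val_dataset is not None:
            vp = predict_content(model, val_dataset.images)
            yv = val_dataset.labels
            row["val_r2"] = r_squared(vp, yv)  # the study's ratio-of-sums form
            # conventional coefficient of determination; unlike the ratio-of-sums
            # form it cannot be satisfied by overdispersed predictions, so it is
            # the quantity early stopping monitors
            row["val_r2_conv"] = 1.0 - float(((vp - yv) ** 2).sum()
                                             / ((yv - yv.mean()) ** 2).sum())
        history.append(row)
        if (stop_at_val_r2 is not None and val_dataset is not None
                and row["val_r2_conv"] >= stop_at_val_r2
                and (stop_at_val_r2_sums is None or row["val_r2"] >= stop_at_val_r2_sums)):
            break
    return pd.DataFrame(history)


def train_regressor(spec_or_model, dataset: ImageDataset, cfg: TrainConfig,
                    test_dataset: ImageDataset | None = None,
                    val_dataset: ImageDataset | None = None,
                    stop_at_val_r2: float | None = None,
                    stop_at_val_r2_sums: float | None = None):
    """Fit a regression backbone by MSE; returns ``(model, history)``.

    ``history`` has one row per epoch (train MSE/RMSE, optional test MSE and
    validation R^2).  Fully deterministic given the config seed.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    if dataset.labels.min() < 0 or dataset.labels.max() > 1:
        raise ValueError("labels must be mass fractions in [0, 1]")
    if isinstance(spec_or_model, ArchitectureSpec):
        model = build_model(spec_or_model, seed=cfg.seed)
    else:
        model = spec_or_model
    if cfg.freeze_spec:
        model.freeze(cfg.freeze_spec)
    history = _run_training(model, dataset, cfg, test_dataset, val_dataset,
                            stop_at_val_r2, stop_at_val_r2_sums)
    return model, history


def predict_content(model, images: np.ndarray, batch_size: int = 64):
    """Adulteration-ratio estimate(s) clipped to [0, 1].

    Accepts a single (3, H, W) image or an (N, 3, H, W) batch.
    """
    arr = np.asarray(images, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[1] != 3:
        raise ValueError(f"expected (3,H,W) or (N,3,H,W) input, got {arr.shape}")
    preds = np.clip(_forward_batched(model.forward, arr, batch_size), 0.0, 1.0)
    return float(preds[0]) if single else preds


# ---------------------------------------------------------------------------
# features and fusion


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    source_model: str
    sample_id: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")


@dataclass(frozen=True)
class FusedFeature:
    values: np.ndarray
    sample_id: str


def extract_features(model: RegressionModel, dataset: ImageDataset,
                     source_model: str = "", batch_size: int = 64):
    """Pooled pre-head descriptors, one :class:`FeatureVector` per image."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    feats = _forward_batched(model.forward_features, dataset.images, batch_size)
    name = source_model or getattr(model.spec, "variant", "model")
    return [FeatureVector(values=f, source_model=name, sample_id=sid)
            for f, sid in zip(feats, dataset.sample_ids)]


def fuse_features(back: FeatureVector, front_leg: FeatureVector,
                  hind_leg: FeatureVector) -> FusedFeature:
    """Series (early) fusion: concatenate in fixed (back, front_leg, hind_leg) order."""
    trio = (back, front_leg, hind_leg)
    ids = {fv.sample_id for fv in trio}
    if len(ids) != 1:
        raise ValueError(f"sample_id mismatch across features: {sorted(ids)}")
    return FusedFeature(values=np.concatenate([fv.values for fv in trio]),
                        sample_id=back.sample_id)


class FusionModel(Layer):
    """Three per-part backbones in series fusion with a shared regression head.

    Every input image runs through all three backbones; the pooled features
    are concatenated (back, front_leg, hind_leg) and a hidden-layer head
    predicts the ratio.  Frozen backbone stages run in inference mode (their
    batch-norm statistics do not move) and are excluded from backprop.
    """

    def __init__(self, backbones: dict, hidden: int = 256, seed: int = 0,
                 freeze_spec: tuple = DEFAULT_FREEZE):
        missing = set(PARTS) - set(backbones)
        if missing:
            raise ValueError(f"missing backbones for parts: {sorted(missing)}")
        self.parts = PARTS
        self.backbones = {p: backbones[p] for p in PARTS}
        self.freeze_spec = tuple(freeze_spec)
        self._validate_freeze()
        for bb in self.backbones.values():
            bb.freeze(self.freeze_spec)
        feat = sum(bb.feature_dim for bb in self.backbones.values())
        rng = np.random.default_rng(seed)
        self.head = Sequential(Dense(feat, hidden, rng=rng, name="fusion.hidden"), ReLU(),
                               Dense(hidden, 1, rng=rng, name="fusion.out"))
        self._dims = [self.backbones[p].feature_dim for p in PARTS]

    def _validate_freeze(self):
        order = RegressionModel.STAGE_NAMES[:-1]  # head is never part of a backbone freeze
        for name in self.freeze_spec:
            if name not in order:
                raise ValueError(f"unknown stage name in freeze_spec: {name!r}")
        # backprop stops at the deepest frozen layer, so freezing must be a prefix
        idx = sorted(order.index(n) for n in self.freeze_spec)
        if idx != list(range(len(idx))):
            raise ValueError("freeze_spec must be an input-proximal prefix "
                             f"of {order}, got {self.freeze_spec}")

    def sublayers(self):
        subs = [(f"backbone_{p}", self.backbones[p]) for p in self.parts]
        return subs + [("head", self.head)]

    def parameters(self):
        params = []
        for p in self.parts:
            params.extend(self.backbones[p].parameters())
        params.extend(self.head.parameters())
        return params

    def _backbone_stages(self, bb: RegressionModel):
        return [("stem", bb.stem)] + [(f"stage{i+1}", s) for i, s in enumerate(bb.stages)]

    def forward(self, x, training=False):
        feats = []
        for p in self.parts:
            bb = self.backbones[p]
            h = x
            for name, stage in self._backbone_stages(bb):
                h = stage.forward(h, training=training and name not in self.freeze_spec)
            feats.append(bb.gap.forward(h, training=training))
        fused = np.concatenate(feats, axis=1)
        return self.head.forward(fused, training=training)[:, 0]

    def backward(self, dy):
        dfused = self.head.backward(dy[:, None])
        offset = 0
        for p, dim in zip(self.parts, self._dims):
            bb = self.backbones[p]
            d = bb.gap.backward(dfused[:, offset : offset + dim])
            for name, stage in reversed(self._backbone_stages(bb)):
                if name in self.freeze_spec:
                    break
                d = stage.backward(d)
            offset += dim
        return None  # gradient w.r.t. the input image is not needed

    def fused_features(self, dataset: ImageDataset, batch_size: int = 64):
        """Series-fused descriptors for a dataset (inference mode)."""
        per_part = {p: extract_features(self.backbones[p], dataset, source_model=p,
                                        batch_size=batch_size) for p in self.parts}
        return [fuse_features(b, f, h) for b, f, h in
                zip(per_part["back"], per_part["front_leg"], per_part["hind_leg"])]


def transfer_finetune(pretrained: dict, dataset: ImageDataset, cfg: TrainConfig,
                      test_dataset: ImageDataset | None = None,
                      val_dataset: ImageDataset | None = None,
                      hidden: int = 256, copy_backbones: bool = True):
    """Build the fusion model from pretrained per-part backbones and fine-tune it.

    Freezes ``cfg.freeze_spec`` (default stem + stages 1-2) in every backbone
    and trains the remaining stages plus the fusion head on the mixed-part
    dataset.  Returns ``(fusion_model, history)``.  Frozen weights and their
    batch-norm statistics are bit-identical before and after training.
    """
    if len(dataset) == 0:
        raise ValueError("fine-tuning dataset is empty")
    backbones = {p: copy.deepcopy(m) if copy_backbones else m for p, m in pretrained.items()}
    freeze = tuple(cfg.freeze_spec) or DEFAULT_FREEZE
    model = FusionModel(backbones, hidden=hidden, seed=cfg.seed, freeze_spec=freeze)
    history = _run_training(model, dataset, cfg, test_dataset, val_dataset, None)
    return model, history
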