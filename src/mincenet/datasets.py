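"""Dataset partitioning and count-driven materialization of augmented splits.

Per part: one third of the source dishes (stratified by adulteration ratio)
become an independent validation set; the remainder split 3:1 into train and
test (test rounded down).  Splits are then *filled* to fixed image counts by
augmentation — the study sizes are 1575/525/700 train/test/validation per
part and exactly 3x that (4725/1575/2100) for the mixed-part dataset.  Count
driven filling (rather than a per-original multiplier) is what makes those
printed sizes reachable from 32 source dishes.

Augmented copies inherit the sample_id of their source dish, so validation
independence is auditable from the manifest: no validation sample_id may
contribute any image to train or test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .preprocess import AugmentationConfig, augment_to_count, extract_roi

__all__ = [
    "DEFAULT_FILL_TARGETS",
    "SplitManifest",
    "assert_no_leakage",
    "build_mixed_manifest",
    "materialize_splits",
    "split_single_part",
]

SPLITS = ("train", "test", "validation")

#: the study's per-part split sizes after augmentation
DEFAULT_FILL_TARGETS = {"train": 1575, "test": 525, "validation": 700}


@dataclass
class SplitManifest:
    dataset_name: str
    assignments: dict = field(default_factory=dict)  # sample_id -> split
    fill_targets: dict = field(default_factory=lambda: dict(DEFAULT_FILL_TARGETS))

    def __post_init__(self):
        bad = set(self.assignments.values()) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split names: {sorted(bad)}")
        if set(self.fill_targets) != set(SPLITS):
            raise ValueError(f"fill_targets must cover exactly {SPLITS}")
        if self.fill_targets["train"] != 3 * self.fill_targets["test"]:
            raise ValueError("train:test fill targets must stand in exact 3:1 ratio")

    def ids_for(self, split: str):
        return sorted(sid for sid, s in self.assignments.items() if s == split)

    def counts(self) -> dict:
        return {s: len(self.ids_for(s)) for s in SPLITS}


def split_single_part(metadata, val_fraction: float = 1 / 3, seed: int = 0,
                      fill_targets: dict | None = None,
                      dataset_name: str | None = None) -> SplitManifest:
    """Stratified per-ratio split of one part's source dishes.

    Per ratio group of size n: ``round(val_fraction * n)`` dishes go to
    validation; of the remaining m, ``floor(m/4)`` go to test and the rest to
    train (the 3:1 rule with test rounded down).  Deterministic given seed.
    """
    metadata = list(metadata)
    if not metadata:
        raise ValueError("metadata must be non-empty")
    parts = {m.part for m in metadata}
    if len(parts) != 1:
        raise ValueError(f"split_single_part expects one part, got {sorted(parts)}")
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError("val_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_ratio: dict = {}
    for m in metadata:
        by_ratio.setdefault(m.ratio, []).append(m)
    assignments: dict = {}
    for ratio in sorted(by_ratio):
        group = sorted(by_ratio[ratio], key=lambda m: m.sample_id)
        if len(group) < 2:
            raise ValueError(f"need at least 2 originals per ratio, got {len(group)} "
                             f"for ratio {ratio}")
        order = rng.permutation(len(group))
        n_val = int(np.floor(val_fraction * len(group) + 0.5))
        remaining = len(group) - n_val
        n_test = remaining // 4
        for pos, idx in enumerate(order):
            if pos < n_val:
                split = "validation"
            elif pos < n_val + n_test:
                split = "test"
            else:
                split = "train"
            assignments[group[idx].sample_id] = split
    return SplitManifest(
        dataset_name=dataset_name or parts.pop(),
        assignments=assignments,
        fill_targets=dict(fill_targets or DEFAULT_FILL_TARGETS),
    )


def build_mixed_manifest(manifests) -> SplitManifest:
    """Union of the three per-part manifests; every sample keeps its split."""
    manifests = list(manifests)
    if len(manifests) != 3:
        raise ValueError(f"expected exactly 3 per-part manifests, got {len(manifests)}")
    assignments: dict = {}
    fill = {s: 0 for s in SPLITS}
    for man in manifests:
        overlap = set(man.assignments) & set(assignments)
        if overlap:
            raise ValueError(f"duplicate sample_ids across parts: {sorted(overlap)[:5]}")
        assignments.update(man.assignments)
        for s in SPLITS:
            fill[s] += man.fill_targets[s]
    return SplitManifest(dataset_name="mixed", assignments=assignments, fill_targets=fill)


def _load_image(source, sample_id: str) -> np.ndarray:
    if isinstance(source, np.ndarray):
        return source
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"image file for sample_id {sample_id!r} not found: {path}")
    return np.asarray(Image.open(path).convert("RGB"))


def materialize_splits(manifest: SplitManifest, metadata, images, cfg: AugmentationConfig,
                       seed: int, out_dir, roi: bool = True) -> pd.DataFrame:
    """Write every split, filled to its target count, plus per-split CSV manifests.

    ``images`` maps sample_id to a PNG/JPEG path or an in-memory RGB array.
    With ``roi=True`` each source is first cropped to its detected dish circle.
    Layout: ``out_dir/dataset_name/split/*.png``; CSV columns are
    path, sample_id, split, part, ratio, is_augmented.
    """
    if not manifest.assignments:
        raise ValueError("manifest has no assigned samples")
    meta_by_id = {m.sample_id: m for m in metadata}
    missing = set(manifest.assignments) - set(meta_by_id)
    if missing:
        raise ValueError(f"metadata missing for sample_ids: {sorted(missing)[:5]}")
    base = Path(out_dir) / manifest.dataset_name
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(SPLITS))
    roi_cache: dict = {}
    for split, child in zip(SPLITS, seeds):
        ids = manifest.ids_for(split)
        if not ids:
            raise ValueError(f"split {split!r} has no source samples")
        sources = []
        for sid in ids:
            if sid not in images:
                raise FileNotFoundError(f"no image registered for sample_id {sid!r}")
            if sid not in roi_cache:
                img = _load_image(images[sid], sid)
                roi_cache[sid] = extract_roi(img)[0] if roi else img
            sources.append(roi_cache[sid])
        rng = np.random.default_rng(child)
        out_images, provenance = augment_to_count(
            sources, manifest.fill_targets[split], cfg, rng, with_provenance=True)
        split_dir = base / split
        split_dir.mkdir(parents=True, exist_ok=True)
        n_orig = len(sources)
        for i, (img, src) in enumerate(zip(out_images, provenance)):
            sid = ids[src]
            path = split_dir / f"{i:05d}_{sid}.png"
            Image.fromarray(img).save(path, compress_level=1)
            rows.append({"path": str(path), "sample_id": sid, "split": split,
                         "part": meta_by_id[sid].part, "ratio": meta_by_id[sid].ratio,
                         "is_augmented": i >= n_orig})
    table = pd.DataFrame(rows)
    for split in SPLITS:
        table[table["split"] == split].to_csv(base / f"{split}.csv", index=False)
    table.to_csv(base / "manifest.csv", index=False)
    return table


def assert_no_leakage(table: pd.DataFrame) -> None:
    """Raise if any validation source dish contributes an image to train or test."""
    val_ids = set(table.loc[table["split"] == "validation", "sample_id"])
    other = set(table.loc[table["split"] != "validation", "sample_id"])
    leaked = val_ids & other
    if leaked:
        raise AssertionError(f"validation samples leaked into train/test: {sorted(leaked)[:5]}")
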