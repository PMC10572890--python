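"""Shared fixtures.

The expensive session fixtures (rendered study, materialized splits, trained
models) are shared across the acceptance tests so each heavy computation runs
once.  Desk-scale conditions: 224 px renders, the study's fill targets, 36 px
network inputs and the tiny-width cbam_invert variant (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mincenet.architectures import ArchitectureSpec, VARIANTS, build_model
from mincenet.datasets import build_mixed_manifest, materialize_splits, split_single_part
from mincenet.pipeline import ImageDataset, TrainConfig, train_regressor
from mincenet.preprocess import AugmentationConfig, extract_roi
from mincenet.synthetic import PARTS, RenderConfig, generate_sample_metadata, render_study

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: training protocol for the desk-scale experiments
DESK_TRAIN = dict(learning_rate=3e-3, lr_decay=0.96, weight_decay=0.01,
                  batch_size=32, epochs=50)
DESK_INPUT = 36


@pytest.fixture(scope="session")
def desk_cfg():
    return RenderConfig().desk_scale(224)


@pytest.fixture(scope="session")
def study_metas():
    return generate_sample_metadata(8)


@pytest.fixture(scope="session")
def study_rois(desk_cfg, study_metas):
    """ROI-cropped renders of the default 96-dish study, keyed by sample_id."""
    images = render_study(study_metas, desk_cfg, seed=42)
    return {sid: extract_roi(img)[0] for sid, img in images.items()}


@pytest.fixture(scope="session")
def part_manifests(study_metas):
    return {part: split_single_part([m for m in study_metas if m.part == part], seed=42)
            for part in PARTS}


@pytest.fixture(scope="session")
def study_datasets(tmp_path_factory, study_metas, study_rois, part_manifests):
    """Materialized per-part and mixed splits at the 36 px desk input size."""
    out = tmp_path_factory.mktemp("splits36")
    acfg = AugmentationConfig(target_size=DESK_INPUT)
    data = {}
    for part in PARTS:
        table = materialize_splits(part_manifests[part], study_metas, study_rois,
                                   acfg, seed=42, out_dir=out, roi=False)
        data[part] = {split: ImageDataset.from_manifest(table, split, name=f"{part}/{split}")
                      for split in ("train", "test", "validation")}
    mixed_man = build_mixed_manifest([part_manifests[p] for p in PARTS])
    table = materialize_splits(mixed_man, study_metas, study_rois,
                               acfg, seed=43, out_dir=out, roi=False)
    data["mixed"] = {split: ImageDataset.from_manifest(table, split, name=f"mixed/{split}")
                     for split in ("train", "validation")}
    return data


@pytest.fixture(scope="session")
def tiny_spec():
    return ArchitectureSpec.tiny(width_divisor=8, input_size=DESK_INPUT)


@pytest.fixture(scope="session")
def trained_back_models(tiny_spec, study_datasets):
    """Three independently seeded trainings of the back-part regressor.

    Early stopping fires once both R^2 forms clear their bars (the model has
    "reached" the target); otherwise training runs the full 50 epochs.
    """
    runs = []
    for seed in (0, 1, 2):
        cfg = TrainConfig(seed=seed, **DESK_TRAIN)
        model, history = train_regressor(
            tiny_spec, study_datasets["back"]["train"], cfg,
            val_dataset=study_datasets["back"]["validation"],
            stop_at_val_r2=0.75, stop_at_val_r2_sums=0.8)
        runs.append((model, history))
    return runs


@pytest.fixture(scope="session")
def pretrained_parts(tiny_spec, study_datasets):
    """One fully trained backbone per part (35-epoch budget each)."""
    models = {}
    for seed, part in ((0, "back"), (1, "front_leg"), (2, "hind_leg")):
        cfg = TrainConfig(seed=seed, **{**DESK_TRAIN, "epochs": 35})
        models[part], _ = train_regressor(
            tiny_spec, study_datasets[part]["train"], cfg,
            val_dataset=study_datasets[part]["validation"])
    return models


@pytest.fixture(scope="session")
def full_models():
    """All four full-size variants (for parameter accounting and forward checks)."""
    return {v: build_model(ArchitectureSpec(variant=v), seed=0) for v in VARIANTS}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
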