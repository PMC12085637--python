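"""End-to-end orchestration helpers shared by the CLI and scripts.

Glue between the stages: simulate/load frames -> dissect -> featurize ->
fit -> predict -> aggregate -> evaluate.  Kept free of I/O except where a
function's purpose is writing result files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import ImageCall, score_vector
from .labels import CLASSES
from .metrics import ConfusionMatrix, MetricsReport, confusion, metrics
from .model import PatchClassifier, TrainingConfig, TrainingResults
from .patches import (
    BrightfieldImage,
    DatasetSplit,
    PatchGridSpec,
    build_patch_dataset,
    dissect_image,
    split_images,
)


def split_by_condition(
    images: Mapping[str, BrightfieldImage],
    counts: tuple[int, int, int] = (64, 22, 22),
    seed: int = 0,
) -> DatasetSplit:
    per_class: dict[str, list[str]] = {}
    for image_id, img in images.items():
        if img.condition is not None:
            per_class.setdefault(img.condition, []).append(image_id)
    for ids in per_class.values():
        ids.sort()
    return split_images(per_class, counts=counts, seed=seed)


def fit_classifier(
    images: Mapping[str, BrightfieldImage],
    split: DatasetSplit,
    grid: PatchGridSpec | None = None,
    config: TrainingConfig | None = None,
) -> tuple[PatchClassifier, TrainingResults, dict]:
    """Dissect an image split and fit the classifier on its train/val parts.

    The patch grid defaults to the geometry of the first frame (all frames
    of a run share one geometry).
    """
    if grid is None:
        first = next(iter(images.values()))
        grid = PatchGridSpec.for_frame(*first.shape)
    sets = build_patch_dataset(images, split, grid)
    clf = PatchClassifier(config)
    results = clf.fit(sets["train"], sets["val"])
    return clf, results, sets


def classify_images(
    clf: PatchClassifier,
    images: Sequence[BrightfieldImage],
    grid: PatchGridSpec | None = None,
) -> list[ImageCall]:
    """Predict patches of each frame and aggregate into image-level calls."""
    calls = []
    for img in images:
        g = grid or PatchGridSpec.for_frame(*img.shape)
        preds = clf.predict_patches(dissect_image(img, g))
        calls.append(
            ImageCall(
                image_id=img.image_id,
                score=score_vector(preds),
                well_id=img.well_id,
                hour=img.hour,
            )
        )
    return calls


def evaluate_patch_level(
    clf: PatchClassifier, patchset
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix and metrics of patch predictions vs ground truth."""
    true_labels: list[str] = []
    pred_labels: list[str] = []
    for pix, y, _ in patchset.iter_batches(256):
        probs = clf.predict_proba(pix, is_features=False)
        pred_labels.extend(CLASSES[i] for i in probs.argmax(axis=1))
        true_labels.extend(CLASSES[i] for i in y)
    cm = confusion(true_labels, pred_labels)
    return cm, metrics(cm, level="patch")


def calls_to_frame(calls: Sequence[ImageCall]) -> pd.DataFrame:
    """Image calls with their score vectors as a flat table."""
    rows = []
    for c in calls:
        row = {
            "image_id": c.image_id,
            "well": c.well_id,
            "hour": c.hour,
            "label": c.label,
        }
        row.update({f"c_{lab}": v for lab, v in zip(CLASSES, c.score.values)})
        rows.append(row)
    return pd.DataFrame(rows)


def streamed_feature_split(
    clf: PatchClassifier,
    per_class: int = 108,
    counts: tuple[int, int, int] = (64, 22, 22),
    base_seed: int = 0,
    grid: PatchGridSpec | None = None,
    **scene_overrides,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], DatasetSplit]:
    """Simulate a dataset and featurize it frame-by-frame (flat memory).

    Generates ``per_class`` frames per class, splits them at the image
    level, and pushes each frame's patches through the frozen backbone as
    soon as the frame is rendered, so no more than one frame is ever held
    in memory.  Returns ``{'train'|'val'|'test': (features, labels)}`` and
    the split.
    """
    from .simulate import dataset_image_ids, iter_simulated

    counts_map = {c: per_class for c in CLASSES}
    split = split_images(dataset_image_ids(counts_map), counts=counts, seed=base_seed)
    membership: dict[str, str] = {}
    for part in ("train", "val", "test"):
        for image_id in getattr(split, part):
            membership[image_id] = part

    grid = grid or PatchGridSpec.native()
    feats: dict[str, list[np.ndarray]] = {p: [] for p in ("train", "val", "test")}
    labels: dict[str, list[int]] = {p: [] for p in ("train", "val", "test")}
    for image, _ in iter_simulated(counts_map, base_seed=base_seed, **scene_overrides):
        part = membership.get(image.image_id)
        if part is None:
            continue
        pix = np.stack([p.pixels for p in dissect_image(image, grid)])
        feats[part].append(clf.featurize(pix))
        labels[part].extend([CLASSES.index(image.condition)] * len(pix))
    out = {
        part: (
            np.concatenate(feats[part])
            if feats[part]
            else np.empty((0, clf.net.FEATURE_DIM), dtype=np.float32),
            np.array(labels[part], dtype=np.int64),
        )
        for part in ("train", "val", "test")
    }
    return out, split


def simulate_screen_calls(
    clf: PatchClassifier,
    plate_map,
    compound_classes: Mapping[str, str],
    hours: Sequence[int] = tuple(range(1, 25)),
    base_seed: int = 0,
    frame_shape: tuple[int, int] = (224, 224),
    cells_per_frame: int | None = None,
) -> list[ImageCall]:
    """Emulate an hourly-imaged plate and classify every (well, hour) frame.

    Each treatment well renders its compound's induced morphotype, vehicle
    wells render healthy cells; frames are static per hour (no kinetics).
    Cell counts scale with frame area relative to the native geometry so
    local density matches the training frames.
    """
    from .simulate import SceneSpec, mix_seed, simulate_scene

    h, w = frame_shape
    if cells_per_frame is None:
        cells_per_frame = max(2, round(60 * (h * w) / (1040 * 1408)))
    grid = PatchGridSpec.for_frame(h, w)
    calls: list[ImageCall] = []
    for widx, row in enumerate(plate_map.wells.itertuples(index=False)):
        label = "hea" if row.role == "vehicle" else compound_classes[row.compound]
        for hour in hours:
            spec = SceneSpec(
                class_label=label,
                frame_height=h,
                frame_width=w,
                cell_count=cells_per_frame,
                seed=mix_seed(base_seed, widx * 1000 + hour),
            )
            image, _ = simulate_scene(spec)
            image.image_id = f"{plate_map.plate_id}_{row.well}_h{hour:02d}"
            image.well_id = row.well
            image.hour = hour
            calls.extend(classify_images(clf, [image], grid=grid))
    return calls


def write_provenance(outdir: str | Path, payload: dict) -> None:
    import json
    import platform

    payload = dict(payload)
    payload["numpy_version"] = np.__version__
    payload["python_version"] = platform.python_version()
    Path(outdir, "provenance.json").write_text(json.dumps(payload, indent=1, default=str))
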