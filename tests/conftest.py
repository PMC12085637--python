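"""Shared fixtures.

Heavy artifacts (simulated datasets, a trained classifier) are
session-scoped so the expensive simulation and training run once and are
reused across the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import morphoscreen as ms
from morphoscreen.pipeline import (
    evaluate_patch_level,
    fit_classifier,
    split_by_condition,
    streamed_feature_split,
)

SEED = 20240917


@pytest.fixture(scope="session")
def tiny_dataset():
    """Ten native-geometry frames per class with ground truth."""
    pairs = ms.simulate_dataset({c: 10 for c in ms.CLASSES}, base_seed=SEED)
    return pairs


@pytest.fixture(scope="session")
def tiny_images(tiny_dataset):
    return {img.image_id: img for img, _ in tiny_dataset}


@pytest.fixture(scope="session")
def trained_tiny(tiny_images):
    """Classifier fitted on the tiny dataset with the fast CPU protocol."""
    split = split_by_condition(tiny_images, counts=(6, 2, 2), seed=SEED)
    cfg = ms.TrainingConfig.cpu_protocol(seed=SEED)
    clf, results, sets = fit_classifier(tiny_images, split, config=cfg)
    cm, report = evaluate_patch_level(clf, sets["test"])
    return {
        "clf": clf,
        "results": results,
        "sets": sets,
        "split": split,
        "cm": cm,
        "report": report,
    }


@pytest.fixture(scope="session")
def full_training_run():
    """The full-size study conditions: 108 frames/class, 64/22/22 split,
    native 16-patch grid, scaled-down (<=10 epochs) head-only training.

    Streams frames through the frozen backbone so memory stays flat.
    """
    clf = ms.PatchClassifier(ms.TrainingConfig.cpu_protocol(seed=SEED))
    parts, split = streamed_feature_split(clf, per_class=108, base_seed=SEED)
    results = clf.fit(parts["train"], parts["val"])
    Fte, yte = parts["test"]
    probs = clf.predict_proba(Fte)
    pred = [ms.CLASSES[i] for i in probs.argmax(axis=1)]
    true = [ms.CLASSES[i] for i in yte]
    cm = ms.confusion(true, pred)
    return {
        "clf": clf,
        "results": results,
        "parts": parts,
        "split": split,
        "test_cm": cm,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
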