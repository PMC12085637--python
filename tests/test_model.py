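"""Classifier harness: schedule, freezing, training contract, inference."""

from __future__ import annotations

import numpy as np
import pytest

import morphoscreen as ms
from morphoscreen.errors import ConfigError, DataError
from morphoscreen.model import PatchPrediction
from morphoscreen.nn import MicroCNN, cross_entropy


# -- learning-rate schedule --------------------------------------------------


def test_lr_schedule_values():
    cfg = ms.TrainingConfig()
    assert ms.lr_at_epoch(cfg, 0) == 1e-4
    rates = {ms.lr_at_epoch(cfg, e) for e in range(5)}
    assert rates == {1e-4}  # constant within the first interval
    assert ms.lr_at_epoch(cfg, 10) == pytest.approx(1e-4 * 0.95**2)  # 9.025e-5
    with pytest.raises(ConfigError):
        ms.lr_at_epoch(cfg, -1)


def test_lr_schedule_non_increasing():
    cfg = ms.TrainingConfig()
    rates = [ms.lr_at_epoch(cfg, e) for e in range(60)]
    assert all(b <= a for a, b in zip(rates, rates[1:]))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(batch_size=0),
        dict(lr_decay_fraction=1.0),
        dict(early_stopping_patience=51),
        dict(num_train_layers=-1),
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ConfigError):
        ms.TrainingConfig(**kwargs)


# -- model construction ------------------------------------------------------


def test_unknown_backbone_rejected():
    with pytest.raises(ConfigError):
        ms.PatchClassifier(ms.TrainingConfig(backbone_id="resnet9000"))


@pytest.mark.parametrize(
    "k,expected_trainable",
    [
        (0, ()),
        (3, ("fc1", "fc2", "head")),
        (6, ("conv1", "conv2", "conv3", "fc1", "fc2", "head")),
    ],
)
def test_trainable_group_selection(k, expected_trainable):
    clf = ms.PatchClassifier(ms.TrainingConfig(num_train_layers=k))
    assert clf.trainable_groups == expected_trainable
    assert set(clf.frozen_groups) | set(clf.trainable_groups) == set(MicroCNN.GROUPS)
    assert not set(clf.frozen_groups) & set(clf.trainable_groups)


def _separable_features(n_per_class=60, seed=0):
    """Linearly separable 5-class blobs in the 136-d feature space."""
    rng = np.random.default_rng(seed)
    dim = MicroCNN.FEATURE_DIM
    X, y = [], []
    for c in range(5):
        center = np.zeros(dim)
        center[c * 10 : c * 10 + 10] = 4.0
        X.append(rng.normal(center, 1.0, size=(n_per_class, dim)))
        y.extend([c] * n_per_class)
    return np.concatenate(X).astype(np.float32), np.array(y, dtype=np.int64)


def test_zero_train_layers_makes_training_a_noop_on_weights():
    clf = ms.PatchClassifier(ms.TrainingConfig(num_train_layers=0, max_epochs=2,
                                               early_stopping_patience=2))
    before = clf.net.copy_params()
    X, y = _separable_features(10)
    res = clf.fit((X, y))
    after = clf.net.flat_params()
    assert all(np.array_equal(after[k], before[k]) for k in before)
    assert res.frozen_params_unchanged()


def test_zero_epochs_returns_initial_weights():
    clf = ms.PatchClassifier(ms.TrainingConfig(max_epochs=0, early_stopping_patience=0))
    before = clf.net.copy_params()
    res = clf.fit(_separable_features(10))
    after = clf.net.flat_params()
    assert all(np.array_equal(after[k], before[k]) for k in before)
    assert res.n_epochs_run == 0


def test_training_reduces_loss_on_separable_data():
    clf = ms.PatchClassifier(ms.TrainingConfig.cpu_protocol(seed=1, max_epochs=5))
    X, y = _separable_features()
    res = clf.fit((X, y))
    hist = res.history
    assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]


def test_frozen_parameters_bit_identical_after_training(rng):
    X = rng.random((40, 224, 224)).astype(np.float32)
    y = rng.integers(0, 5, size=40)
    clf = ms.PatchClassifier(ms.TrainingConfig.cpu_protocol(seed=2, max_epochs=2))
    before = clf.net.copy_params()
    res = clf.fit((X, y))
    after = clf.net.flat_params()
    for g in ("conv1", "conv2", "conv3"):
        for k in ("W", "b"):
            assert np.array_equal(after[f"{g}.{k}"], before[f"{g}.{k}"])
    assert res.frozen_params_unchanged()
    # trainable head actually moved
    assert not np.array_equal(after["head.W"], before["head.W"])


def test_early_stopping_triggers_before_max_epochs():
    """A validation set with shuffled labels cannot keep improving."""
    Xtr, ytr = _separable_features(seed=3)
    rng = np.random.default_rng(4)
    Xval, yval = _separable_features(20, seed=5)
    yval = rng.permutation(yval)  # wrong labels: val loss rises as fit improves
    cfg = ms.TrainingConfig(max_epochs=30, early_stopping_patience=3,
                            initial_lr=1e-3, seed=6)
    clf = ms.PatchClassifier(cfg)
    res = clf.fit((Xtr, ytr), (Xval, yval))
    assert res.stopped_early
    assert res.n_epochs_run < 30
    # the restored weights are those of the best validation epoch
    assert res.best_epoch <= res.n_epochs_run - cfg.early_stopping_patience


def test_seed_determinism_identical_history_and_weights():
    X, y = _separable_features(30, seed=7)
    runs = []
    for _ in range(2):
        clf = ms.PatchClassifier(ms.TrainingConfig.cpu_protocol(seed=9, max_epochs=4))
        res = clf.fit((X, y))
        runs.append((res.history.copy(), clf.net.copy_params()))
    assert runs[0][0].equals(runs[1][0])
    assert all(np.array_equal(runs[0][1][k], runs[1][1][k]) for k in runs[0][1])


def test_empty_training_set_raises():
    clf = ms.PatchClassifier()
    with pytest.raises(DataError):
        clf.fit((np.empty((0, MicroCNN.FEATURE_DIM)), np.empty(0, dtype=int)))


def test_full_backprop_path_trains_conv_groups(rng):
    """With every group unfrozen, convolutional weights receive updates."""
    X = rng.random((12, 224, 224)).astype(np.float32)
    y = rng.integers(0, 5, size=12)
    cfg = ms.TrainingConfig(num_train_layers=6, max_epochs=1, batch_size=6,
                            early_stopping_patience=1, initial_lr=1e-3, seed=10)
    clf = ms.PatchClassifier(cfg)
    before = clf.net.copy_params()
    clf.fit((X, y))
    after = clf.net.flat_params()
    assert not np.array_equal(after["conv1.W"], before["conv1.W"])
    assert clf.frozen_groups == ()


def test_backprop_matches_numerical_gradients(rng):
    """Central-difference check of the full analytic gradient."""
    net = MicroCNN(seed=12)
    # float64 throughout so finite differences are numerically clean
    for g in net.params:
        for k in net.params[g]:
            net.params[g][k] = net.params[g][k].astype(np.float64)
    x = rng.random((2, 3, 224, 224))
    y = np.array([1, 3])

    def loss_fn():
        feat, _ = net._forward_backbone(x, want_cache=False)
        logits, _ = net.head_forward(feat)
        loss, _ = cross_entropy(logits, y)
        return loss

    feat, bcache = net._forward_backbone(x, want_cache=True)
    logits, hcache = net.head_forward(feat, want_cache=True)
    _, dlogits = cross_entropy(logits, y)
    grads, dfeat = net.backward_head(dlogits, hcache)
    grads.update(net.backward_backbone(dfeat, bcache))

    eps = 1e-5  # small enough not to cross relu / max-pool kinks
    check_rng = np.random.default_rng(13)
    for key in ("conv1.W", "conv2.W", "conv3.W", "fc1.W", "head.W", "conv2.b"):
        g, name = key.split(".")
        param = net.params[g][name]
        flat_idx = check_rng.integers(0, param.size, size=3)
        for idx in flat_idx:
            ij = np.unravel_index(idx, param.shape)
            orig = param[ij]
            param[ij] = orig + eps
            lp = loss_fn()
            param[ij] = orig - eps
            lm = loss_fn()
            param[ij] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[key][ij]
            assert numeric == pytest.approx(analytic, rel=1e-3, abs=1e-7), key


# -- inference ---------------------------------------------------------------


def test_predictions_are_valid_distributions_and_deterministic(rng):
    clf = ms.PatchClassifier(ms.TrainingConfig(seed=14))
    patches = [
        ms.Patch("img", 0, c, rng.random((224, 224)).astype(np.float32))
        for c in range(3)
    ]
    preds1 = clf.predict_patches(patches)
    preds2 = clf.predict_patches(patches + patches[:1])  # duplicate submission
    for p in preds1:
        assert abs(p.probabilities.sum() - 1.0) < 1e-6
        assert (p.probabilities >= 0).all()
    assert np.array_equal(preds1[0].probabilities, preds2[3].probabilities)


def test_argmax_tie_breaks_to_lowest_class_index():
    p = PatchPrediction("x", np.array([0.3, 0.3, 0.3, 0.05, 0.05]))
    assert p.label == "apo"
    p = PatchPrediction("x", np.array([0.1, 0.0, 0.45, 0.45, 0.0]))
    assert p.label == "fer"


def test_checkpoint_roundtrip_preserves_predictions(tmp_path, rng):
    X, y = _separable_features(20, seed=15)
    clf = ms.PatchClassifier(ms.TrainingConfig.cpu_protocol(seed=16, max_epochs=3))
    clf.fit((X, y))
    clf.save(tmp_path / "ckpt.npz")
    back = ms.PatchClassifier.load(tmp_path / "ckpt.npz")
    probe = rng.random((4, 224, 224)).astype(np.float32)
    assert np.array_equal(clf.predict_proba(probe), back.predict_proba(probe))


def test_summary_mentions_key_facts():
    X, y = _separable_features(20, seed=17)
    clf = ms.PatchClassifier(ms.TrainingConfig.cpu_protocol(seed=18, max_epochs=2))
    res = clf.fit((X, y))
    text = res.summary()
    assert "micro_cnn" in text
    assert "fc1, fc2, head" in text
    assert "frozen weights intact: True" in text
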