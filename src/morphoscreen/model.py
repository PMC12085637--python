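"""Transfer-learning patch classifier: model and results objects.

:class:`PatchClassifier` wraps a convolutional backbone whose parameters
form an ordered list of groups; only the last ``num_train_layers`` groups
are trainable, the rest stay frozen (bit-identical across training).
Training minimizes cross-entropy with Adam under a stepped learning-rate
schedule (5% multiplicative decay every 5 epochs by default) and early
stopping on the validation loss, restoring the best-epoch weights.

``fit`` returns a :class:`TrainingResults` carrying the per-epoch history,
the best epoch and a ``summary()`` table, in the spirit of statsmodels'
model/results split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, TrainError
from .labels import CLASSES
from .nn import Adam, MicroCNN, cross_entropy, softmax
from .patches import Patch, PatchSet, normalize_patch, stack_to_three_channels

BACKBONES = ("micro_cnn",)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization schedule and backbone selection.

    Defaults follow the reference protocol: batch size 100, up to 50
    epochs, early-stopping patience 25, Adam with initial learning rate
    1e-4 decayed by 5% every five epochs, and the last three parameter
    groups trainable.
    """

    batch_size: int = 100
    max_epochs: int = 50
    early_stopping_patience: int = 25
    initial_lr: float = 1e-4
    lr_decay_fraction: float = 0.05
    lr_decay_interval_epochs: int = 5
    num_train_layers: int = 3
    seed: int = 0
    backbone_id: str = "micro_cnn"
    pretrained: bool = False
    pretrained_path: str | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if not (0 <= self.lr_decay_fraction < 1):
            raise ConfigError("lr_decay_fraction must be in [0, 1)")
        if self.early_stopping_patience > self.max_epochs:
            raise ConfigError("early_stopping_patience must be <= max_epochs")
        if self.lr_decay_interval_epochs < 1:
            raise ConfigError("lr_decay_interval_epochs must be >= 1")
        if self.num_train_layers < 0:
            raise ConfigError("num_train_layers must be >= 0")

    @classmethod
    def cpu_protocol(cls, seed: int = 0, max_epochs: int = 10) -> "TrainingConfig":
        """Fast CPU-scale schedule for head-only training from random init.

        The reference schedule's 1e-4 learning rate suits fine-tuning a
        pretrained backbone over 50 epochs; a dense suffix trained from
        random initialization in <= 10 epochs needs the larger 1e-3 step
        to converge in the few hundred Adam updates available.
        """
        return cls(
            max_epochs=max_epochs,
            early_stopping_patience=max_epochs,
            initial_lr=1e-3,
            seed=seed,
        )


def lr_at_epoch(config: TrainingConfig, epoch: int) -> float:
    """Stepped learning rate: lr0 * (1 - decay)^floor(epoch / interval)."""
    if epoch < 0:
        raise ConfigError(f"epoch must be >= 0, got {epoch}")
    steps = epoch // config.lr_decay_interval_epochs
    return config.initial_lr * (1.0 - config.lr_decay_fraction) ** steps


@dataclass
class PatchPrediction:
    """Per-patch class probabilities and the argmax label."""

    patch_id: str
    probabilities: np.ndarray  # length-5, sums to 1

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.shape != (len(CLASSES),):
            raise DataError("probability vector must have one entry per class")
        if abs(self.probabilities.sum() - 1.0) > 1e-6 or (self.probabilities < 0).any():
            raise DataError("probabilities must be non-negative and sum to 1")

    @property
    def label(self) -> str:
        # np.argmax returns the first maximum -> lowest class index on ties
        return CLASSES[int(np.argmax(self.probabilities))]


class PatchClassifier:
    """Five-way cell-state classifier over 224 x 224 brightfield patches.

    Parameters are grouped in backbone order; with the default
    ``num_train_layers = 3`` the convolutional stages stay frozen and act
    as a fixed feature extractor, so training touches only the dense
    suffix.  When the backbone is frozen, features are precomputed once
    per dataset, which makes CPU training fast even for thousands of
    patches.
    """

    def __init__(self, config: TrainingConfig | None = None):
        self.config = config or TrainingConfig()
        if self.config.backbone_id not in BACKBONES:
            raise ConfigError(
                f"unknown backbone {self.config.backbone_id!r}; available: {BACKBONES}"
            )
        self.net = MicroCNN(n_classes=len(CLASSES), seed=self.config.seed)
        # fixed feature standardization between backbone and head; set once
        # from the training features at fit start, never updated afterwards
        self.feature_mu = np.zeros(self.net.FEATURE_DIM, dtype=np.float32)
        self.feature_sd = np.ones(self.net.FEATURE_DIM, dtype=np.float32)
        if self.config.pretrained:
            if not self.config.pretrained_path:
                raise ConfigError(
                    "pretrained=True requires pretrained_path pointing at a checkpoint"
                )
            flat = dict(np.load(self.config.pretrained_path))
            if "_feature_mu" in flat:
                self.feature_mu = flat.pop("_feature_mu")
                self.feature_sd = flat.pop("_feature_sd")
            self.net.set_flat(flat)
        self.classes_: tuple[str, ...] = CLASSES

    # -- parameter groups ---------------------------------------------------

    @property
    def trainable_groups(self) -> tuple[str, ...]:
        k = min(self.config.num_train_layers, len(self.net.GROUPS))
        return self.net.GROUPS[len(self.net.GROUPS) - k :] if k else ()

    @property
    def frozen_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.net.GROUPS if g not in self.trainable_groups)

    @property
    def backbone_frozen(self) -> bool:
        """True when no convolutional group is trainable (features cacheable)."""
        return not any(g.startswith("conv") for g in self.trainable_groups)

    # -- input preparation --------------------------------------------------

    @staticmethod
    def prepare(pixels: np.ndarray) -> np.ndarray:
        """Normalize raw patches and stack to the (B, 3, 224, 224) input."""
        pixels = np.asarray(pixels, dtype=np.float32)
        if pixels.ndim == 2:
            pixels = pixels[None]
        out = np.empty((len(pixels), 3, *pixels.shape[1:]), dtype=np.float32)
        for i, p in enumerate(pixels):
            out[i] = np.moveaxis(stack_to_three_channels(normalize_patch(p)), 2, 0)
        return out

    def _scale(self, feat: np.ndarray) -> np.ndarray:
        return (feat - self.feature_mu) / self.feature_sd

    def _set_feature_scale(self, feats: np.ndarray) -> None:
        self.feature_mu = feats.mean(axis=0).astype(np.float32)
        self.feature_sd = np.maximum(feats.std(axis=0), 1e-6).astype(np.float32)

    def featurize(self, pixels: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Frozen-backbone features for raw single-channel patches."""
        pixels = np.asarray(pixels, dtype=np.float32)
        if pixels.ndim == 2:
            pixels = pixels[None]
        feats = np.empty((len(pixels), self.net.FEATURE_DIM), dtype=np.float32)
        for s in range(0, len(pixels), batch_size):
            feats[s : s + batch_size] = self.net.features(
                self.prepare(pixels[s : s + batch_size])
            )
        return feats

    def featurize_patchset(self, ps: PatchSet, batch_size: int = 64):
        """Stream a PatchSet through the backbone: (features, labels, ids)."""
        feats, ys, ids = [], [], []
        for pix, y, pids in ps.iter_batches(batch_size):
            feats.append(self.net.features(self.prepare(pix)))
            ys.append(y)
            ids.extend(pids)
        n = len(ids)
        F = np.concatenate(feats) if feats else np.empty((0, self.net.FEATURE_DIM))
        yv = np.concatenate(ys) if ys else np.empty(0, dtype=np.int64)
        return F, yv, ids

    # -- training -----------------------------------------------------------

    def _coerce(self, data) -> tuple[np.ndarray, np.ndarray, bool]:
        """Return (X-or-F, y, is_features)."""
        if isinstance(data, PatchSet):
            if self.backbone_frozen:
                F, y, _ = self.featurize_patchset(data)
                return F, y, True
            rows = data.index
            ps = data.grid.patch_size
            X = np.empty((len(rows), ps, ps), dtype=np.float32)
            ys = np.empty(len(rows), dtype=np.int64)
            pos = 0
            for pix, y, _ in data.iter_batches(256):
                X[pos : pos + len(y)] = pix
                ys[pos : pos + len(y)] = y
                pos += len(y)
            return X, ys, False
        X, y = data
        X = np.asarray(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise DataError("inputs and labels differ in length")
        is_features = X.ndim == 2
        if is_features and X.shape[1] != self.net.FEATURE_DIM:
            raise DataError(
                f"feature matrix must have {self.net.FEATURE_DIM} columns"
            )
        if is_features and not self.backbone_frozen:
            raise DataError("cannot train convolutional groups from cached features")
        return X.astype(np.float32), y, is_features

    def fit(self, train, val=None) -> "TrainingResults":
        """Train the unfrozen suffix; returns the results object.

        ``train``/``val`` may be a :class:`PatchSet`, a ``(pixels, labels)``
        pair of raw 224 x 224 patches, or a ``(features, labels)`` pair of
        cached backbone features (frozen backbone only).
        """
        cfg = self.config
        Xtr, ytr, tr_is_feat = self._coerce(train)
        if len(Xtr) == 0:
            raise DataError("training set is empty")
        if val is not None:
            Xval, yval, val_is_feat = self._coerce(val)
            if val_is_feat != tr_is_feat:
                raise DataError("train and validation inputs must be the same kind")
        else:
            Xval = yval = None

        if not tr_is_feat and self.backbone_frozen:
            # cache features once: the frozen convolutional stages never change
            Xtr, tr_is_feat = self.featurize(Xtr), True
            if Xval is not None:
                Xval = self.featurize(Xval)

        if tr_is_feat:
            self._set_feature_scale(Xtr)
        else:
            self._set_feature_scale(self.featurize(Xtr))

        initial = self.net.copy_params()
        trainable = self.net.flat_params(self.trainable_groups)
        opt = Adam(trainable)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7261696E]))

        history: list[dict] = []
        best_loss = np.inf
        best_epoch = -1
        best_params = {k: v.copy() for k, v in trainable.items()}
        epochs_since_best = 0
        stopped_early = False

        for epoch in range(cfg.max_epochs):
            lr = lr_at_epoch(cfg, epoch)
            order = rng.permutation(len(Xtr))
            epoch_loss = 0.0
            if trainable:
                for s in range(0, len(order), cfg.batch_size):
                    idx = order[s : s + cfg.batch_size]
                    loss, grads = self._batch_grads(Xtr[idx], ytr[idx], tr_is_feat)
                    if not np.isfinite(loss):
                        raise TrainError(f"non-finite training loss at epoch {epoch}")
                    epoch_loss += loss * len(idx)
                    opt.step(trainable, {k: grads[k] for k in trainable}, lr)
                epoch_loss /= len(Xtr)
            else:
                epoch_loss = self._eval_loss(Xtr, ytr, tr_is_feat)

            val_loss = (
                self._eval_loss(Xval, yval, tr_is_feat) if Xval is not None else None
            )
            monitor = val_loss if val_loss is not None else epoch_loss
            history.append(
                {"epoch": epoch, "lr": lr, "train_loss": epoch_loss, "val_loss": val_loss}
            )
            if monitor < best_loss - 1e-12:
                best_loss = monitor
                best_epoch = epoch
                best_params = {k: v.copy() for k, v in trainable.items()}
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best >= cfg.early_stopping_patience:
                    stopped_early = True
                    break

        # restore the best-validation-epoch weights
        for k, v in best_params.items():
            g, name = k.split(".")
            self.net.params[g][name] = v.copy()

        return TrainingResults(
            model=self,
            history=pd.DataFrame(
                history, columns=["epoch", "lr", "train_loss", "val_loss"]
            ),
            best_epoch=best_epoch,
            stopped_early=stopped_early,
            initial_params=initial,
        )

    def _batch_grads(self, X, y, is_features):
        if is_features:
            logits, cache = self.net.head_forward(self._scale(X), want_cache=True)
            loss, dlogits = cross_entropy(logits, y)
            grads, _ = self.net.backward_head(dlogits, cache)
            return loss, grads
        feat, bcache = self.net._forward_backbone(self.prepare(X), want_cache=True)
        logits, hcache = self.net.head_forward(self._scale(feat), want_cache=True)
        loss, dlogits = cross_entropy(logits, y)
        grads, dfeat_scaled = self.net.backward_head(dlogits, hcache)
        grads.update(self.net.backward_backbone(dfeat_scaled / self.feature_sd, bcache))
        return loss, grads

    def _eval_loss(self, X, y, is_features, batch_size: int = 256) -> float:
        total = 0.0
        for s in range(0, len(X), batch_size):
            xb = X[s : s + batch_size]
            feat = xb if is_features else self.net.features(self.prepare(xb))
            logits, _ = self.net.head_forward(self._scale(feat))
            loss, _ = cross_entropy(logits, y[s : s + batch_size])
            total += loss * len(xb)
        return total / max(len(X), 1)

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X, is_features: bool | None = None, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if is_features is None:
            is_features = X.ndim == 2
        out = np.empty((len(X), len(CLASSES)))
        for s in range(0, len(X), batch_size):
            xb = X[s : s + batch_size]
            if is_features:
                feat = xb
            else:
                if xb.shape[1:] != (224, 224):
                    raise DataError(f"expected (B, 224, 224) patches, got {xb.shape}")
                feat = self.net.features(self.prepare(xb))
            logits, _ = self.net.head_forward(self._scale(feat))
            out[s : s + batch_size] = softmax(logits)
        return out

    def predict_patches(self, patches: Sequence[Patch] | PatchSet) -> list[PatchPrediction]:
        """Class probabilities for each patch (deterministic inference)."""
        if isinstance(patches, PatchSet):
            preds: list[PatchPrediction] = []
            for pix, _, ids in patches.iter_batches(256):
                probs = self.predict_proba(pix, is_features=False)
                preds.extend(PatchPrediction(pid, p) for pid, p in zip(ids, probs))
            return preds
        pix = np.stack([p.pixels for p in patches])
        probs = self.predict_proba(pix, is_features=False)
        return [
            PatchPrediction(p.patch_id, pr) for p, pr in zip(patches, probs)
        ]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path, history: pd.DataFrame | None = None) -> None:
        """Checkpoint parameters (.npz) with a JSON sidecar (config, labels)."""
        path = Path(path)
        np.savez(
            path,
            **self.net.flat_params(),
            _feature_mu=self.feature_mu,
            _feature_sd=self.feature_sd,
        )
        sidecar = {
            "label_order": list(CLASSES),
            "config": asdict(self.config),
            "history": None
            if history is None
            else history.where(pd.notna(history), None).to_dict(orient="records"),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PatchClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        clf = cls(TrainingConfig(**sidecar["config"]))
        archive = dict(np.load(path if path.suffix else path.with_suffix(".npz")))
        clf.feature_mu = archive.pop("_feature_mu")
        clf.feature_sd = archive.pop("_feature_sd")
        clf.net.set_flat(archive)
        return clf


@dataclass
class TrainingResults:
    """Outcome of :meth:`PatchClassifier.fit`.

    Carries the fitted model, the per-epoch history (learning rate, train
    and validation loss), the best-validation epoch whose weights the model
    now holds, and the initial parameter snapshot used to verify
    frozen-group invariance.
    """

    model: PatchClassifier
    history: pd.DataFrame
    best_epoch: int
    stopped_early: bool
    initial_params: dict[str, np.ndarray] = field(repr=False)

    @property
    def n_epochs_run(self) -> int:
        return len(self.history)

    def frozen_params_unchanged(self) -> bool:
        """Exact check: every non-trainable parameter equals its initial value."""
        frozen_keys = set(self.model.net.flat_params(self.model.frozen_groups))
        current = self.model.net.flat_params()
        return all(
            np.array_equal(current[k], self.initial_params[k]) for k in frozen_keys
        )

    def evaluate(self, X, y) -> float:
        """Accuracy on held-out data (raw patches or cached features)."""
        probs = self.model.predict_proba(X)
        return float(np.mean(probs.argmax(axis=1) == np.asarray(y)))

    def summary(self) -> str:
        cfg = self.model.config
        n_trainable = sum(
            v.size for v in self.model.net.flat_params(self.model.trainable_groups).values()
        )
        n_total = sum(v.size for v in self.model.net.flat_params().values())
        last = self.history.iloc[-1] if len(self.history) else None
        lines = [
            "PatchClassifier training results",
            "=" * 40,
            f"backbone:            {cfg.backbone_id}",
            f"classes:             {', '.join(CLASSES)}",
            f"trainable groups:    {', '.join(self.model.trainable_groups) or '(none)'}",
            f"parameters:          {n_trainable} trainable / {n_total} total",
            f"epochs run:          {self.n_epochs_run} (max {cfg.max_epochs})",
            f"early stopped:       {self.stopped_early}",
            f"best epoch:          {self.best_epoch}",
        ]
        if last is not None:
            lines.append(f"final train loss:    {last['train_loss']:.4f}")
            if last["val_loss"] is not None and not pd.isna(last["val_loss"]):
                lines.append(f"final val loss:      {last['val_loss']:.4f}")
        lines.append(f"frozen weights intact: {self.frozen_params_unchanged()}")
        return "\n".join(lines)
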