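"""Minimal CPU neural-network primitives for the patch classifier.

Implements exactly what the transfer-learning harness needs: 2-D
convolution via im2col, 2x2 max pooling, global mean+max pooling, dense
layers, softmax cross-entropy and Adam — all in numpy, fully deterministic
for a fixed seed.  The :class:`MicroCNN` backbone exposes its parameters as
an *ordered list of groups* so that "train only the last k layers" has a
precise meaning: groups outside the trainable suffix are never touched by
the optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# functional layers


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, pad: int):
    """Stride-1 'same-ish' convolution. x: (B,C,H,W); W: (O,C,kh,kw)."""
    B, C, H, Wd = x.shape
    O, _, kh, kw = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,C,Ho,Wo,kh,kw)
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
    y = cols @ W.reshape(O, -1).T + b
    y = y.transpose(0, 2, 1).reshape(B, O, Ho, Wo)
    return y, cols


def conv2d_backward(dy: np.ndarray, cols: np.ndarray, x_shape, W: np.ndarray, pad: int):
    """Gradients of conv2d_forward w.r.t. W, b and x."""
    B, C, H, Wd = x_shape
    O, _, kh, kw = W.shape
    Ho, Wo = dy.shape[2], dy.shape[3]
    dyf = dy.reshape(B, O, Ho * Wo).transpose(0, 2, 1)  # (B, HoWo, O)
    dWmat = np.einsum("bpo,bpk->ok", dyf, cols)
    db = dyf.sum(axis=(0, 1))
    dcols = dyf @ W.reshape(O, -1)  # (B, HoWo, C*kh*kw)
    dcols = dcols.reshape(B, Ho, Wo, C, kh, kw)
    dxp = np.zeros((B, C, H + 2 * pad, Wd + 2 * pad), dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    dx = dxp[:, :, pad : pad + H, pad : pad + Wd] if pad else dxp
    return dWmat.reshape(W.shape), db, dx


def maxpool2_forward(x: np.ndarray):
    B, C, H, W = x.shape
    xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    # split gradient equally among tied maxima
    counts = mask.sum(axis=(3, 5), keepdims=True)
    return y, (mask, counts, x.shape)


def maxpool2_backward(dy: np.ndarray, cache):
    mask, counts, x_shape = cache
    B, C, H, W = x_shape
    d = mask * (dy[:, :, :, None, :, None] / counts)
    return d.reshape(B, C, H, W)


def avgpool_forward(x: np.ndarray, k: int):
    B, C, H, W = x.shape
    return x.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))


def global_pool_forward(a: np.ndarray):
    """Per-channel global mean and max, concatenated: (B,C,H,W) -> (B,2C)."""
    mean = a.mean(axis=(2, 3))
    amax = a.max(axis=(2, 3))
    mask = a == amax[:, :, None, None]
    counts = mask.sum(axis=(2, 3), keepdims=True)
    return np.concatenate([mean, amax], axis=1), (mask, counts, a.shape)


def global_pool_backward(dg: np.ndarray, cache):
    mask, counts, a_shape = cache
    B, C, H, W = a_shape
    dmean = dg[:, :C, None, None] / (H * W)
    dmax = mask * (dg[:, C:, None, None] / counts)
    return np.broadcast_to(dmean, a_shape) + dmax


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    eps = np.finfo(p.dtype).tiny
    loss = -float(np.mean(np.log(p[np.arange(n), y] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the backbone


class MicroCNN:
    """Compact multi-scale convolutional backbone with a 5-way head.

    Architecture (input (B, 3, 224, 224), channels replicated grayscale):

    ====== =====================================  ==================
    group  operation                              output
    ====== =====================================  ==================
    (stem) 4x4 average pool, no parameters        (B, 3, 56, 56)
    conv1  5x5 conv -> ReLU                       (B, 12, 56, 56)
           2x2 max pool                           (B, 12, 28, 28)
    conv2  3x3 conv -> ReLU                       (B, 24, 28, 28)
           2x2 max pool                           (B, 24, 14, 14)
    conv3  3x3 conv -> ReLU                       (B, 32, 14, 14)
    (gp)   global mean+max pool of conv1/2/3      (B, 136)
    fc1    dense -> ReLU                          (B, 64)
    fc2    dense -> ReLU                          (B, 48)
    head   dense (logits)                         (B, 5)
    ====== =====================================  ==================

    The multi-scale feature vector (global statistics of all three
    convolutional stages) keeps the frozen backbone informative even with
    random filters, which is what makes CPU-scale fine-tuning of only the
    dense suffix effective.
    """

    GROUPS: tuple[str, ...] = ("conv1", "conv2", "conv3", "fc1", "fc2", "head")
    FEATURE_DIM = 2 * (12 + 24 + 32)

    def __init__(self, n_classes: int = 5, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        self.params: dict[str, dict[str, np.ndarray]] = {
            "conv1": {"W": he((12, 3, 5, 5), 3 * 25), "b": np.zeros(12, np.float32)},
            "conv2": {"W": he((24, 12, 3, 3), 12 * 9), "b": np.zeros(24, np.float32)},
            "conv3": {"W": he((32, 24, 3, 3), 24 * 9), "b": np.zeros(32, np.float32)},
            "fc1": {"W": he((self.FEATURE_DIM, 64), self.FEATURE_DIM), "b": np.zeros(64, np.float32)},
            "fc2": {"W": he((64, 48), 64), "b": np.zeros(48, np.float32)},
            "head": {"W": he((48, n_classes), 48), "b": np.zeros(n_classes, np.float32)},
        }

    # -- parameter plumbing -------------------------------------------------

    def flat_params(self, groups: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
        groups = self.GROUPS if groups is None else groups
        return {f"{g}.{k}": v for g in groups for k, v in self.params[g].items()}

    def set_flat(self, flat: dict[str, np.ndarray]) -> None:
        for key, v in flat.items():
            g, k = key.split(".")
            self.params[g][k] = v.copy()

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.flat_params().items()}

    # -- forward ------------------------------------------------------------

    def features(self, x: np.ndarray) -> np.ndarray:
        """Frozen-boundary features (after conv3): (B, 3, 224, 224) -> (B, 136)."""
        feat, _ = self._forward_backbone(x, want_cache=False)
        return feat

    def _forward_backbone(self, x: np.ndarray, want_cache: bool):
        p = self.params
        if not np.issubdtype(x.dtype, np.floating):
            x = x.astype(np.float32)
        s = avgpool_forward(x, 4)
        z1, cols1 = conv2d_forward(s, p["conv1"]["W"], p["conv1"]["b"], pad=2)
        a1 = np.maximum(z1, 0)
        p1, mp1 = maxpool2_forward(a1)
        z2, cols2 = conv2d_forward(p1, p["conv2"]["W"], p["conv2"]["b"], pad=1)
        a2 = np.maximum(z2, 0)
        p2, mp2 = maxpool2_forward(a2)
        z3, cols3 = conv2d_forward(p2, p["conv3"]["W"], p["conv3"]["b"], pad=1)
        a3 = np.maximum(z3, 0)
        g1, gc1 = global_pool_forward(a1)
        g2, gc2 = global_pool_forward(a2)
        g3, gc3 = global_pool_forward(a3)
        feat = np.concatenate([g1, g2, g3], axis=1)
        cache = None
        if want_cache:
            cache = dict(
                s=s, z1=z1, a1=a1, cols1=cols1, mp1=mp1, p1=p1,
                z2=z2, a2=a2, cols2=cols2, mp2=mp2, p2=p2,
                z3=z3, a3=a3, cols3=cols3,
                gc1=gc1, gc2=gc2, gc3=gc3,
            )
        return feat, cache

    def head_forward(self, feat: np.ndarray, want_cache: bool = False):
        p = self.params
        h1 = np.maximum(feat @ p["fc1"]["W"] + p["fc1"]["b"], 0)
        h2 = np.maximum(h1 @ p["fc2"]["W"] + p["fc2"]["b"], 0)
        logits = h2 @ p["head"]["W"] + p["head"]["b"]
        cache = dict(feat=feat, h1=h1, h2=h2) if want_cache else None
        return logits, cache

    def forward(self, x: np.ndarray, want_cache: bool = False):
        feat, bcache = self._forward_backbone(x, want_cache)
        logits, hcache = self.head_forward(feat, want_cache)
        if want_cache:
            hcache["backbone"] = bcache
        return logits, hcache

    def predict_proba_from_features(self, feat: np.ndarray) -> np.ndarray:
        logits, _ = self.head_forward(feat)
        return softmax(logits)

    # -- backward -----------------------------------------------------------

    def backward_head(self, dlogits: np.ndarray, cache) -> tuple[dict, np.ndarray]:
        """Gradients for fc1/fc2/head and the upstream feature gradient."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        h2, h1, feat = cache["h2"], cache["h1"], cache["feat"]
        grads["head.W"] = h2.T @ dlogits
        grads["head.b"] = dlogits.sum(axis=0)
        dh2 = (dlogits @ p["head"]["W"].T) * (h2 > 0)
        grads["fc2.W"] = h1.T @ dh2
        grads["fc2.b"] = dh2.sum(axis=0)
        dh1 = (dh2 @ p["fc2"]["W"].T) * (h1 > 0)
        grads["fc1.W"] = feat.T @ dh1
        grads["fc1.b"] = dh1.sum(axis=0)
        dfeat = dh1 @ p["fc1"]["W"].T
        return grads, dfeat

    def backward_backbone(self, dfeat: np.ndarray, cache) -> dict:
        """Gradients for conv1/conv2/conv3 given the feature gradient."""
        p = self.params
        c = cache
        g1 = dfeat[:, : 2 * 12]
        g2 = dfeat[:, 2 * 12 : 2 * 12 + 2 * 24]
        g3 = dfeat[:, 2 * 12 + 2 * 24 :]
        grads: dict[str, np.ndarray] = {}

        da3 = global_pool_backward(g3, c["gc3"]) * (c["z3"] > 0)
        dW3, db3, dp2 = conv2d_backward(da3, c["cols3"], c["p2"].shape, p["conv3"]["W"], pad=1)
        grads["conv3.W"], grads["conv3.b"] = dW3, db3

        da2 = global_pool_backward(g2, c["gc2"]) + maxpool2_backward(dp2, c["mp2"])
        da2 *= c["z2"] > 0
        dW2, db2, dp1 = conv2d_backward(da2, c["cols2"], c["p1"].shape, p["conv2"]["W"], pad=1)
        grads["conv2.W"], grads["conv2.b"] = dW2, db2

        da1 = global_pool_backward(g1, c["gc1"]) + maxpool2_backward(dp1, c["mp1"])
        da1 *= c["z1"] > 0
        dW1, db1, _ = conv2d_backward(da1, c["cols1"], c["s"].shape, p["conv1"]["W"], pad=2)
        grads["conv1.W"], grads["conv1.b"] = dW1, db1
        return grads
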