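"""Dual-backbone fusion network and 1024-d deep-feature extraction.

The architecture follows the transfer-learning design for mass classification:
two convolutional backbones (a VGG16-style stack pooling to 512 channels and
an Inception-V3-style stack pooling to 2048), global pooling per branch,
concatenation to 2560, then a three-layer fully connected head
2560 -> 2048 -> 1024 -> 2 with dropout and a softmax output. The activation of
the second FC layer is the 1024-dimensional deep feature.

This module is self-contained numpy. Backbones are deterministic seeded
random-weight convolutional stacks (the ``tiny_test`` weights origin) that
expose exactly the contract dimensions; they act as fixed feature extractors
while the FC head is trained by hand-written backprop with SGD (momentum,
weight decay, cross-entropy). Requesting ``weights_origin="pretrained"``
raises: no published backbone weights are bundled, and silently substituting
random weights for them would be misleading.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import PreprocessedROI

__all__ = [
    "FusionNetworkSpec",
    "TrainConfig",
    "DeepFeatureVector",
    "MissingWeightsError",
    "FusionNetwork",
    "Vgg16Baseline",
    "build_fusion_network",
    "build_vgg16_baseline",
    "fine_tune",
    "extract_deep_features",
]

INPUT_SIZE = 224
VGG_POOLED_DIM = 512
INCEPTION_POOLED_DIM = 2048
CONCAT_DIM = VGG_POOLED_DIM + INCEPTION_POOLED_DIM
FC1_DIM = 2048
FC2_DIM = 1024
N_CLASSES = 2


class MissingWeightsError(RuntimeError):
    """Pretrained backbone weights were requested but are not available."""


@dataclass(frozen=True)
class FusionNetworkSpec:
    pooling: Literal["global_max", "global_average"] = "global_max"
    dropout_rate: float = 0.5
    frozen_prefix_layers: int = 12  # recorded fine-tuning metadata
    weights_origin: Literal["pretrained", "random", "tiny_test"] = "tiny_test"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 16
    seed: int = 0


@dataclass
class DeepFeatureVector:
    values: np.ndarray  # 1024 reals
    roi_id: str
    network_fingerprint: str


# ---------------------------------------------------------------------------
# convolutional backbone (fixed random weights)


def _conv(x: np.ndarray, W: np.ndarray, stride: int) -> np.ndarray:
    """Valid-mode strided convolution; x is (H, W, Cin), W is (kh, kw, Cin, Cout)."""
    kh, kw = W.shape[:2]
    patches = sliding_window_view(x, (kh, kw), axis=(0, 1))[::stride, ::stride]
    # patches: (Ho, Wo, Cin, kh, kw)
    return np.einsum("hwcij,ijco->hwo", patches, W, optimize=True)


class _ConvStack:
    """A small fixed-weight conv stack ending in global pooling."""

    def __init__(self, pooled_dim: int, pooling: str, seed: int):
        rng = np.random.default_rng(seed)
        plan = [(5, 3, 8, 4), (3, 8, 16, 2), (3, 16, 32, 2), (1, 32, pooled_dim, 1)]
        self.layers = []
        for k, cin, cout, stride in plan:
            scale = np.sqrt(2.0 / (k * k * cin))
            self.layers.append((rng.standard_normal((k, k, cin, cout)) * scale, stride))
        self.pooled_dim = pooled_dim
        self.pooling = pooling

    def forward(self, img: np.ndarray) -> np.ndarray:
        x = img
        for W, stride in self.layers:
            x = np.maximum(_conv(x, W, stride), 0.0)
        if self.pooling == "global_max":
            return x.max(axis=(0, 1))
        return x.mean(axis=(0, 1))

    def weight_bytes(self) -> bytes:
        return b"".join(np.ascontiguousarray(W).tobytes() for W, _ in self.layers)


def _prepare_batch(images) -> np.ndarray:
    """Accept PreprocessedROI / 2-D / 3-D inputs; return (n, 224, 224, 3)."""
    arrs = []
    for im in images:
        a = im.pixels if isinstance(im, PreprocessedROI) else np.asarray(im, dtype=np.float64)
        if a.ndim == 2:
            a = np.repeat(a[:, :, None], 3, axis=2)
        if a.shape[:2] != (INPUT_SIZE, INPUT_SIZE) or a.shape[2] != 3:
            raise ValueError(f"expected {INPUT_SIZE}x{INPUT_SIZE} grayscale or 3-channel input, got {a.shape}")
        arrs.append(a.astype(np.float64))
    return np.stack(arrs)


# ---------------------------------------------------------------------------
# fully connected head with manual backprop


class _Head:
    """FC layers with ReLU between and dropout after each hidden layer."""

    def __init__(self, dims: Sequence[int], dropout_rate: float, seed: int):
        rng = np.random.default_rng(seed)
        self.dims = list(dims)
        self.W = [rng.standard_normal((a, b)) * np.sqrt(2.0 / a) for a, b in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(b) for b in dims[1:]]
        self.dropout_rate = dropout_rate
        self._vel = None

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        acts = [x]
        masks = []
        h = x
        L = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < L - 1:
                h = np.maximum(z, 0.0)
                if train and self.dropout_rate > 0:
                    keep = 1.0 - self.dropout_rate
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = z
            acts.append(h)
        zmax = h - h.max(axis=1, keepdims=True)
        e = np.exp(zmax)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, acts, masks

    def backward(self, probs, acts, masks, y_onehot):
        n = probs.shape[0]
        grads_W, grads_b = [None] * len(self.W), [None] * len(self.b)
        delta = (probs - y_onehot) / n
        for i in range(len(self.W) - 1, -1, -1):
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                delta = delta * (acts[i] > 0)
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
        return grads_W, grads_b

    def sgd_step(self, grads_W, grads_b, lr, momentum, weight_decay):
        if self._vel is None:
            self._vel = [np.zeros_like(W) for W in self.W] + [np.zeros_like(b) for b in self.b]
        params = self.W + self.b
        grads = [gW + weight_decay * W for gW, W in zip(grads_W, self.W)] + list(grads_b)
        for p, g, v in zip(params, grads, self._vel):
            v *= momentum
            v -= lr * g
            p += v

    def weight_bytes(self) -> bytes:
        return b"".join(np.ascontiguousarray(a).tobytes() for a in self.W + self.b)


# ---------------------------------------------------------------------------
# networks


class FusionNetwork:
    """Dual-backbone fusion classifier exposing fc2 activations."""

    def __init__(self, spec: FusionNetworkSpec):
        if spec.weights_origin == "pretrained":
            raise MissingWeightsError(
                "pretrained backbone weights are not bundled; use weights_origin='tiny_test' "
                "or 'random', or supply a framework checkpoint out of band"
            )
        self.spec = spec
        self.branch_a = _ConvStack(VGG_POOLED_DIM, spec.pooling, seed=spec.seed * 7919 + 1)
        self.branch_b = _ConvStack(INCEPTION_POOLED_DIM, spec.pooling, seed=spec.seed * 7919 + 2)
        self.head = _Head((CONCAT_DIM, FC1_DIM, FC2_DIM, N_CLASSES), spec.dropout_rate, seed=spec.seed * 7919 + 3)
        assert self.head.dims == [2560, 2048, 1024, 2]
        self.feature_dim = FC2_DIM
        self._train_rng = np.random.default_rng(spec.seed * 7919 + 4)
        self._feature_cache: dict[int, np.ndarray] = {}

    # -- plumbing

    def backbone_features(self, batch: np.ndarray) -> np.ndarray:
        out = np.empty((batch.shape[0], CONCAT_DIM))
        for i, img in enumerate(batch):
            out[i, :VGG_POOLED_DIM] = self.branch_a.forward(img)
            out[i, VGG_POOLED_DIM:] = self.branch_b.forward(img)
        return out

    def forward(self, images, train: bool = False):
        """Class probabilities (n, 2) and fc2 activations (n, 1024)."""
        batch = _prepare_batch(images)
        feats = self.backbone_features(batch)
        probs, acts, _ = self.head.forward(feats, train=train, rng=self._train_rng)
        return probs, acts[2]  # acts[2] = output of second FC layer (post-ReLU/dropout)

    __call__ = forward

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.spec).encode())
        h.update(self.branch_a.weight_bytes())
        h.update(self.branch_b.weight_bytes())
        h.update(self.head.weight_bytes())
        return h.hexdigest()[:16]


class Vgg16Baseline:
    """Single-backbone comparison arm: conv stack -> GAP(512) -> FC1(1024) -> FC2(2)."""

    def __init__(self, spec: FusionNetworkSpec):
        if spec.weights_origin == "pretrained":
            raise MissingWeightsError("pretrained backbone weights are not bundled")
        self.spec = spec
        self.branch = _ConvStack(VGG_POOLED_DIM, "global_average", seed=spec.seed * 104729 + 1)
        self.head = _Head((VGG_POOLED_DIM, 1024, N_CLASSES), spec.dropout_rate, seed=spec.seed * 104729 + 2)
        self.pooled_dim = VGG_POOLED_DIM
        self.fc1_dim = 1024
        self.feature_dim = 1024
        self._train_rng = np.random.default_rng(spec.seed * 104729 + 3)

    def backbone_features(self, batch: np.ndarray) -> np.ndarray:
        return np.stack([self.branch.forward(img) for img in batch])

    def forward(self, images, train: bool = False):
        batch = _prepare_batch(images)
        feats = self.backbone_features(batch)
        probs, acts, _ = self.head.forward(feats, train=train, rng=self._train_rng)
        return probs, acts[1]

    __call__ = forward

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.spec).encode())
        h.update(self.branch.weight_bytes())
        h.update(self.head.weight_bytes())
        return h.hexdigest()[:16]


def build_fusion_network(spec: FusionNetworkSpec | None = None) -> FusionNetwork:
    return FusionNetwork(spec or FusionNetworkSpec())


def build_vgg16_baseline(spec: FusionNetworkSpec | None = None) -> Vgg16Baseline:
    return Vgg16Baseline(spec or FusionNetworkSpec())


# ---------------------------------------------------------------------------
# training


def fine_tune(network, train_images, labels, config: TrainConfig | None = None):
    """Train the FC head with SGD (momentum + weight decay) on cross-entropy.

    Backbone convolutions stay frozen; the head is where transfer-style
    adaptation happens here. Returns the network and a per-epoch trace of
    mean loss and training accuracy.
    """
    config = config or TrainConfig()
    y = np.asarray([1 if lb == "malignant" else (0 if lb == "benign" else int(lb)) for lb in labels])
    if np.unique(y).size < 2:
        raise ValueError("degenerate training set: a single class present")
    batch = _prepare_batch(train_images)
    feats = network.backbone_features(batch)
    onehot = np.eye(N_CLASSES)[y]

    rng = np.random.default_rng(config.seed)
    n = feats.shape[0]
    trace = {"loss": [], "accuracy": []}
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs, acts, masks = network.head.forward(feats[idx], train=True, rng=network._train_rng)
            eps = 1e-12
            losses.append(float(-(onehot[idx] * np.log(probs + eps)).sum() / idx.size))
            gW, gb = network.head.backward(probs, acts, masks, onehot[idx])
            network.head.sgd_step(gW, gb, config.learning_rate, config.momentum, config.weight_decay)
        probs_eval, _, _ = network.head.forward(feats, train=False)
        trace["loss"].append(float(np.mean(losses)))
        trace["accuracy"].append(float((probs_eval.argmax(axis=1) == y).mean()))
    return network, trace


def extract_deep_features(network, rois) -> list[DeepFeatureVector]:
    """One 1024-vector per ROI from the second FC layer, evaluation mode."""
    fp = network.fingerprint()
    _, fc2 = network.forward(rois, train=False)
    if fc2.shape[1] != FC2_DIM:
        raise RuntimeError(f"feature layer has dim {fc2.shape[1]}, expected {FC2_DIM}")
    out = []
    for i, roi in enumerate(rois):
        rid = roi.roi_id if isinstance(roi, PreprocessedROI) else str(i)
        out.append(DeepFeatureVector(values=fc2[i].copy(), roi_id=rid, network_fingerprint=fp))
    return out
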