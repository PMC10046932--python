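"""Recurrent convolutional network classifier.

The backbone is the recurrent convolutional layer (RCL): a convolutional
layer whose state at step t adds a recurrent convolution of its own
previous state to a fixed feed-forward convolution of the layer input,

    z_t = conv_ff(x) + conv_rec(state_{t-1}) + bias,
    state_t = lrn(relu(z_t)),        state_0 from the feed-forward term only,

unrolled for T steps (default T = 3, so the longest computational path has
length T + 1).  The full stack is four RCL blocks with 2x2 max pooling
after the second and fourth, a 512-unit fully connected layer with ReLU and
dropout 0.5, and a softmax over two classes (tumor vs. normal).

Training is momentum SGD with a geometric learning-rate decay from 2e-3
down to 3e-6 over the epochs and a linear momentum ramp from 0.5 to 0.9.
Everything is plain numpy with analytic gradients (finite-difference
checked in the tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import (Dense, Dropout, Flatten, Layer, LRNConfig, MaxPool2,
                  RCLBlock, ReLULayer, conv2d_forward, cross_entropy_grad,
                  lrn_backward, lrn_forward, softmax)

__all__ = [
    "LRNConfig", "RCLParams", "NetworkSpec", "TrainConfig", "Network",
    "rcl_step", "relu", "lrn", "rcl_unroll", "build_network", "train",
    "predict_image", "CRNNClassifier",
]


@dataclass
class RCLParams:
    """Weights of one recurrent convolutional layer."""

    feedforward_weights: np.ndarray  # (F, C, k, k)
    recurrent_weights: np.ndarray  # (F, F, k, k)
    bias: np.ndarray  # (F,)
    unroll_steps: int = 3

    def validate(self) -> None:
        F, _, k, k2 = self.feedforward_weights.shape
        Fr, Fr2, kr, kr2 = self.recurrent_weights.shape
        if k != k2 or kr != kr2 or kr != k:
            raise ValueError("feedforward and recurrent kernels must share size")
        if Fr != F or Fr2 != F or self.bias.shape != (F,):
            raise ValueError("inconsistent filter counts in RCL parameters")
        if self.unroll_steps < 0:
            raise ValueError("unroll_steps must be >= 0")


def _batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError("expected (C, H, W) or (B, C, H, W) feature maps")


def rcl_step(input_maps: np.ndarray, prev_state: np.ndarray | None,
             params: RCLParams) -> np.ndarray:
    """One RCL pre-activation: conv_ff(input) [+ conv_rec(prev_state)] + bias.

    ``prev_state=None`` is the t = 0 case where only the feed-forward path
    exists.
    """
    params.validate()
    x, squeeze = _batched(input_maps)
    out, _ = conv2d_forward(x, params.feedforward_weights, params.bias)
    if prev_state is not None:
        s, _ = _batched(prev_state)
        if s.shape != out.shape:
            raise ValueError("previous state shape does not match output shape")
        rec, _ = conv2d_forward(s, params.recurrent_weights)
        out = out + rec
    return out[0] if squeeze else out


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0)."""
    return np.maximum(np.asarray(x), 0)


def lrn(x: np.ndarray, cfg: LRNConfig | None = None) -> np.ndarray:
    """Local response normalization across feature maps."""
    cfg = cfg or LRNConfig()
    cfg.validate()
    xb, squeeze = _batched(x)
    y, _ = lrn_forward(xb, cfg)
    return y[0] if squeeze else y


def rcl_unroll(input_maps: np.ndarray, params: RCLParams,
               cfg: LRNConfig | None = None) -> np.ndarray:
    """Unroll state_t = lrn(relu(rcl_step(input, state_{t-1}))) for
    t = 0..unroll_steps, re-injecting the feed-forward input every step."""
    cfg = cfg or LRNConfig()
    state = None
    for _ in range(params.unroll_steps + 1):
        state = lrn(relu(rcl_step(input_maps, state, params)), cfg)
    return state


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    The reference stack is a 64x64x3 input into four 256-filter 3x3
    recurrent conv blocks with 2x2 max pooling after blocks 2 and 4, then
    dense 512 + ReLU + dropout 0.5 and a 2-way softmax.  ``compact`` is a
    CPU-sized variant with the same topology used for the phantom
    benchmark.
    """

    input_size: int = 64
    in_channels: int = 3
    num_filters: int = 256
    kernel_size: int = 3
    num_rcl: int = 4
    unroll_steps: int = 3
    pool_after: tuple[int, ...] = (2, 4)
    hidden_units: int = 512
    num_classes: int = 2
    dropout: float = 0.5
    lrn: LRNConfig = field(default_factory=LRNConfig)

    @classmethod
    def table_default(cls) -> "NetworkSpec":
        return cls()

    @classmethod
    def compact(cls, input_size: int = 32) -> "NetworkSpec":
        return cls(input_size=input_size, num_filters=8, hidden_units=64)

    def validate(self) -> None:
        size = self.input_size
        for _ in self.pool_after:
            if size % 2:
                raise ValueError("spatial size becomes odd before a pool layer")
            size //= 2
        if size < 1:
            raise ValueError("too many pooling layers for the input size")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")

    def flat_units(self) -> int:
        return self.num_filters * (self.input_size // 2 ** len(self.pool_after)) ** 2


class Network:
    """An initialized stack of layers with softmax cross-entropy training
    hooks and a single-file checkpoint format."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.seed = seed
        self.dtype = dtype
        self.trained = False
        rng = np.random.default_rng(seed)
        layers: list[Layer] = []
        cin = spec.in_channels
        for i in range(1, spec.num_rcl + 1):
            layers.append(RCLBlock(cin, spec.num_filters, spec.kernel_size,
                                   spec.unroll_steps, spec.lrn, rng, dtype))
            cin = spec.num_filters
            if i in spec.pool_after:
                layers.append(MaxPool2())
        layers.append(Flatten())
        layers.append(Dense(spec.flat_units(), spec.hidden_units, rng, dtype))
        layers.append(ReLULayer())
        layers.append(Dropout(spec.dropout))
        layers.append(Dense(spec.hidden_units, spec.num_classes, rng, dtype))
        self.layers = layers

    def set_dropout_seed(self, seed: int) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    # -- checkpoint format: one .npz with a JSON header and flat weights --
    def save(self, path) -> None:
        header = json.dumps({
            "spec": {**asdict(self.spec), "lrn": asdict(self.spec.lrn)},
            "seed": self.seed,
            "trained": self.trained,
        })
        arrays = {f"param_{i}": p for i, p in enumerate(self.params())}
        np.savez(path, header=np.array(header), **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["header"]))
            spec_d = dict(meta["spec"])
            spec_d["lrn"] = LRNConfig(**spec_d["lrn"])
            spec_d["pool_after"] = tuple(spec_d["pool_after"])
            net = cls(NetworkSpec(**spec_d), seed=meta["seed"])
            for i, p in enumerate(net.params()):
                p[...] = data[f"param_{i}"]
            net.trained = meta["trained"]
        return net


def build_network(spec: NetworkSpec | None = None,
                  lrn_cfg: LRNConfig | None = None, seed: int = 0,
                  dtype=np.float32) -> Network:
    """Reproducibly initialize a network from a spec (scaled-variance
    uniform weights drawn from ``seed``)."""
    spec = spec or NetworkSpec()
    if lrn_cfg is not None:
        spec = NetworkSpec(**{**asdict(spec), "lrn": lrn_cfg})
    return Network(spec, seed=seed, dtype=dtype)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule: geometric lr decay, linear momentum ramp."""

    initial_lr: float = 0.002
    final_lr: float = 3e-6
    initial_momentum: float = 0.5
    final_momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.final_lr <= self.initial_lr) and self.initial_lr != 0:
            raise ValueError("need 0 < final_lr <= initial_lr")
        for m in (self.initial_momentum, self.final_momentum):
            if not (0 <= m < 1):
                raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    def lr_at(self, epoch: int) -> float:
        if self.epochs == 1 or self.initial_lr == 0:
            return self.initial_lr
        frac = epoch / (self.epochs - 1)
        return float(self.initial_lr * (self.final_lr / self.initial_lr) ** frac)

    def momentum_at(self, epoch: int) -> float:
        if self.epochs == 1:
            return self.initial_momentum
        frac = epoch / (self.epochs - 1)
        return float(self.initial_momentum
                     + (self.final_momentum - self.initial_momentum) * frac)


def adapt_images(images: np.ndarray, in_channels: int,
                 dtype=np.float32) -> np.ndarray:
    """Accept (B,H,W), (B,H,W,C) or (B,C,H,W); replicate grayscale across
    the expected channel count; return (B,C,H,W)."""
    x = np.asarray(images, dtype=dtype)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = np.repeat(x[:, None], in_channels, axis=1)
    elif x.ndim == 4:
        if x.shape[1] != in_channels and x.shape[3] == in_channels:
            x = x.transpose(0, 3, 1, 2)
        elif x.shape[1] == 1 and in_channels > 1:
            x = np.repeat(x, in_channels, axis=1)
        if x.shape[1] != in_channels:
            raise ValueError(f"cannot adapt channels {x.shape} -> {in_channels}")
    else:
        raise ValueError(f"unsupported image batch shape {x.shape}")
    return x


def train(network: Network, images: np.ndarray, labels: np.ndarray,
          cfg: TrainConfig | None = None) -> list[dict]:
    """Momentum-SGD training; returns the per-epoch history
    (epoch, lr, momentum, loss, accuracy)."""
    cfg = cfg or TrainConfig()
    cfg.validate()
    y = np.asarray(labels)
    if y.ndim != 1:
        raise ValueError("labels must be a 1D array")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    x = adapt_images(images, network.spec.in_channels, network.dtype)
    if x.shape[0] != y.shape[0]:
        raise ValueError("image/label count mismatch")

    rng = np.random.default_rng(cfg.seed)
    network.set_dropout_seed(cfg.seed + 1)
    params = network.params()
    velocity = [np.zeros_like(p) for p in params]
    n = x.shape[0]
    history = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        mom = cfg.momentum_at(epoch)
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = network.forward(xb, train=True)
            loss, dlogits = cross_entropy_grad(logits, yb)
            network.backward(dlogits.astype(network.dtype))
            for p, g, v in zip(params, network.grads(), velocity):
                v *= mom
                v -= lr * g
                p += v
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.append({
            "epoch": epoch, "lr": lr, "momentum": mom,
            "loss": sum(losses) / n, "accuracy": correct / n,
        })
    network.trained = True
    network.history = history
    return history


def predict_image(network: Network, img: np.ndarray) -> tuple[str, np.ndarray, dict]:
    """Classify a single grayscale image.

    Returns (label, class probabilities, metadata).  Exact probability ties
    resolve to "normal"; an untrained network is flagged in the metadata
    rather than raising.
    """
    x = adapt_images(np.asarray(img)[None] if np.asarray(img).ndim == 2
                     else np.asarray(img), network.spec.in_channels,
                     network.dtype)
    probs = network.predict_proba(x)[0]
    label = "tumor" if probs[1] > probs[0] else "normal"
    return label, probs, {"trained": network.trained}


class CRNNClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style wrapper around the recurrent convolutional network.

    Parameters mirror :class:`NetworkSpec` and :class:`TrainConfig`; ``X``
    is a stack of images (n, H, W) in [0, 1] (grayscale is replicated to
    the network's input channels) and ``y`` holds two class labels.

    Attributes
    ----------
    classes_ : ndarray of the sorted unique labels
    network_ : the trained :class:`Network`
    history_ : list of per-epoch dicts (epoch, lr, momentum, loss, accuracy)
    """

    def __init__(self, spec: NetworkSpec | None = None, epochs: int = 30,
                 batch_size: int = 32, initial_lr: float = 0.002,
                 final_lr: float = 3e-6, initial_momentum: float = 0.5,
                 final_momentum: float = 0.9, random_state: int = 0):
        self.spec = spec
        self.epochs = epochs
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.final_lr = final_lr
        self.initial_momentum = initial_momentum
        self.final_momentum = final_momentum
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(initial_lr=self.initial_lr, final_lr=self.final_lr,
                           initial_momentum=self.initial_momentum,
                           final_momentum=self.final_momentum,
                           epochs=self.epochs, batch_size=self.batch_size,
                           seed=self.random_state)

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("CRNNClassifier is a two-class model")
        if self.spec is not None:
            spec = self.spec
        else:
            # spatial size: (n,H,W) -> shape[1]; (n,C,H,W)/(n,H,W,C) -> shape[2]
            size = int(X.shape[1] if X.ndim == 3 else X.shape[2])
            spec = NetworkSpec.compact(input_size=size)
        self.network_ = build_network(spec, seed=self.random_state)
        self.history_ = train(self.network_, X, y_idx, self._train_config())
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X):
        x = adapt_images(np.asarray(X), self.network_.spec.in_channels,
                         self.network_.dtype)
        return self.network_.predict_proba(x)

    def predict(self, X):
        proba = self.predict_proba(X)
        # argmax takes the first (alphabetically smaller) class on exact ties
        return self.classes_[proba.argmax(axis=1)]
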