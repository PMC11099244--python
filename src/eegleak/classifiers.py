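"""Classifiers and training loops for the leakage experiments.

Three model kinds share one training interface:

* ``cnn1d_raw`` — a 1D CNN over raw (samples, channels) EEG segments: four
  convolution blocks (convolution -> ReLU -> max-pool -> batch norm), then
  dense layers of 20 and 10 units and a 2-unit output;
* ``cnn2d_image`` — a 2D CNN over spectrogram RGB images: four convolution
  blocks, dense layers of 256 and 512 units with dropout, 2-unit output;
* ``surrogate_bandpower`` — log band power per channel fed to a logistic
  model trained by minibatch SGD.  This is the first-class experiment
  classifier: it runs the full audit in minutes on one CPU and shows the
  same leakage direction as the CNNs.

The CNNs are implemented directly on numpy (im2col convolutions, manual
backpropagation, Adam/RMSProp) so the full architecture is runnable and
gradient-checkable without a deep-learning runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler

from .preprocessing import SegmentSet
from .synthetic_cohort import BAND_RANGES

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "FoldResult",
    "build_model",
    "train_and_evaluate",
    "band_power_features",
    "SurrogateBandPower",
    "NumpyCNN",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Architecture description.

    Convolution hyperparameters default to values consistent with the block
    structure of the reproduced architectures; they live here so alternative
    widths can be substituted without code changes.
    """

    kind: str  # cnn1d_raw | cnn2d_image | surrogate_bandpower
    input_shape: tuple = ()
    conv_filters: tuple = ()
    kernel: int = 0
    pool: int = 2
    dense: tuple = ()
    dropout: float = 0.0

    @staticmethod
    def cnn1d_raw(input_shape=(500, 19)) -> "ModelSpec":
        return ModelSpec(
            kind="cnn1d_raw",
            input_shape=tuple(input_shape),
            conv_filters=(16, 32, 64, 128),
            kernel=5,
            pool=2,
            dense=(20, 10),
        )

    @staticmethod
    def cnn2d_image(input_shape=(224, 224, 3)) -> "ModelSpec":
        return ModelSpec(
            kind="cnn2d_image",
            input_shape=tuple(input_shape),
            conv_filters=(32, 64, 128, 256),
            kernel=3,
            pool=2,
            dense=(256, 512),
            dropout=0.5,
        )

    @staticmethod
    def surrogate(fs: float = 250.0) -> "ModelSpec":
        return ModelSpec(kind="surrogate_bandpower", input_shape=(float(fs),))


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: fixed epochs, no early stopping, no model selection."""

    epochs: int = 70
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: str = "adam"  # adam | rmsprop
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FoldResult:
    """Per-epoch accuracy trajectories and final test accuracy for one fold."""

    fold_id: int
    train_acc: list[float]
    test_acc: list[float]
    final_test_acc: float
    n_test: int


# ---------------------------------------------------------------------------
# band-power features (shared by the surrogate and diagnostics)
# ---------------------------------------------------------------------------

def band_power_features(X: np.ndarray, fs: float) -> np.ndarray:
    """Log band power per channel per canonical band, via the periodogram.

    ``X`` is (n, samples, channels); returns (n, channels * n_bands).
    """
    n, m, _ = X.shape
    spec = np.fft.rfft(X, axis=1)
    # one-sided periodogram normalised so that summing over bins gives
    # the signal variance (power), Parseval-style
    psd = (np.abs(spec) ** 2) / (m * m)
    psd[:, 1:-1, :] *= 2.0
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    feats = []
    for lo, hi in BAND_RANGES.values():
        mask = (freqs >= lo) & (freqs < hi)
        feats.append(psd[:, mask, :].sum(axis=1))
    power = np.stack(feats, axis=2)  # (n, channels, bands)
    return np.log(power + 1e-12).reshape(n, -1)


def _cached_band_features(segments: SegmentSet, fs: float) -> np.ndarray:
    """Band-power features of a whole SegmentSet, memoized on the instance.

    Features are per-segment and deterministic, so they are safely shared
    across folds and schemes; all train/test separation happens at the
    index level (the scaler and classifier only ever see training rows).
    """
    cache = getattr(segments, "_band_feature_cache", None)
    if cache is None:
        cache = {}
        segments._band_feature_cache = cache
    key = float(fs)
    if key not in cache:
        cache[key] = band_power_features(segments.X, fs)
    return cache[key]


class SurrogateBandPower:
    """Logistic model on standardized log band powers, trained by minibatch SGD.

    The scaler and the classifier are fit on training folds only.  The
    minibatch loop records online (batch-averaged) training accuracy per
    epoch, mirroring the CNN training protocol; the weight updates are plain
    numpy (L2-regularised log-loss gradients through Adam or RMSProp), which
    keeps a 20-fold audit in the tens of seconds on one CPU.

    Note: sensible surrogate learning rates are ~0.1 (standardized features,
    convex loss), much larger than the CNN protocol defaults.
    """

    _ALPHA = 1e-4  # L2 penalty

    def __init__(self, spec: ModelSpec):
        self.fs = spec.input_shape[0] if spec.input_shape else 250.0
        self.scaler: StandardScaler | None = None
        self.w: np.ndarray | None = None
        self.b: float = 0.0

    # -- training interface -------------------------------------------------
    def init_fit(self, segments: SegmentSet, train_idx, config: TrainConfig) -> None:
        config.validate()
        feats = _cached_band_features(segments, self.fs)[np.asarray(train_idx)]
        self.scaler = StandardScaler().fit(feats)
        self._Xtr = self.scaler.transform(feats)
        self._segments = segments
        self._ytr = np.asarray(segments.y)[np.asarray(train_idx)].astype(int)
        self._rng = np.random.default_rng(config.seed)
        self._batch = config.batch_size
        d = self._Xtr.shape[1]
        self.w = np.zeros(d)
        self.b = 0.0
        self._lr = config.learning_rate
        self._opt = config.optimizer
        self._mw = np.zeros(d)
        self._vw = np.zeros(d)
        self._mb = self._vb = 0.0
        self._t = 0

    def _step(self, gw: np.ndarray, gb: float) -> None:
        lr = self._lr
        if self._opt == "adam":
            b1, b2, eps = 0.9, 0.999, 1e-8
            self._t += 1
            self._mw = b1 * self._mw + (1 - b1) * gw
            self._vw = b2 * self._vw + (1 - b2) * gw * gw
            self._mb = b1 * self._mb + (1 - b1) * gb
            self._vb = b2 * self._vb + (1 - b2) * gb * gb
            c1, c2 = 1 - b1**self._t, 1 - b2**self._t
            self.w -= lr * (self._mw / c1) / (np.sqrt(self._vw / c2) + eps)
            self.b -= lr * (self._mb / c1) / (np.sqrt(self._vb / c2) + eps)
        else:  # rmsprop
            rho, eps = 0.9, 1e-8
            self._vw = rho * self._vw + (1 - rho) * gw * gw
            self._vb = rho * self._vb + (1 - rho) * gb * gb
            self.w -= lr * gw / (np.sqrt(self._vw) + eps)
            self.b -= lr * gb / (np.sqrt(self._vb) + eps)

    def train_epoch(self) -> float:
        order = self._rng.permutation(len(self._ytr))
        accs = []
        for start in range(0, len(order), self._batch):
            idx = order[start : start + self._batch]
            xb, yb = self._Xtr[idx], self._ytr[idx]
            z = xb @ self.w + self.b
            accs.append(float(np.mean((z > 0).astype(int) == yb)))
            p = 1.0 / (1.0 + np.exp(-z))
            resid = p - yb
            gw = xb.T @ resid / len(yb) + self._ALPHA * self.w
            gb = float(resid.mean())
            self._step(gw, gb)
        return float(np.mean(accs))

    def _predict_feats(self, feats: np.ndarray) -> np.ndarray:
        return (feats @ self.w + self.b > 0).astype(int)

    def score(self, segments: SegmentSet, idx) -> float:
        idx = np.asarray(idx)
        feats = self.scaler.transform(
            _cached_band_features(segments, self.fs)[idx]
        )
        y = np.asarray(segments.y)[idx]
        return float(np.mean(self._predict_feats(feats) == y))

    def predict_segments(self, segments: SegmentSet, idx) -> np.ndarray:
        feats = self.scaler.transform(
            _cached_band_features(segments, self.fs)[np.asarray(idx)]
        )
        return self._predict_feats(feats)

    @property
    def n_parameters(self) -> int:
        return int(self.w.size + 1)


# ---------------------------------------------------------------------------
# numpy CNN building blocks
# ---------------------------------------------------------------------------

class _Layer:
    params: list  # list of [array, grad] pairs

    def __init__(self):
        self.params = []

    def forward(self, x, training):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1D(_Layer):
    """Valid-mode 1D convolution over (batch, length, channels)."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.standard_normal((kernel, c_in, c_out)) * scale
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x, training):
        k = self.kernel
        self._x = x
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        # win: (B, Lout, C, k) -> contract with W (k, C, F)
        self._win = win
        out = np.einsum("blck,kcf->blf", win, self.W, optimize=True) + self.b
        return out

    def backward(self, grad):
        self.dW[...] = np.einsum("blck,blf->kcf", self._win, grad, optimize=True)
        self.db[...] = grad.sum(axis=(0, 1))
        B, L, C = self._x.shape
        dx = np.zeros_like(self._x)
        Lout = grad.shape[1]
        for j in range(self.kernel):
            # dcols[:, :, c, j] accumulates into dx[:, j:j+Lout, c]
            dx[:, j : j + Lout, :] += np.einsum(
                "blf,cf->blc", grad, self.W[j], optimize=True
            )
        return dx


class Conv2D(_Layer):
    """Valid-mode 2D convolution over (batch, H, W, channels)."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = rng.standard_normal((kernel, kernel, c_in, c_out)) * scale
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x, training):
        k = self.kernel
        self._x = x
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        self._win = win  # (B, Ho, Wo, C, k, k)
        out = np.einsum("bhwcij,ijcf->bhwf", win, self.W, optimize=True) + self.b
        return out

    def backward(self, grad):
        self.dW[...] = np.einsum(
            "bhwcij,bhwf->ijcf", self._win, grad, optimize=True
        )
        self.db[...] = grad.sum(axis=(0, 1, 2))
        dx = np.zeros_like(self._x)
        Ho, Wo = grad.shape[1], grad.shape[2]
        for i in range(self.kernel):
            for j in range(self.kernel):
                dx[:, i : i + Ho, j : j + Wo, :] += np.einsum(
                    "bhwf,cf->bhwc", grad, self.W[i, j], optimize=True
                )
        return dx


class ReLU(_Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(_Layer):
    def __init__(self, size=2):
        super().__init__()
        self.size = size

    def forward(self, x, training):
        B, L, C = x.shape
        Lp = (L // self.size) * self.size
        x = x[:, :Lp, :]
        self._shape = (B, L, C)
        blocks = x.reshape(B, Lp // self.size, self.size, C)
        self._arg = blocks.argmax(axis=2)
        return np.take_along_axis(blocks, self._arg[:, :, None, :], axis=2)[
            :, :, 0, :
        ]

    def backward(self, grad):
        B, L, C = self._shape
        Lp = (L // self.size) * self.size
        blocks = np.zeros((B, Lp // self.size, self.size, C))
        np.put_along_axis(blocks, self._arg[:, :, None, :], grad[:, :, None, :], 2)
        dx = np.zeros((B, L, C))
        dx[:, :Lp, :] = blocks.reshape(B, Lp, C)
        return dx


class MaxPool2D(_Layer):
    def __init__(self, size=2):
        super().__init__()
        self.size = size

    def forward(self, x, training):
        p = self.size
        B, H, W, C = x.shape
        Hp, Wp = (H // p) * p, (W // p) * p
        self._shape = (B, H, W, C)
        x = x[:, :Hp, :Wp, :]
        blocks = (
            x.reshape(B, Hp // p, p, Wp // p, p, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, Hp // p, Wp // p, p * p, C)
        )
        self._arg = blocks.argmax(axis=3)
        return np.take_along_axis(blocks, self._arg[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]

    def backward(self, grad):
        p = self.size
        B, H, W, C = self._shape
        Hp, Wp = (H // p) * p, (W // p) * p
        blocks = np.zeros((B, Hp // p, Wp // p, p * p, C))
        np.put_along_axis(
            blocks, self._arg[:, :, :, None, :], grad[:, :, :, None, :], 3
        )
        dx = np.zeros((B, H, W, C))
        dx[:, :Hp, :Wp, :] = (
            blocks.reshape(B, Hp // p, Wp // p, p, p, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, Hp, Wp, C)
        )
        return dx


class BatchNorm(_Layer):
    """Normalisation over batch and spatial axes, per feature channel."""

    def __init__(self, n_features, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros(n_features)
        self.dbeta = np.zeros(n_features)
        self.params = [[self.gamma, self.dgamma], [self.beta, self.dbeta]]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._training = training
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        if not self._training:
            # inference: mean/var are constants, no batch-statistic terms
            return dxhat / self._std
        return (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class Flatten(_Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(_Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.params, self.lr, self.b1, self.b2, self.eps = params, lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _RMSProp:
    def __init__(self, params, lr, rho=0.9, eps=1e-8):
        self.params, self.lr, self.rho, self.eps = params, lr, rho, eps
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for i, (p, g) in enumerate(self.params):
            self.v[i] = self.rho * self.v[i] + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(self.v[i]) + self.eps)


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class NumpyCNN:
    """Sequential CNN with manual backprop; two-class softmax output."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        layers: list[_Layer] = []
        if spec.kind == "cnn1d_raw":
            length, c = spec.input_shape
            for f in spec.conv_filters:
                layers += [
                    Conv1D(c, f, spec.kernel, rng),
                    ReLU(),
                    MaxPool1D(spec.pool),
                    BatchNorm(f),
                ]
                length = (length - spec.kernel + 1) // spec.pool
                if length < 1:
                    raise ValueError(
                        f"input of {spec.input_shape} too short for "
                        f"{len(spec.conv_filters)} conv blocks"
                    )
                c = f
            layers.append(Flatten())
            width = length * c
        elif spec.kind == "cnn2d_image":
            h, w, c = spec.input_shape
            for f in spec.conv_filters:
                layers += [
                    Conv2D(c, f, spec.kernel, rng),
                    ReLU(),
                    MaxPool2D(spec.pool),
                    BatchNorm(f),
                ]
                h = (h - spec.kernel + 1) // spec.pool
                w = (w - spec.kernel + 1) // spec.pool
                if min(h, w) < 1:
                    raise ValueError(
                        f"input of {spec.input_shape} too small for "
                        f"{len(spec.conv_filters)} conv blocks"
                    )
                c = f
            layers.append(Flatten())
            width = h * w * c
        else:
            raise ValueError(f"NumpyCNN cannot build kind {spec.kind!r}")
        for units in spec.dense:
            layers += [Dense(width, units, rng), ReLU()]
            width = units
        if spec.dropout > 0:
            layers.append(Dropout(spec.dropout, self._dropout_rng))
        layers.append(Dense(width, 2, rng))
        self.layers = layers

    # -- core ----------------------------------------------------------------
    def forward(self, x, training=False):
        x = np.asarray(x, dtype=float)
        if x.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape mismatch: expected {tuple(self.spec.input_shape)}, "
                f"got {x.shape[1:]}"
            )
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def train_batch(self, x, y, optimizer) -> tuple[float, float]:
        """One gradient step; returns (loss, batch accuracy)."""
        logits = self.forward(x, training=True)
        probs = _softmax(logits)
        n = len(y)
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
        acc = float(np.mean(logits.argmax(axis=1) == y))
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad /= n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        optimizer.step()
        return loss, acc

    def predict(self, x, batch_size=64) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch_size):
            out.append(self.forward(x[start : start + batch_size]).argmax(axis=1))
        return np.concatenate(out)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p, _ in layer.params)

    def parameters(self) -> list:
        return [p for layer in self.layers for p, _ in layer.params]

    # -- training interface (same as the surrogate) --------------------------
    def init_fit(self, segments, train_idx, config: TrainConfig) -> None:
        config.validate()
        train_idx = np.asarray(train_idx)
        self._Xtr = np.asarray(segments.X[train_idx], dtype=float)
        self._ytr = np.asarray(segments.y)[train_idx]
        self._rng = np.random.default_rng(config.seed)
        self._batch = config.batch_size
        params = [(p, g) for layer in self.layers for p, g in layer.params]
        if config.optimizer == "adam":
            self._opt = _Adam(params, config.learning_rate)
        else:
            self._opt = _RMSProp(params, config.learning_rate)

    def train_epoch(self) -> float:
        order = self._rng.permutation(len(self._ytr))
        accs = []
        for start in range(0, len(order), self._batch):
            idx = order[start : start + self._batch]
            _, acc = self.train_batch(self._Xtr[idx], self._ytr[idx], self._opt)
            accs.append(acc)
        return float(np.mean(accs))

    def score(self, segments, idx) -> float:
        idx = np.asarray(idx)
        preds = self.predict(np.asarray(segments.X[idx], dtype=float))
        return float(np.mean(preds == np.asarray(segments.y)[idx]))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int = 0):
    """Instantiate a trainable model from its spec."""
    if spec.kind == "surrogate_bandpower":
        return SurrogateBandPower(spec)
    return NumpyCNN(spec, seed=seed)


def train_and_evaluate(
    model,
    segments: SegmentSet,
    plan_fold: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    fold_id: int = 0,
) -> FoldResult:
    """Train on the fold's train indices; record accuracies every epoch.

    Test data is only ever passed to ``score`` — it cannot influence the
    fit.  Per-epoch test accuracy is monitoring only and is never used for
    stopping or selection.
    """
    config.validate()
    train_idx, test_idx = np.asarray(plan_fold[0]), np.asarray(plan_fold[1])
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("empty train or test set")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    if train_idx.max() >= segments.n_segments or test_idx.max() >= segments.n_segments:
        raise IndexError("fold indices exceed the segment count")

    model.init_fit(segments, train_idx, config)
    train_curve, test_curve = [], []
    for _ in range(config.epochs):
        train_curve.append(model.train_epoch())
        test_curve.append(model.score(segments, test_idx))
    return FoldResult(
        fold_id=fold_id,
        train_acc=train_curve,
        test_acc=test_curve,
        final_test_acc=test_curve[-1],
        n_test=len(test_idx),
    )
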