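"""Benign/malignant classification of nodule ROIs.

Two classifiers share one contract (a malignancy score in [0, 1]; label
MALIGNANT iff score >= threshold, default 0.5):

* a small convolutional network, implemented here in NumPy: stacks of
  conv(3x3, same padding) -> ReLU -> max-pool(2) followed by a dense ReLU
  layer and a 2-way softmax, trained with Adam on cross-entropy.  Its
  default input is the 32x32 LBP code map of an ROI patch (scaled to
  [0, 1]); a ``histogram`` input mode feeds a raw LBP histogram through the
  dense head instead (no conv blocks).
* an RBF-kernel SVM baseline (scikit-learn) on LBP histograms, the
  comparison classifier for PSO/GA pipelines.

All weight initialization, shuffling and training is driven by a single
seed, so identical data + seed reproduce identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CNNConfig",
    "SVMConfig",
    "Prediction",
    "CNNClassifier",
    "SVMBaseline",
    "build_cnn",
    "train_classifier",
    "train_svm_baseline",
    "predict",
    "format_prediction",
    "MALIGNANT",
    "BENIGN",
]

MALIGNANT = "MALIGNANT"
BENIGN = "BENIGN"


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training settings for the small CNN.

    ``conv_blocks`` lists (filters, kernel, pool) triples; each block is
    conv -> ReLU -> max-pool.  The default (two blocks, 8 and 16 filters,
    3x3 kernels, pool 2) is the smallest net that separates phantom nodule
    textures reliably on a CPU in seconds.
    """

    input_mode: str = "code_map"  # or "histogram"
    input_size: int = 32  # side of the code-map input
    input_dim: int = 256  # length of the histogram input
    conv_blocks: tuple[tuple[int, int, int], ...] = ((8, 3, 2), (16, 3, 2))
    dense_units: int = 32
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.input_mode not in ("code_map", "histogram"):
            raise ValueError("input_mode must be 'code_map' or 'histogram'")
        if self.input_mode == "code_map" and not self.conv_blocks:
            raise ValueError("code_map mode needs at least one conv block")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        side = self.input_size
        for _, kernel, pool in self.conv_blocks:
            if kernel % 2 == 0:
                raise ValueError("kernels must be odd (same padding)")
            if side % pool != 0:
                raise ValueError(
                    f"input size {self.input_size} incompatible with pooling"
                )
            side //= pool


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM baseline settings."""

    C: float = 10.0
    gamma: str | float = "scale"
    decision_threshold: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class Prediction:
    """Two-class decision with the malignancy probability behind it."""

    label: str
    score: float


def format_prediction(pred: Prediction) -> str:
    """The classifier's verdict line, e.g. ``Tumor is MALIGNANT``."""
    return f"Tumor is {pred.label}"


# ---------------------------------------------------------------- layers


class _Conv:
    """3x3-style convolution, stride 1, zero 'same' padding, via im2col."""

    def __init__(self, in_ch, out_ch, kernel, rng):
        fan_in = in_ch * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in))
        self.b = np.zeros(out_ch)
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch

    def _cols(self, x):
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(
            x.shape[0], x.shape[2] * x.shape[3], -1
        )

    def forward(self, x):
        self._x_shape = x.shape
        self._cols_cache = self._cols(x)
        out = self._cols_cache @ self.W.T + self.b  # N, HW, F
        n, _, h, w = x.shape
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, h, w)

    def backward(self, grad):
        n, _, h, w = self._x_shape
        g = grad.reshape(n, self.out_ch, h * w).transpose(0, 2, 1)  # N,HW,F
        cols = self._cols_cache
        self.dW = np.einsum("nif,nij->fj", g, cols) / n
        self.db = g.sum(axis=(0, 1)) / n
        dcols = g @ self.W  # N, HW, C*k*k
        k = self.kernel
        p = k // 2
        dxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p))
        dcols = dcols.reshape(n, h, w, self.in_ch, k, k)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[
                    :, :, :, :, di, dj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class _MaxPool:
    def __init__(self, pool):
        self.pool = pool

    def forward(self, x):
        p = self.pool
        n, c, h, w = x.shape
        self._x = x
        xr = x.reshape(n, c, h // p, p, w // p, p)
        out = xr.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, grad):
        p = self.pool
        n, c, h, w = self._x.shape
        up = np.repeat(np.repeat(self._out, p, axis=2), p, axis=3)
        mask = self._x == up
        # ties split the gradient evenly within the window (deterministic)
        counts = (
            mask.reshape(n, c, h // p, p, w // p, p)
            .sum(axis=(3, 5), keepdims=True)
            .reshape(n, c, h // p, 1, w // p, 1)
        )
        gup = np.repeat(np.repeat(grad, p, axis=2), p, axis=3)
        cnt = np.repeat(np.repeat(counts.reshape(n, c, h // p, w // p), p, axis=2), p, axis=3)
        return gup * mask / cnt

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad / len(grad)
        self.db = grad.mean(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for li, layer in enumerate(layers):
            for name, p, _ in layer.params():
                self.m[(li, name)] = np.zeros_like(p)
                self.v[(li, name)] = np.zeros_like(p)

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, p, gname in layer.params():
                g = getattr(layer, gname)
                key = (li, name)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
                mhat = self.m[key] / (1 - self.beta1**self.t)
                vhat = self.v[key] / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ------------------------------------------------------------ classifier


@dataclass
class TrainingReport:
    """Per-epoch loss trace plus final training accuracy."""

    epoch_loss: list[float] = field(default_factory=list)
    final_train_accuracy: float = 0.0
    epochs: int = 0
    n_train: int = 0


class NotTrainedError(RuntimeError):
    """Prediction requested from an untrained model."""


class CNNClassifier:
    """Small seeded CNN (or dense net in ``histogram`` mode)."""

    def __init__(self, config: CNNConfig | None = None):
        self.config = config or CNNConfig()
        self.trained = False
        self._build()

    def _build(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        layers: list = []
        if cfg.input_mode == "code_map":
            side = cfg.input_size
            in_ch = 1
            for filters, kernel, pool in cfg.conv_blocks:
                layers.append(_Conv(in_ch, filters, kernel, rng))
                layers.append(_ReLU())
                layers.append(_MaxPool(pool))
                in_ch = filters
                side //= pool
            layers.append(_Flatten())
            flat = in_ch * side * side
        else:
            layers.append(_Flatten())
            flat = cfg.input_dim
        layers.append(_Dense(flat, cfg.dense_units, rng))
        layers.append(_ReLU())
        layers.append(_Dense(cfg.dense_units, 2, rng))
        self.layers = layers
        self._rng = rng

    def parameter_count(self) -> int:
        return sum(p.size for l in self.layers for _, p, _ in l.params())

    def parameter_hash(self) -> int:
        """Order-stable hash of all weights (identity check for seeding)."""
        import hashlib

        h = hashlib.sha256()
        for layer in self.layers:
            for _, p, _ in layer.params():
                h.update(np.ascontiguousarray(p).tobytes())
        return int.from_bytes(h.digest()[:8], "big")

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.config.input_mode == "code_map":
            if X.ndim == 2:
                X = X[None]
            if X.ndim == 3:
                X = X[:, None]
            if X.max() > 1.5:  # raw LBP codes -> [0, 1]
                X = X / 255.0
        else:
            if X.ndim == 1:
                X = X[None]
            X = X[:, None] if X.ndim == 2 else X
        return X

    def forward(self, X: np.ndarray) -> np.ndarray:
        out = self._prepare(X)
        for layer in self.layers:
            out = layer.forward(out)
        return _softmax(out)

    def fit(self, X: np.ndarray, y: np.ndarray) -> TrainingReport:
        cfg = self.config
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        Xp = self._prepare(X)
        n = len(Xp)
        opt = _Adam(self.layers, cfg.learning_rate)
        report = TrainingReport(epochs=cfg.epochs, n_train=n)
        rng = np.random.default_rng(cfg.seed + 1)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xp[idx], y[idx]
                out = xb
                for layer in self.layers:
                    out = layer.forward(out)
                probs = _softmax(out)
                eps = 1e-12
                losses.append(
                    float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + eps)))
                )
                grad = probs.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step()
            report.epoch_loss.append(float(np.mean(losses)))
        preds = self.forward(X)[:, 1] >= cfg.decision_threshold
        report.final_train_accuracy = float(np.mean(preds.astype(int) == y))
        self.trained = True
        return report

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise NotTrainedError("model has not been trained")
        return self.forward(X)

    def predict(self, X: np.ndarray) -> list[Prediction]:
        probs = self.predict_proba(X)[:, 1]
        thr = self.config.decision_threshold
        return [
            Prediction(MALIGNANT if s >= thr else BENIGN, float(s)) for s in probs
        ]

    # persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for li, layer in enumerate(self.layers):
            for name, p, _ in layer.params():
                arrays[f"{li}:{name}"] = p
        import json

        from dataclasses import asdict

        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        import json

        data = np.load(path)
        cfg_raw = json.loads(bytes(data["__config__"]).decode())
        cfg_raw["conv_blocks"] = tuple(tuple(b) for b in cfg_raw["conv_blocks"])
        model = cls(CNNConfig(**cfg_raw))
        for li, layer in enumerate(model.layers):
            for name, p, _ in layer.params():
                p[...] = data[f"{li}:{name}"]
        model.trained = True
        return model


class SVMBaseline:
    """RBF-SVM on LBP histograms with the shared predict contract."""

    def __init__(self, config: SVMConfig | None = None):
        from sklearn.svm import SVC

        self.config = config or SVMConfig()
        self._svc = SVC(
            C=self.config.C,
            gamma=self.config.gamma,
            kernel="rbf",
            random_state=self.config.seed,
        )
        self.trained = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMBaseline":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self._svc.fit(np.asarray(X, dtype=float), y)
        self.trained = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise NotTrainedError("model has not been trained")
        # logistic squash of the margin: monotone score in [0, 1]
        d = self._svc.decision_function(np.asarray(X, dtype=float))
        p1 = 1.0 / (1.0 + np.exp(-d))
        return np.column_stack([1 - p1, p1])

    def predict(self, X: np.ndarray) -> list[Prediction]:
        probs = self.predict_proba(X)[:, 1]
        thr = self.config.decision_threshold
        return [
            Prediction(MALIGNANT if s >= thr else BENIGN, float(s)) for s in probs
        ]


# ------------------------------------------------------- thin functional API


def build_cnn(config: CNNConfig | None = None) -> CNNClassifier:
    """Untrained CNN with seeded initial weights."""
    return CNNClassifier(config)


def train_classifier(model, X, y) -> TrainingReport | None:
    """Train either classifier on labeled features/patches."""
    return model.fit(X, y)


def train_svm_baseline(X, y, config: SVMConfig | None = None) -> SVMBaseline:
    """Fit the RBF-SVM comparison classifier."""
    return SVMBaseline(config).fit(X, y)


def predict(model, X) -> list[Prediction]:
    """Batch predictions (equal, element-wise, to one-at-a-time calls)."""
    return model.predict(X)
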