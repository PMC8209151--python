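"""Pair classification: a small 1-D CNN plus interchangeable baselines.

The primary classifier is a convolutional network over the 384-long fused
descriptor treated as a length-384, single-channel sequence:

    conv(32 filters, 3x1) -> conv(64 filters, 3x1) -> maxpool(2x1)
    -> flatten -> dense -> 2-way softmax

implemented in numpy with analytic gradients and Adam (no framework
dependency).  ``baseline_classifiers`` registers scikit-learn alternatives
(Bagging, LogisticRegression, NaiveBayes, AdaBoost, MLP) behind the same
fit/predict_proba contract so the evaluation harness can swap models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier

from ._autoencoder import Adam


@dataclass
class CnnConfig:
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel: int = 3
    pool: int = 2
    dense_units: int = 128
    dropout: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 60
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.conv1_filters <= 0 or self.conv2_filters <= 0:
            raise ValueError("filter counts must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class CnnClassifier:
    """1-D CNN over fixed-length descriptors with a 2-way probability head.

    Build with :func:`build_cnn`; train with :func:`fit`.  ``predict_proba``
    returns the positive-class probability per row (the full 2-way
    distribution is available from ``predict_proba_full``).
    """

    def __init__(self, input_len: int, cfg: CnnConfig):
        if input_len < 8:
            raise ValueError(f"input length {input_len} too short")
        self.cfg = cfg
        self.input_len = input_len
        k, pool = cfg.kernel, cfg.pool
        self.len1 = input_len - k + 1
        self.len2 = self.len1 - k + 1
        self.len_pool = self.len2 // pool
        if self.len_pool < 1:
            raise ValueError(
                f"input length {input_len} too short for the conv/pool chain"
            )
        rng = np.random.default_rng(cfg.seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(
                np.float32
            )

        f1, f2, du = cfg.conv1_filters, cfg.conv2_filters, cfg.dense_units
        flat = self.len_pool * f2
        self.W1 = he((k, f1), k)
        self.b1 = np.zeros(f1, dtype=np.float32)
        self.W2 = he((f1 * k, f2), f1 * k)
        self.b2 = np.zeros(f2, dtype=np.float32)
        # head layers start small so initial logits are near zero
        # (initial cross-entropy ~ ln 2) and early updates stay stable
        self.Wd = he((flat, du), flat) * 0.1
        self.bd = np.zeros(du, dtype=np.float32)
        self.Wo = he((du, 2), du) * 0.01
        self.bo = np.zeros(2, dtype=np.float32)
        self.history: list[float] = []
        self.fitted = False
        self._rng = rng
        # per-feature standardisation statistics, learned in fit()
        self._mu = np.zeros(input_len, dtype=np.float32)
        self._sd = np.ones(input_len, dtype=np.float32)

    # -- introspection ----------------------------------------------------

    def summary(self) -> list[str]:
        c = self.cfg
        return [
            f"input({self.input_len}x1)",
            f"conv({c.conv1_filters}, {c.kernel}x1) -> {self.len1}x{c.conv1_filters}",
            f"conv({c.conv2_filters}, {c.kernel}x1) -> {self.len2}x{c.conv2_filters}",
            f"maxpool({c.pool}x1) -> {self.len_pool}x{c.conv2_filters}",
            "flatten",
            f"dense({c.dense_units})",
            "softmax(2)",
        ]

    def n_parameters(self) -> int:
        return sum(
            p.size
            for p in (self.W1, self.b1, self.W2, self.b2,
                      self.Wd, self.bd, self.Wo, self.bo)
        )

    def _params(self):
        return [self.W1, self.b1, self.W2, self.b2,
                self.Wd, self.bd, self.Wo, self.bo]

    # -- forward/backward -------------------------------------------------

    def _forward(self, X: np.ndarray, drop_mask: np.ndarray | None = None):
        k, pool = self.cfg.kernel, self.cfg.pool
        cols1 = sliding_window_view(X, k, axis=1)            # (B, len1, k)
        Z1 = cols1 @ self.W1 + self.b1                       # (B, len1, f1)
        A1 = np.maximum(Z1, 0.0)
        cols2 = sliding_window_view(A1, k, axis=1)           # (B, len2, f1, k)
        cols2f = cols2.reshape(X.shape[0], self.len2, -1)    # (B, len2, f1*k)
        Z2 = cols2f @ self.W2 + self.b2                      # (B, len2, f2)
        A2 = np.maximum(Z2, 0.0)
        trim = self.len_pool * pool
        blocks = A2[:, :trim].reshape(X.shape[0], self.len_pool, pool, -1)
        arg = blocks.argmax(axis=2)                          # (B, len_pool, f2)
        P = blocks.max(axis=2)
        F = P.reshape(X.shape[0], -1)
        Zd = F @ self.Wd + self.bd
        Ad = np.maximum(Zd, 0.0)
        Ad_used = Ad if drop_mask is None else Ad * drop_mask
        Zo = Ad_used @ self.Wo + self.bo
        probs = _softmax(Zo)
        cache = (cols1, Z1, A1, cols2f, Z2, blocks, arg, F, Zd, Ad_used)
        return probs, cache

    def _backward(self, X, y_onehot, probs, cache, drop_mask):
        k, pool = self.cfg.kernel, self.cfg.pool
        B = X.shape[0]
        cols1, Z1, A1, cols2f, Z2, blocks, arg, F, Zd, Ad_used = cache
        dZo = (probs - y_onehot) / B
        gWo = Ad_used.T @ dZo
        gbo = dZo.sum(axis=0)
        dAd = dZo @ self.Wo.T
        if drop_mask is not None:
            dAd = dAd * drop_mask
        dZd = dAd * (Zd > 0)
        gWd = F.T @ dZd
        gbd = dZd.sum(axis=0)
        dF = dZd @ self.Wd.T
        dP = dF.reshape(B, self.len_pool, -1)
        # unpool: route gradient to the argmax position of each window
        dblocks = np.zeros_like(blocks)
        np.put_along_axis(dblocks, arg[:, :, None, :], dP[:, :, None, :], axis=2)
        dA2 = np.zeros((B, self.len2, blocks.shape[3]), dtype=blocks.dtype)
        trim = self.len_pool * pool
        dA2[:, :trim] = dblocks.reshape(B, trim, -1)
        dZ2 = dA2 * (Z2 > 0)
        gW2 = cols2f.reshape(-1, cols2f.shape[2]).T @ dZ2.reshape(-1, dZ2.shape[2])
        gb2 = dZ2.sum(axis=(0, 1))
        dcols2 = (dZ2 @ self.W2.T).reshape(B, self.len2, -1, k)
        dA1 = np.zeros_like(A1)
        for t in range(k):
            dA1[:, t : t + self.len2] += dcols2[:, :, :, t]
        dZ1 = dA1 * (Z1 > 0)
        gW1 = cols1.reshape(-1, k).T @ dZ1.reshape(-1, dZ1.shape[2])
        gb1 = dZ1.sum(axis=(0, 1))
        return [gW1, gb1, gW2, gb2, gWd, gbd, gWo, gbo]

    # -- public API -------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CnnClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(
                f"expected rows of length {self.input_len}, got {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError("non-finite inputs")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present in training data")
        cfg = self.cfg
        # standardise features on training statistics (applied in predict too)
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0) + np.float32(1e-8)
        X = (X - self._mu) / self._sd
        onehot = np.eye(2, dtype=np.float32)[y]
        n = X.shape[0]
        bs = min(cfg.batch_size, n)
        opt = Adam(lr=cfg.learning_rate)
        self.history = []
        for epoch in range(cfg.epochs):
            # step decay: x0.3 at 60% and 85% of the epoch budget
            frac = epoch / max(cfg.epochs, 1)
            opt.lr = cfg.learning_rate * (
                1.0 if frac < 0.6 else 0.3 if frac < 0.85 else 0.09
            )
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                Xb, yb = X[idx], onehot[idx]
                if cfg.dropout > 0:
                    mask = (
                        (
                            self._rng.random((len(idx), cfg.dense_units))
                            >= cfg.dropout
                        )
                        / (1.0 - cfg.dropout)
                    ).astype(np.float32)
                else:
                    mask = None
                probs, cache = self._forward(Xb, mask)
                eps = 1e-12
                epoch_loss += -float(
                    np.sum(yb * np.log(probs + eps))
                )
                grads = self._backward(Xb, yb, probs, cache, mask)
                opt.step(self._params(), grads)
            self.history.append(epoch_loss / n)
        self.fitted = True
        return self

    def predict_proba_full(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) class-probability matrix; rows sum to 1."""
        if not self.fitted and self.cfg.epochs > 0:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(
                f"expected rows of length {self.input_len}, got {X.shape}"
            )
        X = (X - self._mu) / self._sd
        probs, _ = self._forward(X, None)
        return probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability per row, in [0, 1]."""
        return self.predict_proba_full(X)[:, 1]


def build_cnn(input_len: int = 384, cfg: CnnConfig | None = None) -> CnnClassifier:
    """Construct the untrained CNN for descriptors of ``input_len``."""
    return CnnClassifier(input_len, cfg or CnnConfig())


def fit(model: CnnClassifier, X: np.ndarray, y: np.ndarray) -> CnnClassifier:
    """Train ``model`` in place and return it (history in ``model.history``)."""
    return model.fit(X, y)


def predict_proba(clf: CnnClassifier, X: np.ndarray) -> np.ndarray:
    return clf.predict_proba(X)


class SklearnBinary:
    """Adapter giving scikit-learn estimators the harness contract."""

    def __init__(self, estimator):
        self.estimator = estimator
        self.fitted = False

    def fit(self, X, y):
        self.estimator.fit(X, y)
        self.fitted = True
        return self

    def predict_proba(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]


def baseline_classifiers(seed: int = 0) -> dict[str, Callable[[], SklearnBinary]]:
    """Factories for the five comparison classifiers, same contract as CNN."""
    return {
        "bagging": lambda: SklearnBinary(
            BaggingClassifier(n_estimators=50, random_state=seed)
        ),
        "logreg": lambda: SklearnBinary(
            LogisticRegression(max_iter=2000, random_state=seed)
        ),
        "nb": lambda: SklearnBinary(GaussianNB()),
        "adaboost": lambda: SklearnBinary(
            AdaBoostClassifier(n_estimators=100, random_state=seed)
        ),
        "mlp": lambda: SklearnBinary(
            MLPClassifier(
                hidden_layer_sizes=(64,), max_iter=500, random_state=seed
            )
        ),
    }


def make_classifier(
    name: str,
    input_len: int,
    seed: int = 0,
    cnn_cfg: CnnConfig | None = None,
):
    """Instantiate a classifier by registry name ('cnn' or a baseline)."""
    if name == "cnn":
        cfg = cnn_cfg or CnnConfig()
        cfg = CnnConfig(**{**cfg.__dict__, "seed": seed})
        return build_cnn(input_len, cfg)
    registry = baseline_classifiers(seed)
    if name not in registry:
        raise KeyError(
            f"unknown classifier {name!r}; known: cnn, {', '.join(registry)}"
        )
    return registry[name]()
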