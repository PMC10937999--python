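"""Small, fully deterministic neural-network classifiers in numpy.

Implements the two neural families used for pixel-level spectral
classification — a fully-connected net and a 1-D convolutional net — as
sklearn-compatible classifiers trained with minibatch Adam on softmax
cross-entropy. Everything (weight init, batch order) derives from the
``random_state`` seed, so a rerun on the same data is bit-reproducible.

The 1D-CNN default is three strided convolution blocks (kernel 7, stride 2,
channel widths 8/16/32) with ReLU, global average pooling and a dense output
layer: a receptive field wide enough to span a full absorption band at the
default axis spacing while staying cheap enough to train on a single CPU.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["FCNNClassifier", "CNN1DClassifier"]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][:] = self._x.T @ dy
        self.grads[1][:] = dy.sum(axis=0)
        return dy @ self.W.T


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class _Conv1D:
    """Valid-mode strided 1-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        fan_in = c_in * kernel
        self.W = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.kernel, self.stride, self.c_in = kernel, stride, c_in
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_len(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def forward(self, x):  # x: (N, C, L)
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        cols = win[:, :, ::s]                      # (N, C, L_out, k)
        cols = cols.transpose(0, 2, 1, 3)          # (N, L_out, C, k)
        n, l_out = cols.shape[:2]
        self._cols = cols.reshape(n, l_out, -1)    # (N, L_out, C*k)
        self._in_shape = x.shape
        out = self._cols @ self.W.T + self.b       # (N, L_out, C_out)
        return out.transpose(0, 2, 1)              # (N, C_out, L_out)

    def backward(self, dy):  # dy: (N, C_out, L_out)
        k, s = self.kernel, self.stride
        n, _, l_out = dy.shape
        dyt = dy.transpose(0, 2, 1)                # (N, L_out, C_out)
        self.grads[0][:] = dyt.reshape(-1, dy.shape[1]).T @ self._cols.reshape(
            n * l_out, -1
        )
        self.grads[1][:] = dyt.sum(axis=(0, 1))
        dcols = (dyt @ self.W).reshape(n, l_out, self.c_in, k)
        dx = np.zeros(self._in_shape)
        for j in range(k):
            dx[:, :, j:j + s * l_out:s] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx


class _GlobalAvgPool:
    params: list = []
    grads: list = []

    def forward(self, x):  # (N, C, L) -> (N, C)
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._l, axis=2) / self._l


class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.params = [p for lay in layers for p in lay.params]
        self.grads = [g for lay in layers for g in lay.grads]
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

class _NumpyNetClassifier(ClassifierMixin, BaseEstimator):
    """Shared minibatch-Adam training loop; subclasses define the layers."""

    def __init__(self, epochs=25, batch_size=128, learning_rate=1e-3,
                 random_state=0, class_weight="balanced"):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.class_weight = class_weight

    def _build(self, n_features: int, n_classes: int,
               rng: np.random.Generator) -> list:
        raise NotImplementedError

    def _forward(self, layers, X):
        h = X
        for lay in layers:
            h = lay.forward(h)
        return h

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes in y")
        rng = np.random.default_rng(self.random_state)
        # z-score features for optimizer conditioning
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Xs = (X - self._mu) / self._sd
        n, d = Xs.shape
        k = self.classes_.size
        self._layers = self._build(d, k, rng)
        opt = _Adam(self._layers, lr=self.learning_rate)
        onehot = np.eye(k)[y_idx]
        if self.class_weight == "balanced":
            counts = np.bincount(y_idx, minlength=k)
            cw = n / (k * counts.astype(float))
        else:
            cw = np.ones(k)
        w = cw[y_idx]
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            total = 0.0
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                logits = self._forward(self._layers, Xs[idx])
                p = _softmax(logits)
                eps = 1e-12
                wb = w[idx]
                total += (-np.log(p[np.arange(idx.size), y_idx[idx]] + eps)
                          * wb).sum()
                dlogits = (p - onehot[idx]) * wb[:, None] / wb.sum()
                grad = dlogits
                for lay in reversed(self._layers):
                    grad = lay.backward(grad)
                opt.step()
            self.loss_curve_.append(total / n)
        self.n_features_in_ = d
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_layers")
        Xs = (np.asarray(X, dtype=float) - self._mu) / self._sd
        # predict in chunks to bound conv im2col memory
        out = []
        for s in range(0, Xs.shape[0], 4096):
            out.append(_softmax(self._forward(self._layers, Xs[s:s + 4096])))
        return np.vstack(out)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class FCNNClassifier(_NumpyNetClassifier):
    """Fully-connected feedforward net: Dense(128)-ReLU-Dense(32)-ReLU-out."""

    def __init__(self, hidden=(128, 32), epochs=25, batch_size=128,
                 learning_rate=1e-3, random_state=0):
        super().__init__(epochs, batch_size, learning_rate, random_state)
        self.hidden = hidden

    def _build(self, n_features, n_classes, rng):
        layers = []
        d = n_features
        for h in self.hidden:
            layers += [_Dense(d, h, rng), _ReLU()]
            d = h
        layers.append(_Dense(d, n_classes, rng))
        return layers


class _Reshape1C:
    """(N, L) -> (N, 1, L) adapter in front of the conv stack."""

    params: list = []
    grads: list = []

    def forward(self, x):
        return x[:, None, :]

    def backward(self, dy):
        return dy[:, 0, :]


class CNN1DClassifier(_NumpyNetClassifier):
    """1-D CNN over spectral features.

    Three strided conv blocks (kernel ``kernel``, stride ``stride``, channel
    widths ``channels``) with ReLU, global average pooling, dense output.
    """

    def __init__(self, channels=(8, 16, 32), kernel=7, stride=2,
                 epochs=25, batch_size=128, learning_rate=1e-3,
                 random_state=0):
        super().__init__(epochs, batch_size, learning_rate, random_state)
        self.channels = channels
        self.kernel = kernel
        self.stride = stride

    def _build(self, n_features, n_classes, rng):
        layers: list = [_Reshape1C()]
        c_in, length = 1, n_features
        for c_out in self.channels:
            conv = _Conv1D(c_in, c_out, self.kernel, self.stride, rng)
            if conv.out_len(length) < 1:
                raise ValueError(
                    f"feature length {n_features} too short for conv stack"
                )
            layers += [conv, _ReLU()]
            length = conv.out_len(length)
            c_in = c_out
        layers += [_GlobalAvgPool(), _Dense(c_in, n_classes, rng)]
        return layers
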