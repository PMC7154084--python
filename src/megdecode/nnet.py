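"""Minimal feed-forward neural-network engine (numpy).

Supports exactly what the decoders need: dense and 2-D convolutional layers,
sigmoid/ReLU activations, max pooling, softmax cross-entropy, SGD and Adam
with optional global-norm gradient clipping and per-layer learning-rate
multipliers, minibatch training with validation-patience early stopping and
best-validation snapshotting.  All randomness flows through a caller-supplied
``numpy.random.Generator``, so training is bit-reproducible.

Shapes: dense layers take (n, d); conv/pool layers take NHWC arrays.
"""

from __future__ import annotations

import copy

import numpy as np


class Layer:
    """Base layer: stateless unless it has ``params``/``grads`` lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]
    lr_mult: float = 1.0

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 lr_mult: float = 1.0) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.lr_mult = lr_mult

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        self.grads[0][...] = self._x.T @ gout
        self.grads[1][...] = gout.sum(axis=0)
        return gout @ self.W.T


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, gout):
        return gout * self._y * (1.0 - self._y)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """(n, H, W, C) -> (n, oh, ow, kh*kw*C) patch matrix (view-free copy)."""
    n, h, w, c = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, kh, kw, c),
        strides=(s0, s1 * stride, s2 * stride, s1, s2, s3), writeable=False)
    return windows.reshape(n, oh, ow, kh * kw * c), oh, ow


class Conv2D(Layer):
    """Valid-mode 2-D convolution over NHWC input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, lr_mult: float = 1.0) -> None:
        super().__init__()
        fan_in = kernel * kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(kernel, kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.kernel, self.stride = kernel, stride
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.lr_mult = lr_mult

    def forward(self, x):
        self._xshape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride)
        self._cols = cols
        Wm = self.W.reshape(-1, self.W.shape[-1])
        return cols @ Wm + self.b

    def backward(self, gout):
        n, h, w, c = self._xshape
        k, s = self.kernel, self.stride
        Wm = self.W.reshape(-1, self.W.shape[-1])
        cols = self._cols  # (n, oh, ow, k*k*c)
        self.grads[0][...] = np.einsum("nijp,nijq->pq", cols, gout).reshape(self.W.shape)
        self.grads[1][...] = gout.sum(axis=(0, 1, 2))
        gcols = gout @ Wm.T  # (n, oh, ow, k*k*c)
        gx = np.zeros((n, h, w, c))
        oh, ow = gout.shape[1], gout.shape[2]
        gcols = gcols.reshape(n, oh, ow, k, k, c)
        for i in range(oh):
            for j in range(ow):
                gx[:, i * s:i * s + k, j * s:j * s + k, :] += gcols[:, i, j]
        return gx


class MaxPool2D(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x):
        n, h, w, c = x.shape
        p = self.size
        hh, ww = h // p, w // p
        self._xshape = x.shape
        xr = x[:, :hh * p, :ww * p, :].reshape(n, hh, p, ww, p, c)
        self._xr = xr
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, gout):
        n, h, w, c = self._xshape
        p = self.size
        hh, ww = h // p, w // p
        g = self._mask * gout[:, :, None, :, None, :]
        # split ties evenly so gradients stay bounded
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        g = g / counts
        gx = np.zeros((n, h, w, c))
        gx[:, :hh * p, :ww * p, :] = g.reshape(n, hh * p, ww * p, c)
        return gx


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """A plain layer stack trained with softmax cross-entropy."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size])))
        return np.concatenate(out, axis=0)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on a batch; fills every layer's grads."""
        logits = self.forward(x)
        p = softmax(logits)
        n = x.shape[0]
        loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
        g = p.copy()
        g[np.arange(n), y] -= 1.0
        g /= n
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return float(loss)

    def loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        total, n = 0.0, len(x)
        for i in range(0, n, batch_size):
            p = softmax(self.forward(x[i:i + batch_size]))
            yy = y[i:i + batch_size]
            total += -np.sum(np.log(p[np.arange(len(yy)), yy] + 1e-12))
        return float(total / n)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = state[i]
                i += 1


class SGD:
    def __init__(self, lr: float = 0.01, clip_norm: float | None = None) -> None:
        self.lr, self.clip_norm = lr, clip_norm

    def step(self, net: Network) -> None:
        _clip(net, self.clip_norm)
        for layer in net.layers:
            for p, g in zip(layer.params, layer.grads):
                p -= self.lr * layer.lr_mult * g


class Adam:
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clip_norm: float | None = 1.0) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self._m: list[np.ndarray] | None = None
        self._t = 0

    def step(self, net: Network) -> None:
        _clip(net, self.clip_norm)
        grads = [(layer, g) for layer in net.layers for g in layer.grads]
        if self._m is None:
            self._m = [np.zeros_like(g) for _, g in grads]
            self._v = [np.zeros_like(g) for _, g in grads]
        self._t += 1
        params = [p for layer in net.layers for p in layer.params]
        mults = [layer.lr_mult for layer in net.layers for _ in layer.params]
        for i, ((layer, g), p, mult) in enumerate(zip(grads, params, mults)):
            self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
            self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g**2
            mhat = self._m[i] / (1 - self.beta1**self._t)
            vhat = self._v[i] / (1 - self.beta2**self._t)
            p -= self.lr * mult * mhat / (np.sqrt(vhat) + self.eps)


def _clip(net: Network, clip_norm: float | None) -> None:
    if clip_norm is None:
        return
    total = np.sqrt(sum(float(np.sum(g**2))
                        for layer in net.layers for g in layer.grads))
    if total > clip_norm and total > 0:
        scale = clip_norm / total
        for layer in net.layers:
            for g in layer.grads:
                g *= scale


def fit(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    optimizer,
    rng: np.random.Generator,
    batch_size: int = 32,
    max_epochs: int = 100,
    patience: int = 6,
    validate_every: int | None = None,
) -> dict:
    """Minibatch training with early stopping on validation loss.

    Validation runs once per epoch, or every ``validate_every`` optimizer
    steps when given; ``patience`` counts validation events since the best
    validation loss.  The best-validation parameter snapshot is restored
    before returning.  The returned history holds per-validation-event train
    loss, validation loss and validation accuracy.
    """
    y = np.asarray(y)
    history = {"train_loss": [], "val_loss": [], "val_acc": [], "epoch": []}
    best_loss = np.inf
    best_state = net.get_state()
    events_since_best = 0
    step = 0
    stop = False

    def validate(epoch: int, train_loss: float) -> None:
        nonlocal best_loss, best_state, events_since_best, stop
        vl = net.loss(X_val, y_val)
        acc = float(np.mean(net.predict_proba(X_val).argmax(axis=1) == y_val))
        history["train_loss"].append(train_loss)
        history["val_loss"].append(vl)
        history["val_acc"].append(acc)
        history["epoch"].append(epoch)
        if vl < best_loss - 1e-12:
            best_loss = vl
            best_state = net.get_state()
            events_since_best = 0
        else:
            events_since_best += 1
            if events_since_best > patience:
                stop = True

    for epoch in range(max_epochs):
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(X), batch_size):
            idx = order[i:i + batch_size]
            losses.append(net.loss_and_backward(X[idx], y[idx]))
            optimizer.step(net)
            step += 1
            if validate_every is not None and step % validate_every == 0:
                validate(epoch, float(np.mean(losses)))
                if stop:
                    break
        if stop:
            break
        if validate_every is None:
            validate(epoch, float(np.mean(losses)))
            if stop:
                break
    net.set_state(best_state)
    history["best_val_loss"] = best_loss
    return history
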