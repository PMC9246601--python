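"""Compact deterministic numpy CNN backend.

Implements the layer vocabulary the searches emit — same-padding stride-1
convolution, batch normalization, inverted dropout, max/average pooling
(stride = pool size), flatten and dense — with full backpropagation and an
Adam optimizer.  Everything runs in float32; all randomness (weight
initialization, shuffling, dropout masks) flows from a single seed, so a
fit is bit-reproducible on a fixed BLAS.

Intended for small images (32–128 px) and small datasets, which is the
regime the architecture searches operate in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Network", "ShapeError", "build_layer", "FitHistory"]


class ShapeError(ValueError):
    """A layer cannot be applied to its input shape."""


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) with same-padding -> (N*H*W, k*k*C) patch matrix."""
    n, h, w, c = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    # stride tricks over the padded array
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, h, w, k, k, c),
        strides=(s[0], s[1], s[2], s[1], s[2], s[3]),
        writeable=False,
    )
    return windows.reshape(n * h * w, k * k * c)


def _col2im(cols: np.ndarray, x_shape: tuple[int, ...], k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, h, w, c = x_shape
    pad = k // 2
    xp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=np.float32)
    cols = cols.reshape(n, h, w, k, k, c)
    for i in range(k):
        for j in range(k):
            xp[:, i : i + h, j : j + w, :] += cols[:, :, :, i, j, :]
    return xp[:, pad : pad + h, pad : pad + w, :] if pad else xp


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params)


LEAKY_SLOPE = 0.1  # leaky-ReLU negative slope; avoids dead units in small nets


class Conv2D(_Layer):
    """Same-padding stride-1 convolution followed by leaky ReLU."""

    def __init__(self, rng, in_ch: int, filters: int, kernel: int, relu: bool = True):
        super().__init__()
        self.k, self.in_ch, self.filters, self.relu = kernel, in_ch, filters, relu
        w = _he_init(rng, (kernel * kernel * in_ch, filters), kernel * kernel * in_ch)
        b = np.zeros(filters, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k)
        out = self.cols @ self.params[0] + self.params[1]
        n, h, w, _ = x.shape
        out = out.reshape(n, h, w, self.filters)
        if self.relu:
            self.mask = np.where(out > 0, np.float32(1.0), np.float32(LEAKY_SLOPE))
            out = out * self.mask
        return out

    def backward(self, g):
        if self.relu:
            g = g * self.mask
        gf = g.reshape(-1, self.filters)
        self.grads[0][...] = self.cols.T @ gf
        self.grads[1][...] = gf.sum(axis=0)
        gcols = gf @ self.params[0].T
        return _col2im(gcols, self.x_shape, self.k)


class Dense(_Layer):
    def __init__(self, rng, in_dim: int, units: int, relu: bool = True):
        super().__init__()
        self.relu = relu
        w = _he_init(rng, (in_dim, units), in_dim)
        b = np.zeros(units, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train, rng):
        self.x = x
        out = x @ self.params[0] + self.params[1]
        if self.relu:
            self.mask = np.where(out > 0, np.float32(1.0), np.float32(LEAKY_SLOPE))
            out = out * self.mask
        return out

    def backward(self, g):
        if self.relu:
            g = g * self.mask
        self.grads[0][...] = self.x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.params[0].T


class BatchNorm(_Layer):
    """Per-channel (4-D input) or per-feature (2-D input) batch norm."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        gamma = np.ones(n_ch, dtype=np.float32)
        beta = np.zeros(n_ch, dtype=np.float32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.run_mean = np.zeros(n_ch, dtype=np.float32)
        self.run_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x, train, rng):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean) * self.inv_std
        self.axes = axes
        self.m = x.size // x.shape[-1]
        return self.params[0] * self.xhat + self.params[1]

    def backward(self, g):
        gamma = self.params[0]
        self.grads[0][...] = (g * self.xhat).sum(axis=self.axes)
        self.grads[1][...] = g.sum(axis=self.axes)
        # standard batch-norm input gradient
        gxhat = g * gamma
        return (
            self.inv_std
            / self.m
            * (
                self.m * gxhat
                - gxhat.sum(axis=self.axes)
                - self.xhat * (gxhat * self.xhat).sum(axis=self.axes)
            )
        )


class Dropout(_Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train:
            self.mask = None
            return x
        self.mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (
            1.0 - self.rate
        )
        return x * self.mask

    def backward(self, g):
        return g if self.mask is None else g * self.mask


class Pool(_Layer):
    """Max or average pooling, stride = pool size, floor division."""

    def __init__(self, size: int, mode: str):
        super().__init__()
        self.size, self.mode = size, mode

    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        p = self.size
        ho, wo = h // p, w // p
        self.x_shape = x.shape
        xv = x[:, : ho * p, : wo * p, :].reshape(n, ho, p, wo, p, c)
        if self.mode == "max":
            flat = xv.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, p * p)
            self.arg = flat.argmax(axis=-1)
            return flat.max(axis=-1)
        return xv.mean(axis=(2, 4))

    def backward(self, g):
        n, h, w, c = self.x_shape
        p = self.size
        ho, wo = h // p, w // p
        gx = np.zeros(self.x_shape, dtype=np.float32)
        if self.mode == "max":
            scat = np.zeros((n, ho, wo, c, p * p), dtype=np.float32)
            np.put_along_axis(scat, self.arg[..., None], g[..., None], axis=-1)
            scat = scat.reshape(n, ho, wo, c, p, p).transpose(0, 1, 4, 2, 5, 3)
            gx[:, : ho * p, : wo * p, :] = scat.reshape(n, ho * p, wo * p, c)
        else:
            gx[:, : ho * p, : wo * p, :] = np.repeat(
                np.repeat(g, p, axis=1), p, axis=2
            ) / (p * p)
        return gx


class Flatten(_Layer):
    def forward(self, x, train, rng):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self.x_shape)


def build_layer(rng, kind: str, in_shape, **kw):
    """Construct one backend layer for ``kind`` given its input shape.

    Returns ``(layer, out_shape)``; raises :class:`ShapeError` when the
    layer cannot be applied (pooling underflow, dense on spatial input,
    spatial op on flat input).
    """
    spatial = len(in_shape) == 3
    if kind == "C2D":
        if not spatial:
            raise ShapeError("convolution requires a spatial input")
        h, w, c = in_shape
        layer = Conv2D(rng, c, kw["filter_count"], kw["kernel_size"])
        return layer, (h, w, kw["filter_count"])
    if kind in ("MP", "AP"):
        if not spatial:
            raise ShapeError("pooling requires a spatial input")
        h, w, c = in_shape
        p = kw["pool_size"]
        if h // p < 1 or w // p < 1:
            raise ShapeError(f"pooling size {p} underflows {h}x{w} input")
        return Pool(p, "max" if kind == "MP" else "avg"), (h // p, w // p, c)
    if kind == "BN":
        return BatchNorm(in_shape[-1]), in_shape
    if kind == "DO":
        return Dropout(kw["rate"]), in_shape
    if kind == "F":
        if not spatial:
            return Flatten(), in_shape  # no-op on already-flat input
        h, w, c = in_shape
        return Flatten(), (h * w * c,)
    if kind == "DE":
        if spatial:
            raise ShapeError("dense layer requires a flattened input")
        layer = Dense(rng, in_shape[0], kw["unit_count"], relu=kw.get("relu", True))
        return layer, (kw["unit_count"],)
    raise ValueError(f"unknown layer kind {kind!r}")


@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_early: bool = False
    diverged: bool = False


class Network:
    """A sequential classifier over backend layers with a softmax head."""

    def __init__(self, layers: list[_Layer], n_classes: int, seed: int = 0):
        self.layers = layers
        self.n_classes = n_classes
        self.rng = np.random.default_rng(seed)
        self._adam_m = [np.zeros_like(p) for l in layers for p in l.params]
        self._adam_v = [np.zeros_like(p) for l in layers for p in l.params]
        self._adam_t = 0

    # -- inference --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Return class logits."""
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, train, self.rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            probs.append(_softmax(logits))
        return np.concatenate(probs, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    # -- training ---------------------------------------------------------
    def _step(self, x, y, lr):
        logits = self.forward(x, train=True)
        p = _softmax(logits)
        n = len(x)
        loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
        g = p
        g[np.arange(n), y] -= 1.0
        g /= n
        for layer in reversed(self.layers):
            g = layer.backward(g)
        self._adam_t += 1
        t = self._adam_t
        i = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        for layer in self.layers:
            for p_, g_ in zip(layer.params, layer.grads):
                self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g_
                self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g_ * g_
                mhat = self._adam_m[i] / (1 - b1**t)
                vhat = self._adam_v[i] / (1 - b2**t)
                p_ -= lr * mhat / (np.sqrt(vhat) + eps)
                i += 1
        return float(loss)

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 1,
        batch_size: int = 32,
        lr: float = 1e-3,
        patience: int = 0,
        restore_best: bool = True,
    ) -> FitHistory:
        """Mini-batch Adam training with optional accuracy early stopping.

        ``patience`` > 0 stops after that many epochs without validation
        accuracy improvement (always training at least one epoch).  With
        ``restore_best`` (default) the weights of the best-validation
        epoch are restored at the end, guarding against late-epoch
        instability.
        """
        hist = FitHistory()
        best_acc, since_best = -1.0, 0
        best_state = None
        for _ in range(epochs):
            order = self.rng.permutation(len(x_train))
            losses = []
            for i in range(0, len(order), batch_size):
                idx = order[i : i + batch_size]
                loss = self._step(x_train[idx], y_train[idx], lr)
                if not np.isfinite(loss):
                    warnings.warn("training diverged (non-finite loss)")
                    hist.diverged = True
                    hist.train_loss.append(loss)
                    return hist
                losses.append(loss)
            hist.train_loss.append(float(np.mean(losses)))
            if x_val is not None:
                acc = float((self.predict(x_val) == y_val).mean())
                hist.val_accuracy.append(acc)
                if acc > best_acc:
                    best_acc, since_best = acc, 0
                    if restore_best:
                        best_state = self._snapshot()
                else:
                    since_best += 1
                    if patience > 0 and since_best >= patience:
                        hist.stopped_early = True
                        break
        if best_state is not None:
            self._restore(best_state)
        return hist

    def _snapshot(self):
        state = [[p.copy() for p in l.params] for l in self.layers]
        bn = [
            (l.run_mean.copy(), l.run_var.copy())
            for l in self.layers
            if isinstance(l, BatchNorm)
        ]
        return state, bn

    def _restore(self, state) -> None:
        params, bn = state
        for layer, saved in zip(self.layers, params):
            for p, s in zip(layer.params, saved):
                p[...] = s
        it = iter(bn)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                m, v = next(it)
                layer.run_mean, layer.run_var = m, v


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
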