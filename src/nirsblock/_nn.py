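"""Minimal NumPy neural-network engine for the fNIRS classifiers.

Implements exactly what the two architectures need - 3D convolution
(im2col + GEMM), per-row temporal 1D convolution with shared filters,
fully connected layers, inverted dropout, ReLU, softmax cross-entropy and
Adam - with bit-reproducible behaviour from a single Generator that
drives initialisation, batch shuffling and dropout masks.

Convolutions use "valid" padding.  Two single-core performance choices
matter here: the first convolution of a network skips its input gradient
(nothing below it to update), and all large per-batch intermediates
(im2col packs, GEMM outputs, transposes, Adam temporaries) live in
per-layer scratch buffers that are reused across steps - repeated fresh
allocations of ~100 MB arrays page-fault on first touch and otherwise
dominate the step time.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    def params(self):
        return []

    def _scratch(self, name, shape, dtype=DTYPE):
        store = self.__dict__.setdefault("_scratch_bufs", {})
        key = (name, shape)
        buf = store.get(key)
        if buf is None:
            buf = store[key] = np.empty(shape, dtype)
        return buf

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """Valid 3D convolution over [N, C, T, H, W] with per-input-channel kernels."""

    def __init__(self, in_channels, n_filters, kernel, rng, needs_input_grad=True):
        kt, kh, kw = kernel
        fan_in = in_channels * kt * kh * kw
        self.w = (rng.standard_normal((n_filters, in_channels, kt, kh, kw)) *
                  np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(n_filters, dtype=DTYPE)
        self.kernel = kernel
        self.needs_input_grad = needs_input_grad
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _im2col(self, x):
        N, C, T, H, W = x.shape
        kt, kh, kw = self.kernel
        To, Ho, Wo = T - kt + 1, H - kh + 1, W - kw + 1
        if min(To, Ho, Wo) < 1:
            raise ValueError(f"kernel {self.kernel} larger than input {(T, H, W)}")
        K = C * kt * kh * kw
        col = self._scratch("col", (K, N, To, Ho, Wo))
        i = 0
        for c in range(C):
            for a in range(kt):
                for b in range(kh):
                    for d in range(kw):
                        col[i] = x[:, c, a : a + To, b : b + Ho, d : d + Wo]
                        i += 1
        return col.reshape(K, -1), (N, To, Ho, Wo)

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._x_shape = x.shape
        colm, (N, To, Ho, Wo) = self._im2col(x)
        self._colm = colm if train else None
        F = self.w.shape[0]
        out = self._scratch("out", (F, colm.shape[1]))
        np.matmul(self.w.reshape(F, -1), colm, out=out)
        out += self.b[:, None]
        self._out_dims = (N, To, Ho, Wo)
        tr = self._scratch("tr", (N, F, To, Ho, Wo))
        tr[...] = out.reshape(F, N, To, Ho, Wo).transpose(1, 0, 2, 3, 4)
        return tr

    def backward(self, grad):
        N, To, Ho, Wo = self._out_dims
        F = self.w.shape[0]
        dm = self._scratch("dm", (F, N * To * Ho * Wo))
        dm.reshape(F, N, To, Ho, Wo)[...] = grad.transpose(1, 0, 2, 3, 4)
        np.matmul(dm, self._colm.T, out=self.dw.reshape(F, -1))
        dm.sum(axis=1, out=self.db)
        colm = self._colm
        self._colm = None
        if not self.needs_input_grad:
            return None
        _, C, T, H, W = self._x_shape
        kt, kh, kw = self.kernel
        dx = self._scratch("dx", self._x_shape)
        dx[...] = 0.0
        contrib = (self.w.reshape(F, -1).T @ dm).reshape(C, kt, kh, kw, N, To, Ho, Wo)
        for a in range(kt):
            for b in range(kh):
                for d in range(kw):
                    dx[:, :, a : a + To, b : b + Ho, d : d + Wo] += contrib[
                        :, a, b, d
                    ].transpose(1, 0, 2, 3, 4)
        return dx


class ConvTime1D(Layer):
    """Temporal convolution applied independently to every input row.

    Input [N, R, C, T]; the same (C x kt) filter bank is shared by all R
    rows, so features are extracted across time only and every measurement
    row is treated as an independent variable.
    """

    def __init__(self, in_channels, n_filters, kt, rng, needs_input_grad=True):
        fan_in = in_channels * kt
        self.w = (rng.standard_normal((n_filters, in_channels, kt)) *
                  np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(n_filters, dtype=DTYPE)
        self.kt = kt
        self.needs_input_grad = needs_input_grad
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _im2col(self, x):
        N, R, C, T = x.shape
        kt = self.kt
        To = T - kt + 1
        if To < 1:
            raise ValueError(f"temporal kernel {kt} larger than input length {T}")
        K = C * kt
        col = self._scratch("col", (K, N, R, To))
        i = 0
        for c in range(C):
            for a in range(kt):
                col[i] = x[:, :, c, a : a + To]
                i += 1
        return col.reshape(K, -1), (N, R, C, T, To)

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        colm, dims = self._im2col(x)
        self._colm = colm if train else None
        self._dims = dims
        N, R, C, T, To = dims
        F = self.w.shape[0]
        out = self._scratch("out", (F, colm.shape[1]))
        np.matmul(self.w.reshape(F, -1), colm, out=out)
        out += self.b[:, None]
        tr = self._scratch("tr", (N, R, F, To))
        tr[...] = out.reshape(F, N, R, To).transpose(1, 2, 0, 3)
        return tr

    def backward(self, grad):
        N, R, C, T, To = self._dims
        F = self.w.shape[0]
        dm = self._scratch("dm", (F, N * R * To))
        dm.reshape(F, N, R, To)[...] = grad.transpose(2, 0, 1, 3)
        np.matmul(dm, self._colm.T, out=self.dw.reshape(F, -1))
        dm.sum(axis=1, out=self.db)
        self._colm = None
        if not self.needs_input_grad:
            return None
        dx = self._scratch("dx", (N, R, C, T))
        dx[...] = 0.0
        contrib = (self.w.reshape(F, -1).T @ dm).reshape(C, self.kt, N, R, To)
        for a in range(self.kt):
            dx[:, :, :, a : a + To] += contrib[:, a].transpose(1, 2, 0, 3)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, scale=None):
        std = np.sqrt((2.0 if scale is None else scale) / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * std).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=False, rng=None):
        self._x = x if train else None
        out = self._scratch("out", (x.shape[0], self.w.shape[1]))
        np.matmul(x, self.w, out=out)
        out += self.b
        return out

    def backward(self, grad):
        np.matmul(self._x.T, grad, out=self.dw)
        grad.sum(axis=0, out=self.db)
        dx = self._scratch("dx", (grad.shape[0], self.w.shape[0]))
        np.matmul(grad, self.w.T, out=dx)
        self._x = None
        return dx


class ReLU(Layer):
    """In-place rectifier; safe because inputs are layer-owned scratch."""

    def forward(self, x, train=False, rng=None):
        if train:
            mask = self._scratch("mask", x.shape, bool)
            np.greater(x, 0, out=mask)
            self._mask = mask
        np.maximum(x, 0, out=x)
        return x

    def backward(self, grad):
        grad *= self._mask
        return grad


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        x *= self._mask
        return x

    def backward(self, grad):
        if self._mask is None:
            return grad
        grad *= self._mask
        return grad


class Network:
    """A plain layer stack ending in logits."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                break

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, y_idx):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y_idx)
    loss = float(-np.mean(np.log(np.clip(p[np.arange(n), y_idx], 1e-12, None))))
    grad = p
    grad[np.arange(n), y_idx] -= 1.0
    return loss, (grad / n).astype(DTYPE)


class Adam:
    """Adam with bias correction; all moment updates run in place."""

    def __init__(self, net: Network, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _ in net.params()]
        self._tmp = [np.empty_like(p) for p, _ in net.params()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        step_scale = DTYPE(self.lr * correction)
        for (p, g), m, v, tmp in zip(self.net.params(), self.m, self.v, self._tmp):
            m *= b1
            np.multiply(g, DTYPE(1 - b1), out=tmp)
            m += tmp
            v *= b2
            np.multiply(g, g, out=tmp)
            tmp *= DTYPE(1 - b2)
            v += tmp
            np.sqrt(v, out=tmp)
            tmp += DTYPE(self.eps)
            np.divide(m, tmp, out=tmp)
            tmp *= step_scale
            p -= tmp


def train_network(net, X, y_idx, *, n_epochs, batch_size, learning_rate, rng):
    """Mini-batch Adam on softmax cross-entropy; returns per-epoch mean loss."""
    n = len(X)
    if n == 0:
        raise ValueError("empty training set")
    opt = Adam(net, learning_rate)
    losses = []
    for epoch in range(n_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            logits = net.forward(X[idx], train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y_idx[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {n_batches} (lr={learning_rate})"
                )
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return losses
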