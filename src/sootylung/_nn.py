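"""Minimal CPU neural-network engine (float32, numpy, exact determinism).

Implements just the layers the CNN-GRU classifier needs: valid 3x3
convolution (im2col + BLAS matmul), 2x2 max pooling, inverted dropout,
dense layers, a gated-recurrent-unit layer with backpropagation through
time, and a fused softmax cross-entropy loss.  All randomness (weight
initialization, dropout masks, batch shuffling) flows through a single
seeded :class:`numpy.random.Generator`, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, L) patch matrix, L = (H-k+1)*(W-k+1)."""
    v = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, Ho, Wo, k, k)
    n, c, ho, wo = v.shape[:4]
    return np.ascontiguousarray(
        v.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    ), (ho, wo)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Valid-padding stride-1 square convolution."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        cols, (ho, wo) = _im2col(x, self.k)
        self._cols = cols if train else None
        out = np.matmul(self.W[None], cols) + self.b[None, :, None]
        return out.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, grad, need_dx: bool = True):
        n, _, ho, wo = grad.shape
        dflat = grad.reshape(n, self.c_out, ho * wo)
        self.grads[0][...] = np.tensordot(dflat, self._cols, axes=([0, 2], [0, 2]))
        self.grads[1][...] = dflat.sum(axis=(0, 2))
        self._cols = None
        if not need_dx:  # first layer: the input gradient is never consumed
            return None
        # dx = full correlation of grad with flipped kernels, via im2col again
        k = self.k
        pad = np.zeros((n, self.c_out, ho + 2 * (k - 1), wo + 2 * (k - 1)), dtype=DTYPE)
        pad[:, :, k - 1: k - 1 + ho, k - 1: k - 1 + wo] = grad
        cols_b, _ = _im2col(pad, k)
        w4 = self.W.reshape(self.c_out, self.c_in, k, k)
        wf = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, self.c_out * k * k)
        dx = np.matmul(wf[None], cols_b)
        h, w = self._x_shape[2], self._x_shape[3]
        return dx.reshape(n, self.c_in, h, w)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (floor on odd sizes)."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        win = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._idx = np.argmax(win, axis=4)
        self._in_shape = (n, c, h, w)
        return np.take_along_axis(win, self._idx[..., None], axis=4)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, c, h2, w2, 4), dtype=grad.dtype)
        np.put_along_axis(dwin, self._idx[..., None], grad[..., None], axis=4)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        dx = grad @ self.W.T
        self._x = None
        return dx


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRU(Layer):
    """Single GRU layer over (N, T, F) sequences; outputs the last hidden state.

    Gates: reset r = sigmoid(x Wxr + h Whr + br), update z likewise;
    candidate c = tanh(x Wxn + (r * h) Whn + bn); h' = (1 - z) c + z h.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.hidden = n_in, hidden
        s_x, s_h = np.sqrt(1.0 / n_in), np.sqrt(1.0 / hidden)
        self.Wx = rng.normal(0.0, s_x, (n_in, 3 * hidden)).astype(DTYPE)   # [r|z|n]
        self.Wh = rng.normal(0.0, s_h, (hidden, 3 * hidden)).astype(DTYPE)
        self.b = np.zeros(3 * hidden, dtype=DTYPE)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False, rng=None):
        n, t, _ = x.shape
        hdim = self.hidden
        h = np.zeros((n, hdim), dtype=DTYPE)
        self._cache = [] if train else None
        for step in range(t):
            xt = x[:, step, :]
            pre = xt @ self.Wx + self.b
            pre_rz = pre[:, : 2 * hdim] + h @ self.Wh[:, : 2 * hdim]
            r = _sigmoid(pre_rz[:, :hdim])
            z = _sigmoid(pre_rz[:, hdim:])
            hr = r * h
            c = np.tanh(pre[:, 2 * hdim:] + hr @ self.Wh[:, 2 * hdim:])
            h_new = (1.0 - z) * c + z * h
            if train:
                self._cache.append((xt, h, r, z, hr, c))
            h = h_new
        self._t = t
        return h

    def backward(self, grad):
        hdim = self.hidden
        dWx, dWh, db = (np.zeros_like(g) for g in self.params)
        dh = grad.astype(DTYPE)
        dx_steps = []
        for step in range(self._t - 1, -1, -1):
            xt, h_prev, r, z, hr, c = self._cache[step]
            dc = dh * (1.0 - z)
            dz = dh * (h_prev - c)
            dh_prev = dh * z
            dpre_n = dc * (1.0 - c * c)
            dWx[:, 2 * hdim:] += xt.T @ dpre_n
            dWh[:, 2 * hdim:] += hr.T @ dpre_n
            db[2 * hdim:] += dpre_n.sum(axis=0)
            dhr = dpre_n @ self.Wh[:, 2 * hdim:].T
            dh_prev += dhr * r
            dr = dhr * h_prev
            dpre_z = dz * z * (1.0 - z)
            dpre_r = dr * r * (1.0 - r)
            dWx[:, :hdim] += xt.T @ dpre_r
            dWx[:, hdim: 2 * hdim] += xt.T @ dpre_z
            dWh[:, :hdim] += h_prev.T @ dpre_r
            dWh[:, hdim: 2 * hdim] += h_prev.T @ dpre_z
            db[:hdim] += dpre_r.sum(axis=0)
            db[hdim: 2 * hdim] += dpre_z.sum(axis=0)
            dh_prev += dpre_r @ self.Wh[:, :hdim].T + dpre_z @ self.Wh[:, hdim: 2 * hdim].T
            dx_steps.append(
                dpre_r @ self.Wx[:, :hdim].T
                + dpre_z @ self.Wx[:, hdim: 2 * hdim].T
                + dpre_n @ self.Wx[:, 2 * hdim:].T
            )
            dh = dh_prev
        self.grads[0][...], self.grads[1][...], self.grads[2][...] = dWx, dWh, db
        self._cache = None
        return np.stack(dx_steps[::-1], axis=1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits for integer labels."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(DTYPE)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad, input_grad: bool = False):
        for i, layer in enumerate(reversed(self.layers)):
            is_first = i == len(self.layers) - 1
            if is_first and not input_grad and isinstance(layer, Conv2D):
                return layer.backward(grad, need_dx=False)
            grad = layer.backward(grad)
        return grad

    def sgd_step(self, lr: float, clip_norm: float | None = None):
        if clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                                for layer in self.layers for g in layer.grads))
            if total > clip_norm:
                scale = DTYPE(clip_norm / total)
                for layer in self.layers:
                    for g in layer.grads:
                        g *= scale
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                p -= DTYPE(lr) * g

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))
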