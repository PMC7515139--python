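"""Minimal neural-network core: dense, 2-D convolution, plain-RNN and LSTM
layers with hand-written backpropagation, softmax cross-entropy, and Adam.

Everything runs in float64 numpy for exact determinism given a seed.  The
scope is deliberately small — exactly the three sequence-classifier
architectures the package trains — and every layer's gradient is covered
by finite-difference tests.

Conventions: batches first; recurrent layers take a boolean mask whose
True prefix marks real timesteps and carry hidden state through padded
steps, so the hidden state at the final index always equals the state at
the last real step.
"""

from __future__ import annotations

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(n), y_idx] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    return loss, dlogits / n


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        s = np.sqrt(2.0 / (d_in + d_out))
        self.W = rng.normal(0.0, s, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class Conv3x3:
    """3x3 'same' convolution, stride 1, on (n, C, H, W) input."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        s = np.sqrt(2.0 / (c_in * 9 + c_out))
        self.W = rng.normal(0.0, s, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.empty((n, c, 9, h * w))
        for k in range(9):
            di, dj = divmod(k, 3)
            cols[:, :, k, :] = xp[:, :, di:di + h, dj:dj + w].reshape(n, c, h * w)
        self._cols, self._shape = cols, (n, c, h, w)
        Wr = self.W.reshape(self.W.shape[0], c, 9)
        y = np.einsum("ock,nckm->nom", Wr, cols) + self.b[None, :, None]
        return y.reshape(n, -1, h, w)

    def backward(self, dy):
        n, c, h, w = self._shape
        dyf = dy.reshape(n, -1, h * w)
        Wr = self.W.reshape(self.W.shape[0], c, 9)
        self.grads[0][...] = np.einsum("nom,nckm->ock", dyf, self._cols).reshape(self.W.shape)
        self.grads[1][...] = dyf.sum(axis=(0, 2))
        dcols = np.einsum("ock,nom->nckm", Wr, dyf)
        dxp = np.zeros((n, c, h + 2, w + 2))
        for k in range(9):
            di, dj = divmod(k, 3)
            dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, k, :].reshape(n, c, h, w)
        return dxp[:, :, 1:-1, 1:-1]


class MaxPool2x2:
    """2x2 max pooling, stride 2; an axis shorter than 2 is left alone and
    odd trailing rows/columns are dropped."""

    params: list = []
    grads: list = []

    def forward(self, x):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        ph = 2 if h >= 2 else 1
        pw = 2 if w >= 2 else 1
        self._ph, self._pw = ph, pw
        h2, w2 = h // ph, w // pw
        xc = x[:, :, :h2 * ph, :w2 * pw]
        xr = xc.reshape(n, c, h2, ph, w2, pw)
        y = xr.max(axis=(3, 5))
        self._x_crop = xc
        self._y = y
        return y

    def backward(self, dy):
        n, c, h, w = self._in_shape
        ph, pw = self._ph, self._pw
        h2, w2 = dy.shape[2], dy.shape[3]
        up = np.repeat(np.repeat(dy, ph, axis=2), pw, axis=3)
        ymax = np.repeat(np.repeat(self._y, ph, axis=2), pw, axis=3)
        is_max = (self._x_crop == ymax)
        # share gradient among ties to keep backward a true derivative a.e.
        counts = is_max.reshape(n, c, h2, ph, w2, pw).sum(axis=(3, 5))
        counts = np.repeat(np.repeat(counts, ph, axis=2), pw, axis=3)
        dxc = up * is_max / counts
        dx = np.zeros(self._in_shape)
        dx[:, :, :h2 * ph, :w2 * pw] = dxc
        return dx


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class RNNLayer:
    """Plain tanh recurrence returning the full hidden sequence."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        s = np.sqrt(1.0 / max(d_in, 1))
        self.Wx = rng.normal(0.0, s, size=(d_in, d_h))
        self.Wh = rng.normal(0.0, np.sqrt(1.0 / d_h), size=(d_h, d_h))
        self.b = np.zeros(d_h)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, mask):
        n, T, _ = x.shape
        d_h = self.b.shape[0]
        H = np.zeros((n, T, d_h))
        raw = np.zeros((n, T, d_h))
        h = np.zeros((n, d_h))
        for t in range(T):
            a = np.tanh(x[:, t] @ self.Wx + h @ self.Wh + self.b)
            m = mask[:, t][:, None]
            raw[:, t] = a
            h = m * a + (1.0 - m) * h
            H[:, t] = h
        self._x, self._mask, self._H, self._raw = x, mask, H, raw
        return H

    def backward(self, dH):
        x, mask, H, raw = self._x, self._mask, self._H, self._raw
        n, T, _ = x.shape
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, self.b.shape[0]))
        for g in self.grads:
            g[...] = 0.0
        for t in range(T - 1, -1, -1):
            dh = dH[:, t] + dh_next
            m = mask[:, t][:, None]
            da = dh * m * (1.0 - raw[:, t] ** 2)
            h_prev = H[:, t - 1] if t > 0 else np.zeros_like(dh)
            self.grads[0] += x[:, t].T @ da
            self.grads[1] += h_prev.T @ da
            self.grads[2] += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh_next = dh * (1.0 - m) + da @ self.Wh.T
        return dx


class LSTMLayer:
    """LSTM with fused gate matrices, returning the full hidden sequence.

    Gate order in the fused dimension: input, forget, candidate, output.
    Forget-gate bias initialized to 1 (standard trick for gradient flow).
    """

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        s = np.sqrt(1.0 / max(d_in, 1))
        self.Wx = rng.normal(0.0, s, size=(d_in, 4 * d_h))
        self.Wh = rng.normal(0.0, np.sqrt(1.0 / d_h), size=(d_h, 4 * d_h))
        self.b = np.zeros(4 * d_h)
        self.b[d_h:2 * d_h] = 1.0
        self.d_h = d_h
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, mask):
        n, T, _ = x.shape
        d = self.d_h
        H = np.zeros((n, T, d))
        self._cache = []
        h = np.zeros((n, d))
        c = np.zeros((n, d))
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :d])
            f = _sigmoid(z[:, d:2 * d])
            g = np.tanh(z[:, 2 * d:3 * d])
            o = _sigmoid(z[:, 3 * d:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t][:, None]
            self._cache.append((h, c, i, f, g, o, c_new, tc, m))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
            H[:, t] = h
        self._x = x
        return H

    def backward(self, dH):
        x = self._x
        n, T, _ = x.shape
        d = self.d_h
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, d))
        dc_next = np.zeros((n, d))
        for g_ in self.grads:
            g_[...] = 0.0
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tc, m = self._cache[t]
            dh = dH[:, t] + dh_next
            # through the mask carry
            dh_new = dh * m
            dc_new = dc_next * m + dh_new * o * (1.0 - tc ** 2)
            do = dh_new * tc
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            self.grads[0] += x[:, t].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dh * (1.0 - m) + dz @ self.Wh.T
            dc_next = dc_next * (1.0 - m) + dc_new * f
        return dx


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale


class RecurrentNet:
    """Stacked recurrent layers -> final hidden state -> dense logits."""

    def __init__(self, d_in, hidden, n_classes, rng, cell="lstm"):
        Layer = LSTMLayer if cell == "lstm" else RNNLayer
        self.layers = []
        d = d_in
        for h in hidden:
            self.layers.append(Layer(d, h, rng))
            d = h
        self.head = Dense(d, n_classes, rng)

    @property
    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params)
        out.extend(self.head.params)
        return out

    @property
    def grads(self):
        out = []
        for l in self.layers:
            out.extend(l.grads)
        out.extend(self.head.grads)
        return out

    def forward(self, X, mask):
        h = X
        for l in self.layers:
            h = l.forward(h, mask)
        self._T = h.shape[1]
        return self.head.forward(h[:, -1, :])

    def backward(self, dlogits):
        dh_last = self.head.backward(dlogits)
        dH = np.zeros((dh_last.shape[0], self._T, dh_last.shape[1]))
        dH[:, -1, :] = dh_last
        for l in reversed(self.layers):
            dH = l.backward(dH)
        return dH


class ConvNet:
    """Conv(3x3)+ReLU+MaxPool blocks on the (keyframes x features) matrix
    as a one-channel image, then dense layers to logits.  Padded rows are
    consumed as zeros."""

    def __init__(self, input_shape, conv_channels, dense_units, n_classes, rng):
        T, F = input_shape
        self.blocks = []
        c = 1
        h, w = T, F
        for cc in conv_channels:
            conv = Conv3x3(c, cc, rng)
            pool = MaxPool2x2()
            self.blocks += [conv, ReLU(), pool]
            c = cc
            h = max(h // 2, 1) if h >= 2 else h
            w = max(w // 2, 1) if w >= 2 else w
        self.blocks.append(Flatten())
        d = c * h * w
        for du in dense_units:
            self.blocks += [Dense(d, du, rng), ReLU()]
            d = du
        self.blocks.append(Dense(d, n_classes, rng))

    @property
    def params(self):
        return [p for l in self.blocks for p in l.params]

    @property
    def grads(self):
        return [g for l in self.blocks for g in l.grads]

    def forward(self, X, mask=None):
        h = X[:, None, :, :]  # (n,1,T,F)
        for l in self.blocks:
            h = l.forward(h)
        return h

    def backward(self, dlogits):
        d = dlogits
        for l in reversed(self.blocks):
            d = l.backward(d)
        return d[:, 0, :, :]
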