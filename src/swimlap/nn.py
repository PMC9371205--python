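"""A small self-contained NumPy neural-network engine.

Implements exactly the pieces the swimming-activity classifier needs:
LSTM cells run bidirectionally (with input dropout and recurrent dropout),
dense layers, batch normalisation, inverted dropout, softmax with sparse
categorical cross-entropy, Adam, and Xavier (Glorot) uniform initialisation.
Backpropagation is hand-derived per layer and verified against finite
differences in the test suite.

Conventions follow the common deep-learning-framework semantics:

* LSTM gate order i, f, g, o; kernel shapes ``Wx (d, 4u)``, ``Wh (u, 4u)``,
  bias ``(4u,)`` with a unit forget-gate bias at initialisation; parameter
  count per direction is therefore ``4u(d + u + 1)``.
* Input dropout and recurrent dropout use one mask per sequence, shared
  across time steps; inverted scaling so inference needs no correction.
* Batch normalisation keeps moving averages (momentum 0.99) that are frozen
  at inference.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Dropout",
    "BatchNorm",
    "Flatten",
    "BiLSTM",
    "Sequential",
    "Adam",
    "softmax",
    "sparse_ce_loss_and_grad",
    "xavier_uniform",
]


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, int], dtype=np.float64) -> np.ndarray:
    fan_in, fan_out = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sparse_ce_loss_and_grad(logits: np.ndarray, targets: np.ndarray,
                            class_weights: np.ndarray | None = None):
    """Mean sparse categorical cross-entropy over the batch and its gradient
    with respect to the logits (softmax folded in)."""
    p = softmax(logits)
    n = logits.shape[0]
    idx = np.arange(n)
    logp = -np.log(np.clip(p[idx, targets], 1e-12, None))
    if class_weights is None:
        loss = logp.mean()
        grad = p.copy()
        grad[idx, targets] -= 1.0
        grad /= n
    else:
        w = class_weights[targets]
        loss = (w * logp).sum() / w.sum()
        grad = p * w[:, None]
        grad[idx, targets] -= w
        grad /= w.sum()
    return float(loss), grad


class Layer:
    """Base: subclasses fill ``params``/``grads`` (aligned lists of arrays)."""

    trainable = True

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x, train: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    def __init__(self, input_dim: int, units: int, activation: str = "linear",
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = xavier_uniform(rng, (input_dim, units), dtype)
        self.b = np.zeros(units, dtype=dtype)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z  # linear (softmax handled in the loss)

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    trainable = False

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class BatchNorm(Layer):
    """Feature-axis batch normalisation with frozen statistics at inference.

    ``n_params`` counts gamma, beta and the two moving-statistic vectors
    (4 per feature), matching how standard frameworks report the layer.
    """

    def __init__(self, dim: int, momentum: float = 0.99, eps: float = 1e-3, dtype=np.float64):
        super().__init__()
        self.gamma = np.ones(dim, dtype=dtype)
        self.beta = np.zeros(dim, dtype=dtype)
        self.moving_mean = np.zeros(dim, dtype=dtype)
        self.moving_var = np.ones(dim, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def n_params(self) -> int:
        return int(self.gamma.size * 4)

    def forward(self, x, train, rng):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.moving_mean[...] = self.momentum * self.moving_mean + (1 - self.momentum) * mu
            self.moving_var[...] = self.momentum * self.moving_var + (1 - self.momentum) * var
        else:
            mu, var = self.moving_mean, self.moving_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xc = x - mu
        self._xhat = self._xc * self._ivar
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        self.grads[0][...] = (dy * self._xhat).sum(axis=0)
        self.grads[1][...] = dy.sum(axis=0)
        dxhat = dy * self.gamma
        if not self._train:
            return dxhat * self._ivar
        n = dy.shape[0]
        dvar = (dxhat * self._xc).sum(axis=0) * (-0.5) * self._ivar ** 3
        dmu = -(dxhat.sum(axis=0)) * self._ivar + dvar * (-2.0 / n) * self._xc.sum(axis=0)
        return dxhat * self._ivar + dvar * (2.0 / n) * self._xc + dmu / n


class Flatten(Layer):
    """Collapse all trailing axes; identity on already-flat (B, F) input."""

    trainable = False

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _LSTMDirection:
    """One direction of an LSTM over a (batch, time, features) input."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 backwards: bool, dtype=np.float64, unit_forget_bias: bool = True):
        d, u = input_dim, units
        self.u = u
        self.backwards = backwards
        self.Wx = xavier_uniform(rng, (d, 4 * u), dtype)
        self.Wh = xavier_uniform(rng, (u, 4 * u), dtype)
        self.b = np.zeros(4 * u, dtype=dtype)
        if unit_forget_bias:
            self.b[u:2 * u] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def forward(self, x, in_mask, rec_mask):
        """x: (B, T, d) already in this direction's time order."""
        B, T, d = x.shape
        u = self.u
        xd = x if in_mask is None else x * in_mask[:, None, :]
        self._xd = xd
        xz = xd.reshape(B * T, d) @ self.Wx
        xz = xz.reshape(B, T, 4 * u) + self.b
        h = np.zeros((B, u), dtype=x.dtype)
        c = np.zeros((B, u), dtype=x.dtype)
        self._cache = []
        H = np.empty((B, T, u), dtype=x.dtype)
        self._rec_mask = rec_mask
        for t in range(T):
            hd = h if rec_mask is None else h * rec_mask
            z = xz[:, t] + hd @ self.Wh
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((hd, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            H[:, t] = h
        return H

    def backward(self, dH):
        """dH: (B, T, u) gradient w.r.t. this direction's outputs."""
        B, T, u = dH.shape
        xd = self._xd
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dXd = np.empty_like(xd)
        dh_next = np.zeros((B, u), dtype=dH.dtype)
        dc_next = np.zeros((B, u), dtype=dH.dtype)
        rec_mask = self._rec_mask
        dZ = np.empty((B, T, 4 * u), dtype=dH.dtype)
        for t in range(T - 1, -1, -1):
            hd, c_prev, i, f, g, o, c_new, tc = self._cache[t]
            dh = dH[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dZ[:, t] = dz
            self.dWh += hd.T @ dz
            dh_prev = dz @ self.Wh.T
            if rec_mask is not None:
                dh_prev = dh_prev * rec_mask
            dh_next = dh_prev
        d = xd.shape[2]
        flatZ = dZ.reshape(B * T, 4 * u)
        self.dWx[...] = xd.reshape(B * T, d).T @ flatZ
        self.db[...] = flatZ.sum(axis=0)
        dXd[...] = (flatZ @ self.Wx.T).reshape(B, T, d)
        return dXd


class BiLSTM(Layer):
    """Bidirectional LSTM; concatenates forward and backward features.

    ``return_sequences=True`` yields (B, T, 2u); otherwise (B, 2u) built
    from each direction's final state. Parameter count: 2 * 4u(d + u + 1).
    """

    def __init__(self, input_dim: int, units: int, return_sequences: bool,
                 dropout: float = 0.0, recurrent_dropout: float = 0.0,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fwd = _LSTMDirection(input_dim, units, rng, backwards=False, dtype=dtype)
        self.bwd = _LSTMDirection(input_dim, units, rng, backwards=True, dtype=dtype)
        self.units = units
        self.input_dim = input_dim
        self.return_sequences = return_sequences
        self.dropout = dropout
        self.recurrent_dropout = recurrent_dropout
        self.params = [self.fwd.Wx, self.fwd.Wh, self.fwd.b,
                       self.bwd.Wx, self.bwd.Wh, self.bwd.b]
        self.grads = [self.fwd.dWx, self.fwd.dWh, self.fwd.db,
                      self.bwd.dWx, self.bwd.dWh, self.bwd.db]

    def _masks(self, B, d, train, rng, dtype):
        if not train:
            return None, None, None, None
        def mk(rate, dim):
            if rate <= 0.0:
                return None
            keep = 1.0 - rate
            return (rng.random((B, dim)) < keep).astype(dtype) / keep
        return (mk(self.dropout, d), mk(self.recurrent_dropout, self.units),
                mk(self.dropout, d), mk(self.recurrent_dropout, self.units))

    def forward(self, x, train, rng):
        B, T, d = x.shape
        im_f, rm_f, im_b, rm_b = self._masks(B, d, train, rng, x.dtype)
        self._im_f, self._im_b = im_f, im_b
        Hf = self.fwd.forward(x, im_f, rm_f)
        x_rev = x[:, ::-1]
        Hb = self.bwd.forward(x_rev, im_b, rm_b)
        self._T = T
        if self.return_sequences:
            # backward outputs re-reversed so step t aligns with input step t
            return np.concatenate([Hf, Hb[:, ::-1]], axis=2)
        return np.concatenate([Hf[:, -1], Hb[:, -1]], axis=1)

    def backward(self, dy):
        u = self.units
        T = self._T
        if self.return_sequences:
            dHf = np.ascontiguousarray(dy[:, :, :u])
            dHb = np.ascontiguousarray(dy[:, ::-1, u:])
        else:
            B = dy.shape[0]
            dHf = np.zeros((B, T, u), dtype=dy.dtype)
            dHb = np.zeros((B, T, u), dtype=dy.dtype)
            dHf[:, -1] = dy[:, :u]
            dHb[:, -1] = dy[:, u:]
        dXf = self.fwd.backward(dHf)
        dXb = self.bwd.backward(dHb)[:, ::-1]
        if self._im_f is not None:
            dXf = dXf * self._im_f[:, None, :]
        if self._im_b is not None:
            dXb = dXb * self._im_b[:, None, :]
        return dXf + dXb

    def n_params(self) -> int:
        return int(2 * 4 * self.units * (self.input_dim + self.units + 1))


class Sequential:
    """A plain feed-forward stack of layers with shared dropout RNG."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def dtype(self):
        return self.parameters()[0].dtype

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self.layers:
            out.extend(layer.grads)
        return out

    def layer_param_counts(self) -> list[int]:
        return [layer.n_params() for layer in self.layers]

    def n_params(self) -> int:
        return sum(self.layer_param_counts())

    def get_weights(self) -> list[np.ndarray]:
        extra = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                extra.extend([layer.moving_mean, layer.moving_var])
        return [p.copy() for p in self.parameters() + extra]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        targets = self.parameters()
        extra = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                extra.extend([layer.moving_mean, layer.moving_var])
        targets = targets + extra
        if len(weights) != len(targets):
            raise ValueError(f"expected {len(targets)} weight arrays, got {len(weights)}")
        for tgt, w in zip(targets, weights):
            if tgt.shape != w.shape:
                raise ValueError(f"shape mismatch: {tgt.shape} vs {w.shape}")
            tgt[...] = w


class Adam:
    """Adam optimiser over a Sequential's parameter list."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in model.parameters()]
        self.v = [np.zeros_like(p) for p in model.parameters()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.model.parameters(), self.model.gradients(),
                              self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
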