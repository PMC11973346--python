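"""Trainable layer primitives with explicit reverse-mode gradients.

Minimal layer framework used by the decoder: each :class:`Layer` caches
what its ``forward`` needs for ``backward`` and accumulates parameter
gradients into :class:`Parameter` objects, which the :class:`Adam`
optimizer updates.  Every backward pass is checked against finite
differences in the test suite.

Shapes follow the decoder's conventions:

* band tensors      ``(N, B, C, T)``  trials, bands/maps, channels, time
* node features     ``(N, B, C, F)``
* channel-collapsed ``(N, F, T)``
* sequences         ``(N, steps, F)``
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter", "Layer", "Sequential", "Adam",
    "TemporalConv", "ChannelConv", "GroupedChannelConv",
    "BatchNorm", "MaxPoolTime", "AvgPoolTime", "Dropout",
    "ReLU", "ELU", "GraphConv", "LSTM", "Linear", "LogSoftmax",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base class: subclasses set ``params`` and implement forward/backward.

    ``skip_input_grad`` may be set on a layer that sits directly on the
    network input; its ``backward`` then accumulates parameter gradients
    but returns None instead of the (unused) input gradient.
    """

    params: list[Parameter]

    def __init__(self) -> None:
        self.params = []
        self.skip_input_grad = False

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)
        self.params = [p for l in layers for p in l.params]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------

class TemporalConv(Layer):
    """2-D convolution with kernel (1, k): per-channel temporal filtering.

    Input ``(N, B_in, C, T)`` -> output ``(N, F, C, T)`` with "same"
    zero padding along time, stride 1.  Internally the input is moved to
    a channels-last scratch layout and the convolution is computed as k
    shifted GEMMs, which avoids materializing the (N, B, C, T, k) window
    tensor.
    """

    def __init__(self, in_maps: int, out_maps: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel
        fan_in = in_maps * kernel
        self.weight = Parameter(_fan_in_uniform(rng, (out_maps, in_maps, kernel), fan_in), "weight")
        self.bias = Parameter(_fan_in_uniform(rng, (out_maps,), fan_in), "bias")
        self.params = [self.weight, self.bias]

    def _pad(self) -> tuple[int, int]:
        return ((self.k - 1) // 2, self.k // 2)

    def forward(self, x, training=False):
        n, b, c, t = x.shape
        pl, pr = self._pad()
        w = self.weight.data.astype(x.dtype, copy=False)  # (f, b, k)
        # channels-last: (n, c, t_padded, b), contiguous in the last axis
        xt = np.zeros((n, c, t + pl + pr, b), dtype=x.dtype)
        xt[:, :, pl : pl + t, :] = x.transpose(0, 2, 3, 1)
        y = np.zeros((n, c, t, self.weight.data.shape[0]), dtype=x.dtype)
        for j in range(self.k):
            y += xt[:, :, j : j + t, :] @ w[:, :, j].T
        self._xt, self._xshape = xt, x.shape
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        return y + self.bias.data.astype(x.dtype, copy=False)[None, :, None, None]

    def backward(self, dy):
        n, b, c, t = self._xshape
        pl, pr = self._pad()
        f = self.weight.data.shape[0]
        w = self.weight.data.astype(dy.dtype, copy=False)
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))  # (n, c, t, f)
        dy2 = dyt.reshape(-1, f)
        dw = np.empty_like(self.weight.data)
        dxt = None if self.skip_input_grad else np.zeros_like(self._xt)
        for j in range(self.k):
            xs = self._xt[:, :, j : j + t, :].reshape(-1, b)
            dw[:, :, j] = dy2.T @ xs
            if dxt is not None:
                dxt[:, :, j : j + t, :] += dy2.reshape(n, c, t, f) @ w[:, :, j]
        self.weight.grad += dw
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        self._xt = None
        if dxt is None:
            return None
        dx = dxt[:, :, pl : pl + t, :].transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dx)


class ChannelConv(Layer):
    """2-D convolution with kernel (C, 1) collapsing the channel axis.

    Input ``(N, B, C, F)`` -> output ``(N, out_maps, F)``; each output map
    mixes all bands and all channels at one position of the last axis.
    """

    def __init__(self, in_maps: int, n_channels: int, out_maps: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = in_maps * n_channels
        self.weight = Parameter(_fan_in_uniform(rng, (out_maps, in_maps, n_channels), fan_in), "weight")
        self.bias = Parameter(_fan_in_uniform(rng, (out_maps,), fan_in), "bias")
        self.params = [self.weight, self.bias]

    def forward(self, x, training=False):
        self._x = x
        w = self.weight.data.astype(x.dtype, copy=False)
        y = np.einsum("nbcf,obc->nof", x, w, optimize=True)
        return y + self.bias.data.astype(x.dtype, copy=False)[None, :, None]

    def backward(self, dy):
        w = self.weight.data.astype(dy.dtype, copy=False)
        self.weight.grad += np.einsum("nbcf,nof->obc", self._x, dy, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2))
        dx = np.einsum("nof,obc->nbcf", dy, w, optimize=True)
        self._x = None
        return dx


class GroupedChannelConv(Layer):
    """Grouped (C, 1) spatial convolution: each band gets its own filters.

    Input ``(N, G, C, T)`` with G groups; ``filters_per_group`` spatial
    filters are learned per group, so the output is
    ``(N, G * filters_per_group, T)`` and filter ``o`` reads only band
    ``o // filters_per_group``.
    """

    def __init__(self, n_groups: int, n_channels: int, filters_per_group: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.g, self.m = n_groups, filters_per_group
        fan_in = n_channels
        self.weight = Parameter(
            _fan_in_uniform(rng, (n_groups, filters_per_group, n_channels), fan_in), "weight")
        self.bias = Parameter(
            _fan_in_uniform(rng, (n_groups * filters_per_group,), fan_in), "bias")
        self.params = [self.weight, self.bias]

    def forward(self, x, training=False):
        self._x = x
        n, g, c, t = x.shape
        w = self.weight.data.astype(x.dtype, copy=False)
        y = np.einsum("ngct,gmc->ngmt", x, w, optimize=True)
        y = y.reshape(n, g * self.m, t)
        return y + self.bias.data.astype(x.dtype, copy=False)[None, :, None]

    def backward(self, dy):
        n, _, t = dy.shape
        dyg = dy.reshape(n, self.g, self.m, t)
        self.weight.grad += np.einsum("ngct,ngmt->gmc", self._x, dyg, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2))
        self._x = None
        if self.skip_input_grad:
            return None
        w = self.weight.data.astype(dy.dtype, copy=False)
        return np.einsum("ngmt,gmc->ngct", dyg, w, optimize=True)


# ---------------------------------------------------------------------------
# Normalization / pooling / regularization
# ---------------------------------------------------------------------------

class BatchNorm(Layer):
    """Batch normalization over feature maps (axis 1), any trailing shape.

    Normalizes each feature map over the batch and all trailing axes;
    keeps running statistics for inference mode.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Parameter(np.ones(num_features), "gamma")
        self.beta = Parameter(np.zeros(num_features), "beta")
        self.params = [self.gamma, self.beta]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def _axes(self, x):
        return (0,) + tuple(range(2, x.ndim))

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training=False):
        axes, sh = self._axes(x), self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        mean = mean.astype(x.dtype, copy=False)
        inv_std = inv_std.astype(x.dtype, copy=False)
        xhat = (x - mean.reshape(sh)) * inv_std.reshape(sh)
        self._cache = (xhat, inv_std, axes, sh, training, x.shape)
        gamma = self.gamma.data.astype(x.dtype, copy=False)
        beta = self.beta.data.astype(x.dtype, copy=False)
        return gamma.reshape(sh) * xhat + beta.reshape(sh)

    def backward(self, dy):
        xhat, inv_std, axes, sh, training, xshape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.data.astype(dy.dtype, copy=False).reshape(sh)
        if not training:
            return dxhat * inv_std.reshape(sh)
        m = np.prod([xshape[a] for a in axes])
        term = dxhat - dxhat.mean(axis=axes).reshape(sh) \
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(sh)
        self._cache = None
        return term * inv_std.reshape(sh)


class MaxPoolTime(Layer):
    """Non-overlapping max pooling along the last (time) axis."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.p = pool

    def forward(self, x, training=False):
        t = x.shape[-1]
        if t % self.p:
            raise ValueError(f"time length {t} not divisible by pool {self.p}")
        xr = x.reshape(*x.shape[:-1], t // self.p, self.p)
        self._argmax = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        t = self._shape[-1]
        dxr = np.zeros(dy.shape + (self.p,))
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        self._argmax = None
        return dxr.reshape(self._shape)


class AvgPoolTime(Layer):
    """Non-overlapping mean over windows of the last axis."""

    def __init__(self, window: int) -> None:
        super().__init__()
        self.w = window

    def forward(self, x, training=False):
        t = x.shape[-1]
        if t % self.w:
            raise ValueError(f"time length {t} not divisible by window {self.w}")
        self._shape = x.shape
        return x.reshape(*x.shape[:-1], t // self.w, self.w).mean(axis=-1)

    def backward(self, dy):
        dx = np.repeat(dy[..., None], self.w, axis=-1) / self.w
        return dx.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout p must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dy = dy * self._mask
        self._mask = None
        return dy


class ReLU(Layer):
    def forward(self, x, training=False):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, dy):
        dy = np.where(self._pos, dy, 0.0)
        self._pos = None
        return dy


class ELU(Layer):
    def forward(self, x, training=False):
        neg = np.expm1(np.minimum(x, 0.0))
        self._cache = (x > 0, neg)
        return np.where(x > 0, x, neg)

    def backward(self, dy):
        pos, neg = self._cache
        self._cache = None
        return np.where(pos, dy, dy * (neg + 1.0))


# ---------------------------------------------------------------------------
# Graph convolution (trainable layer form)
# ---------------------------------------------------------------------------

class GraphConv(Layer):
    """Graph convolution ``relu(S H W + b)`` over node features.

    Input ``(N, B, C, Fin)``; the fixed propagation matrix S ``(C, C)``
    mixes channels, the weight mixes features, both shared across bands.
    """

    def __init__(self, prop: np.ndarray, in_features: int, out_features: int,
                 rng: np.random.Generator, activation: str = "relu") -> None:
        super().__init__()
        self.s = np.asarray(prop, dtype=np.float64)
        self.weight = Parameter(
            _fan_in_uniform(rng, (in_features, out_features), in_features), "weight")
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features), "bias")
        self.params = [self.weight, self.bias]
        self.act = ReLU() if activation == "relu" else None

    def forward(self, x, training=False):
        s_mat = self.s.astype(x.dtype, copy=False)
        sh = np.einsum("cu,nbuf->nbcf", s_mat, x, optimize=True)
        z = sh @ self.weight.data.astype(x.dtype, copy=False) \
            + self.bias.data.astype(x.dtype, copy=False)
        self._sh = sh
        y = self.act.forward(z, training) if self.act else z
        return y

    def backward(self, dy):
        dz = self.act.backward(dy) if self.act else dy
        self.weight.grad += np.einsum("nbcf,nbcg->fg", self._sh, dz, optimize=True)
        self.bias.grad += dz.sum(axis=(0, 1, 2))
        dsh = dz @ self.weight.data.astype(dz.dtype, copy=False).T
        dx = np.einsum("cu,nbcf->nbuf", self.s.astype(dz.dtype, copy=False),
                       dsh, optimize=True)  # S symmetric
        self._sh = None
        return dx


# ---------------------------------------------------------------------------
# Recurrence
# ---------------------------------------------------------------------------

class LSTM(Layer):
    """Single-layer LSTM over ``(N, steps, features)`` sequences.

    Gate equations (sigmoid gates, tanh candidate, zero initial state):

        i_t = sig(W_i x_t + U_i h_{t-1} + b_i)
        f_t = sig(W_f x_t + U_f h_{t-1} + b_f)
        o_t = sig(W_o x_t + U_o h_{t-1} + b_o)
        c~_t = tanh(W_c x_t + U_c h_{t-1} + b_c)
        c_t = f_t * c_{t-1} + i_t * c~_t
        h_t = o_t * tanh(c_t)

    Returns the hidden state at every step, ``(N, steps, hidden)``.
    """

    GATES = ("i", "f", "o", "c")

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden_size
        self.w = {}
        self.u = {}
        self.b = {}
        for g in self.GATES:
            self.w[g] = Parameter(_fan_in_uniform(rng, (input_size, hidden_size), input_size), f"w_{g}")
            self.u[g] = Parameter(_fan_in_uniform(rng, (hidden_size, hidden_size), hidden_size), f"u_{g}")
            self.b[g] = Parameter(np.zeros(hidden_size), f"b_{g}")
        self.params = [*self.w.values(), *self.u.values(), *self.b.values()]

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    def forward(self, x, training=False):
        n, steps, _ = x.shape
        dt = x.dtype
        wd = {g: self.w[g].data.astype(dt, copy=False) for g in self.GATES}
        ud = {g: self.u[g].data.astype(dt, copy=False) for g in self.GATES}
        bd = {g: self.b[g].data.astype(dt, copy=False) for g in self.GATES}
        h = np.zeros((n, self.hidden), dtype=dt)
        c = np.zeros((n, self.hidden), dtype=dt)
        cache = []
        hs = np.empty((n, steps, self.hidden), dtype=dt)
        for t in range(steps):
            xt = x[:, t]
            gates = {
                g: xt @ wd[g] + h @ ud[g] + bd[g]
                for g in self.GATES
            }
            i = self._sigmoid(gates["i"])
            f = self._sigmoid(gates["f"])
            o = self._sigmoid(gates["o"])
            ct = np.tanh(gates["c"])
            c_prev = c
            c = f * c_prev + i * ct
            tanh_c = np.tanh(c)
            h_prev = h
            h = o * tanh_c
            hs[:, t] = h
            cache.append((xt, h_prev, c_prev, i, f, o, ct, tanh_c))
        self._cache = cache
        return hs

    def backward(self, dhs):
        cache = self._cache
        n, steps, _ = dhs.shape
        dt = dhs.dtype
        wd = {g: self.w[g].data.astype(dt, copy=False) for g in self.GATES}
        ud = {g: self.u[g].data.astype(dt, copy=False) for g in self.GATES}
        dx = np.empty((n, steps, self.w["i"].data.shape[0]), dtype=dt)
        dh_next = np.zeros((n, self.hidden), dtype=dt)
        dc_next = np.zeros((n, self.hidden), dtype=dt)
        for t in reversed(range(steps)):
            xt, h_prev, c_prev, i, f, o, ct, tanh_c = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * ct
            df = dc * c_prev
            dct = dc * i
            dc_next = dc * f
            dgate = {
                "i": di * i * (1 - i),
                "f": df * f * (1 - f),
                "o": do * o * (1 - o),
                "c": dct * (1 - ct**2),
            }
            dxt = np.zeros_like(xt)
            dh_next = np.zeros((n, self.hidden))
            for g in self.GATES:
                self.w[g].grad += xt.T @ dgate[g]
                self.u[g].grad += h_prev.T @ dgate[g]
                self.b[g].grad += dgate[g].sum(axis=0)
                dxt += dgate[g] @ wd[g].T
                dh_next += dgate[g] @ ud[g].T
            dx[:, t] = dxt
        self._cache = None
        return dx


class Linear(Layer):
    """Affine map applied to the last axis."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.weight = Parameter(
            _fan_in_uniform(rng, (in_features, out_features), in_features), "weight")
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features), "bias")
        self.params = [self.weight, self.bias]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.weight.data.astype(x.dtype, copy=False) \
            + self.bias.data.astype(x.dtype, copy=False)

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.weight.grad += x2.T @ dy2
        self.bias.grad += dy2.sum(axis=0)
        dx = dy @ self.weight.data.astype(dy.dtype, copy=False).T
        self._x = None
        return dx


class LogSoftmax(Layer):
    """Row-wise log-softmax over the last axis."""

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        self._logp = z - lse
        return self._logp

    def backward(self, dy):
        p = np.exp(self._logp)
        dx = dy - p * dy.sum(axis=-1, keepdims=True)
        self._logp = None
        return dx


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard moment coefficients and no weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
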