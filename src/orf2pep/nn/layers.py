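"""Neural-network building blocks on top of the autograd engine.

Shapes follow the (batch, channels, length) convention for convolutions and
(batch, time, features) for recurrent/attention layers.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autograd import DEFAULT_DTYPE, Tensor, concat


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, v in self._named_buffers():
            state[name] = v.copy()
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = arr.astype(params[name].data.dtype).copy()
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unexpected key {name}")

    def _named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, np.ndarray) and name.startswith("running_"):
                yield path, v
            elif isinstance(v, Module):
                yield from v._named_buffers(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{path}.{i}.")


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.weight = Tensor(_glorot(rng, (in_features, out_features), in_features,
                                     out_features, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution (no padding, stride 1) with explicit backward."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = Tensor(_glorot(rng, (out_channels, in_channels, kernel_size),
                                     fan_in, out_channels, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
        self.kernel_size = kernel_size

    def __call__(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        xd, wd = x.data, w.data
        B, C, L = xd.shape
        K = self.kernel_size
        if L < K:
            raise ValueError(f"input length {L} shorter than kernel {K}")
        Lo = L - K + 1
        s0, s1, s2 = xd.strides
        xu = as_strided(xd, shape=(B, C, K, Lo), strides=(s0, s1, s2, s2))
        y = np.einsum("bckl,ock->bol", xu, wd, optimize=True) + b.data[:, None]
        prev = tuple(t for t in (x, w, b) if t.requires_grad or t._prev)
        out = Tensor(y, _prev=prev)
        if prev:
            def bw(g):
                if w.requires_grad:
                    w._accum(np.einsum("bckl,bol->ock", xu, g, optimize=True))
                if b.requires_grad:
                    b._accum(g.sum(axis=(0, 2)))
                if x.requires_grad or x._prev:
                    gx = np.zeros_like(xd)
                    for k in range(K):
                        gx[:, :, k:k + Lo] += np.einsum("bol,ock->bcl", g, wd[:, :, k:k + 1],
                                                        optimize=True)
                    x._accum(gx)
            out._backward = bw
        return out


class MaxPool1d(Module):
    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.pool_size = pool_size

    def __call__(self, x: Tensor) -> Tensor:
        P = self.pool_size
        B, C, L = x.data.shape
        Lo = L // P
        trimmed = x.data[:, :, :Lo * P].reshape(B, C, Lo, P)
        idx = trimmed.argmax(axis=3)
        y = np.take_along_axis(trimmed, idx[..., None], axis=3)[..., 0]
        out = Tensor(y, _prev=x._track())
        if out._prev:
            def bw(g):
                gx = np.zeros((B, C, Lo, P), dtype=x.data.dtype)
                np.put_along_axis(gx, idx[..., None], g[..., None], axis=3)
                full = np.zeros_like(x.data)
                full[:, :, :Lo * P] = gx.reshape(B, C, Lo * P)
                x._accum(full)
            out._backward = bw
        return out


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE, pad_id: int | None = None):
        super().__init__()
        w = (rng.standard_normal((num_embeddings, dim)) * 0.1).astype(dtype)
        if pad_id is not None:
            w[pad_id] = 0.0
        self.weight = Tensor(w, requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids)]


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=DEFAULT_DTYPE, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu) * inv
        y = gamma.data * xhat + beta.data
        prev = tuple(t for t in (x, gamma, beta) if t.requires_grad or t._prev)
        out = Tensor(y, _prev=prev)
        if prev:
            N = x.data.shape[-1]

            def bw(g):
                if gamma.requires_grad:
                    gamma._accum((g * xhat).reshape(-1, N).sum(axis=0))
                if beta.requires_grad:
                    beta._accum(g.reshape(-1, N).sum(axis=0))
                if x.requires_grad or x._prev:
                    dxhat = g * gamma.data
                    t1 = dxhat.sum(axis=-1, keepdims=True)
                    t2 = (dxhat * xhat).sum(axis=-1, keepdims=True)
                    x._accum(inv / N * (N * dxhat - t1 - xhat * t2))
            out._backward = bw
        return out


class BatchNorm1d(Module):
    def __init__(self, dim: int, dtype=DEFAULT_DTYPE, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(dim, dtype=dtype)
        self.running_var = np.ones(dim, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        if self.training:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu) * inv
        y = gamma.data * xhat + beta.data
        prev = tuple(t for t in (x, gamma, beta) if t.requires_grad or t._prev)
        out = Tensor(y, _prev=prev)
        if prev:
            training = self.training
            N = x.data.shape[0]

            def bw(g):
                if gamma.requires_grad:
                    gamma._accum((g * xhat).sum(axis=0))
                if beta.requires_grad:
                    beta._accum(g.sum(axis=0))
                if x.requires_grad or x._prev:
                    dxhat = g * gamma.data
                    if training:
                        t1 = dxhat.sum(axis=0)
                        t2 = (dxhat * xhat).sum(axis=0)
                        x._accum(inv / N * (N * dxhat - t1 - xhat * t2))
                    else:
                        x._accum(dxhat * inv)
            out._backward = bw
        return out


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"heads ({heads}) must divide model width ({dim})")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.wq = Linear(dim, dim, rng, dtype)
        self.wk = Linear(dim, dim, rng, dtype)
        self.wv = Linear(dim, dim, rng, dtype)
        self.wo = Linear(dim, dim, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        H, dh = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)  # (B,H,T,dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: MHA + residual + LN, then FFN + residual + LN."""

    def __init__(self, dim: int, heads: int, ff_dim: int, rng: np.random.Generator,
                 dropout: float = 0.0, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, heads, rng, dtype)
        self.ln1 = LayerNorm(dim, dtype)
        self.ff1 = Linear(dim, ff_dim, rng, dtype)
        self.ff2 = Linear(ff_dim, dim, rng, dtype)
        self.ln2 = LayerNorm(dim, dtype)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x + self.drop(self.attn(x)))
        return self.ln2(h + self.drop(self.ff2(self.ff1(h).relu())))


class LSTM(Module):
    """Single-direction LSTM with hand-written backpropagation through time.

    Gate order in the packed weight matrices is (input, forget, cell, output).
    Returns the full hidden-state sequence (B, T, H).
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.hidden_dim = hidden_dim
        self.wx = Tensor(_glorot(rng, (input_dim, 4 * hidden_dim), input_dim,
                                 hidden_dim, dtype), requires_grad=True)
        self.wh = Tensor(_glorot(rng, (hidden_dim, 4 * hidden_dim), hidden_dim,
                                 hidden_dim, dtype), requires_grad=True)
        b = np.zeros(4 * hidden_dim, dtype=dtype)
        b[hidden_dim:2 * hidden_dim] = 1.0  # forget-gate bias: remember by default
        self.bias = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        wx, wh, bias = self.wx, self.wh, self.bias
        xd = x.data
        B, T, D = xd.shape
        H = self.hidden_dim
        h = np.zeros((B, H), dtype=xd.dtype)
        c = np.zeros((B, H), dtype=xd.dtype)
        cache = []
        hs = np.empty((B, T, H), dtype=xd.dtype)
        for t in range(T):
            z = xd[:, t] @ wx.data + h @ wh.data + bias.data
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
            g = np.tanh(z[:, 2 * H:3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, tc))
        prev = tuple(t_ for t_ in (x, wx, wh, bias) if t_.requires_grad or t_._prev)
        out = Tensor(hs, _prev=prev)
        if prev:
            h_prevs = np.concatenate([np.zeros((B, 1, H), dtype=xd.dtype),
                                      hs[:, :-1]], axis=1)

            def bw(g_all):
                gwx = np.zeros_like(wx.data)
                gwh = np.zeros_like(wh.data)
                gb = np.zeros_like(bias.data)
                gx = np.zeros_like(xd)
                gh_next = np.zeros((B, H), dtype=xd.dtype)
                gc_next = np.zeros((B, H), dtype=xd.dtype)
                for t in range(T - 1, -1, -1):
                    i, f, g_, o, c_prev, tc = cache[t]
                    gh = g_all[:, t] + gh_next
                    go = gh * tc
                    gc = gc_next + gh * o * (1.0 - tc * tc)
                    gi = gc * g_
                    gf = gc * c_prev
                    gg = gc * i
                    dz = np.concatenate([gi * i * (1 - i), gf * f * (1 - f),
                                         gg * (1 - g_ * g_), go * o * (1 - o)], axis=1)
                    gx[:, t] = dz @ wx.data.T
                    gwx += xd[:, t].T @ dz
                    gwh += h_prevs[:, t].T @ dz
                    gb += dz.sum(axis=0)
                    gh_next = dz @ wh.data.T
                    gc_next = gc * f
                if wx.requires_grad:
                    wx._accum(gwx)
                if wh.requires_grad:
                    wh._accum(gwh)
                if bias.requires_grad:
                    bias._accum(gb)
                if x.requires_grad or x._prev:
                    x._accum(gx)
            out._backward = bw
        return out


def gather_timesteps(hs: Tensor, idx: np.ndarray) -> Tensor:
    """Pick hidden state at per-sample time index: (B, T, H), (B,) -> (B, H)."""
    B = hs.shape[0]
    return hs[(np.arange(B), np.asarray(idx))]


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
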