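"""Minimal NumPy neural-network core with hand-written backpropagation.

Implements exactly the building blocks the fusion architectures need —
dense and temporal-convolution layers, a (bi)directional GRU, multi-head
attention, layer normalization, dropout, sinusoidal positional encoding —
plus AdamW and global-norm gradient clipping.  Every layer caches its
forward activations and exposes ``backward(dy) -> dx`` accumulating
parameter gradients; correctness is pinned down by finite-difference tests.

All layers accept inputs shaped (B, T, C) and default to float32; a float64
mode exists for gradient checking.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def positional_encoding(T: int, H: int, dtype=DEFAULT_DTYPE) -> np.ndarray:
    """Sinusoidal positional encoding, geometric wavelengths base 10000.

    PE[t, 2k] = sin(t / 10000^(2k/H)), PE[t, 2k+1] = cos(t / 10000^(2k/H)).
    """
    if T < 1 or H < 1:
        raise ValueError("T and H must be >= 1")
    pos = np.arange(T, dtype=np.float64)[:, None]
    k = np.arange(0, H, 2, dtype=np.float64)
    div = np.power(10000.0, k / H)
    pe = np.zeros((T, H), dtype=np.float64)
    pe[:, 0::2] = np.sin(pos / div)
    pe[:, 1::2] = np.cos(pos / div[: pe[:, 1::2].shape[1]])
    return pe.astype(dtype)


class Module:
    """Base class: parameter/gradient registry plus recursive traversal."""

    def __init__(self):
        self.p: dict[str, np.ndarray] = {}
        self.g: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def named_parameters(self, prefix: str = ""):
        for k, v in self.p.items():
            yield (prefix + k, v)
        for name, child in self._children.items():
            yield from child.named_parameters(prefix + name + ".")

    def named_grads(self, prefix: str = ""):
        for k, v in self.g.items():
            yield (prefix + k, v)
        for name, child in self._children.items():
            yield from child.named_grads(prefix + name + ".")

    def zero_grad(self):
        for k in self.g:
            self.g[k][...] = 0.0
        for child in self._children.values():
            child.zero_grad()

    def n_parameters(self) -> int:
        return sum(int(v.size) for _, v in self.named_parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match")
        for k, v in own.items():
            v[...] = state[k]

    def _init(self, name: str, shape, rng: np.random.Generator,
              bound: float, dtype) -> None:
        self.p[name] = rng.uniform(-bound, bound, size=shape).astype(dtype)
        self.g[name] = np.zeros(shape, dtype=dtype)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        bound = 1.0 / np.sqrt(din)
        self._init("W", (din, dout), rng, bound, dtype)
        self._init("b", (dout,), rng, bound, dtype)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.p["W"] + self.p["b"]

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.g["W"] += x2.T @ dy2
        self.g["b"] += dy2.sum(axis=0)
        return dy @ self.p["W"].T


class Conv1dSame(Module):
    """Length-preserving temporal convolution over (B, T, Cin) input."""

    def __init__(self, cin: int, cout: int, kernel: int,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd for symmetric padding")
        self.kernel = kernel
        bound = 1.0 / np.sqrt(cin * kernel)
        self._init("W", (kernel, cin, cout), rng, bound, dtype)
        self._init("b", (cout,), rng, bound, dtype)

    def forward(self, x, training=False, rng=None):
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # windows: (B, T, Cin, K)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        self._win = win
        self._shape = x.shape
        return np.einsum("btck,kco->bto", win, self.p["W"],
                         optimize=True) + self.p["b"]

    def backward(self, dy):
        B, T, _ = self._shape
        pad = self.kernel // 2
        self.g["W"] += np.einsum("btck,bto->kco", self._win, dy, optimize=True)
        self.g["b"] += dy.sum(axis=(0, 1))
        dwin = np.einsum("bto,kco->btkc", dy, self.p["W"], optimize=True)
        dxp = np.zeros((B, T + 2 * pad, self._shape[2]), dtype=dy.dtype)
        for k in range(self.kernel):
            dxp[:, k:k + T, :] += dwin[:, :, k, :]
        return dxp[:, pad:pad + T, :]


class ReLU(Module):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Module):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float):
        super().__init__()
        self.rate = p

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask.astype(dy.dtype)


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=DEFAULT_DTYPE, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.p["gamma"] = np.ones(dim, dtype=dtype)
        self.p["beta"] = np.zeros(dim, dtype=dtype)
        self.g["gamma"] = np.zeros(dim, dtype=dtype)
        self.g["beta"] = np.zeros(dim, dtype=dtype)

    def forward(self, x, training=False, rng=None):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.p["gamma"] * self._xhat + self.p["beta"]

    def backward(self, dy):
        xhat = self._xhat
        dxhat = dy * self.p["gamma"]
        self.g["gamma"] += (dy * xhat).reshape(-1, dy.shape[-1]).sum(axis=0)
        self.g["beta"] += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return self._inv * (dxhat - m1 - xhat * m2)


class GRU(Module):
    """Single-layer unidirectional GRU over (B, T, D) input.

    Gate layout follows the common r/z/n convention with the candidate's
    hidden contribution gated by r before the tanh.
    """

    def __init__(self, din: int, dh: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.dh = dh
        bound = 1.0 / np.sqrt(dh)
        self._init("W_ih", (din, 3 * dh), rng, bound, dtype)
        self._init("W_hh", (dh, 3 * dh), rng, bound, dtype)
        self._init("b_ih", (3 * dh,), rng, bound, dtype)
        self._init("b_hh", (3 * dh,), rng, bound, dtype)

    def forward(self, x, training=False, rng=None):
        B, T, _ = x.shape
        H = self.dh
        Xp = x @ self.p["W_ih"] + self.p["b_ih"]  # (B, T, 3H)
        h = np.zeros((B, H), dtype=x.dtype)
        R = np.empty((B, T, H), dtype=x.dtype)
        Z = np.empty_like(R)
        N = np.empty_like(R)
        HN = np.empty_like(R)  # W_hn h + b_hn term (pre r-gating)
        Hout = np.empty_like(R)
        W_hh, b_hh = self.p["W_hh"], self.p["b_hh"]
        for t in range(T):
            hp = h @ W_hh + b_hh
            r = sigmoid(Xp[:, t, :H] + hp[:, :H])
            z = sigmoid(Xp[:, t, H:2 * H] + hp[:, H:2 * H])
            hn = hp[:, 2 * H:]
            n = np.tanh(Xp[:, t, 2 * H:] + r * hn)
            h = (1.0 - z) * n + z * h
            R[:, t], Z[:, t], N[:, t], HN[:, t], Hout[:, t] = r, z, n, hn, h
        self._cache = (x, R, Z, N, HN, Hout)
        return Hout

    def backward(self, dH):
        x, R, Z, N, HN, Hout = self._cache
        B, T, _ = x.shape
        H = self.dh
        W_hh = self.p["W_hh"]
        dXp = np.zeros((B, T, 3 * H), dtype=dH.dtype)
        dW_hh = np.zeros_like(self.g["W_hh"])
        db_hh = np.zeros_like(self.g["b_hh"])
        dh = np.zeros((B, H), dtype=dH.dtype)
        for t in range(T - 1, -1, -1):
            dh_t = dH[:, t] + dh
            h_prev = Hout[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dH.dtype)
            r, z, n, hn = R[:, t], Z[:, t], N[:, t], HN[:, t]
            dz = dh_t * (h_prev - n)
            dn = dh_t * (1.0 - z)
            dh = dh_t * z
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * hn
            dhn = dn_pre * r
            dr_pre = dr * r * (1.0 - r)
            dz_pre = dz * z * (1.0 - z)
            dXp[:, t, :H] = dr_pre
            dXp[:, t, H:2 * H] = dz_pre
            dXp[:, t, 2 * H:] = dn_pre
            dhp = np.concatenate([dr_pre, dz_pre, dhn], axis=1)  # (B, 3H)
            dW_hh += h_prev.T @ dhp
            db_hh += dhp.sum(axis=0)
            dh = dh + dhp @ W_hh.T
        self.g["W_hh"] += dW_hh
        self.g["b_hh"] += db_hh
        x2 = x.reshape(-1, x.shape[-1])
        dXp2 = dXp.reshape(-1, 3 * H)
        self.g["W_ih"] += x2.T @ dXp2
        self.g["b_ih"] += dXp2.sum(axis=0)
        return dXp @ self.p["W_ih"].T


class BiGRU(Module):
    """Bidirectional single-layer GRU; outputs (B, T, 2*dh)."""

    def __init__(self, din: int, dh: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.fwd = self.add_child("fwd", GRU(din, dh, rng, dtype))
        self.bwd = self.add_child("bwd", GRU(din, dh, rng, dtype))

    def forward(self, x, training=False, rng=None):
        hf = self.fwd.forward(x, training)
        hb = self.bwd.forward(x[:, ::-1], training)[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy):
        dh = self.fwd.dh
        dx = self.fwd.backward(np.ascontiguousarray(dy[:, :, :dh]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, dh:]))
        return dx + dxb[:, ::-1]


class MultiheadAttention(Module):
    """Multi-head scaled dot-product attention with separate query and
    key/value inputs (cross-attention) and dropout on the attention weights."""

    def __init__(self, H: int, heads: int, dropout: float,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        super().__init__()
        if H % heads != 0:
            raise ValueError("H must be divisible by the number of heads")
        self.H, self.heads, self.dh = H, heads, H // heads
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self._init(name, (H, H), rng, 1.0 / np.sqrt(H), dtype)
            self._init(name.replace("W", "b"), (H,), rng, 1.0 / np.sqrt(H), dtype)
        self.drop = self.add_child("drop", Dropout(dropout))
        self.last_attn: np.ndarray | None = None

    def _split(self, x):
        B, T, _ = x.shape
        return x.reshape(B, T, self.heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, h, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dh)

    def forward(self, q_in, kv_in, training=False, rng=None):
        p = self.p
        self._q_in, self._kv_in = q_in, kv_in
        Q = self._split(q_in @ p["Wq"] + p["bq"])
        K = self._split(kv_in @ p["Wk"] + p["bk"])
        V = self._split(kv_in @ p["Wv"] + p["bv"])
        scale = 1.0 / np.sqrt(self.dh)
        scores = np.einsum("bhtd,bhsd->bhts", Q, K, optimize=True) * scale
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        self.last_attn = attn
        attn_d = self.drop.forward(attn, training, rng)
        ctx = np.einsum("bhts,bhsd->bhtd", attn_d, V, optimize=True)
        ctx_m = self._merge(ctx)
        self._cache = (Q, K, V, attn, attn_d, ctx_m, scale)
        return ctx_m @ p["Wo"] + p["bo"]

    def backward(self, dy):
        p = self.p
        Q, K, V, attn, attn_d, ctx_m, scale = self._cache
        dy2 = dy.reshape(-1, self.H)
        self.g["Wo"] += ctx_m.reshape(-1, self.H).T @ dy2
        self.g["bo"] += dy2.sum(axis=0)
        dctx = self._split(dy @ p["Wo"].T)
        dattn_d = np.einsum("bhtd,bhsd->bhts", dctx, V, optimize=True)
        dV = np.einsum("bhts,bhtd->bhsd", attn_d, dctx, optimize=True)
        dattn = self.drop.backward(dattn_d)
        # softmax backward (row-wise)
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores *= scale
        dQ = np.einsum("bhts,bhsd->bhtd", dscores, K, optimize=True)
        dK = np.einsum("bhts,bhtd->bhsd", dscores, Q, optimize=True)

        def unproject(dX4, x_in, Wname):
            dX = self._merge(dX4)
            x2 = x_in.reshape(-1, self.H)
            self.g[Wname] += x2.T @ dX.reshape(-1, self.H)
            self.g[Wname.replace("W", "b")] += dX.reshape(-1, self.H).sum(axis=0)
            return dX @ p[Wname].T

        dq_in = unproject(dQ, self._q_in, "Wq")
        dkv = unproject(dK, self._kv_in, "Wk") + unproject(dV, self._kv_in, "Wv")
        return dq_in, dkv


class AdamW:
    """Decoupled weight-decay Adam over a module's parameter registry."""

    def __init__(self, module: Module, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.module = module
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in module.named_parameters()}
        self.v = {k: np.zeros_like(v) for k, v in module.named_parameters()}

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        params = dict(self.module.named_parameters())
        grads = dict(self.module.named_grads())
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, pv in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            pv -= self.lr * self.wd * pv
            pv -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(pv.dtype)


def clip_grad_norm(module: Module, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    grads = dict(module.named_grads())
    for g in grads.values():
        total += float(np.sum(g.astype(np.float64) ** 2))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for g in grads.values():
            g *= scale
    return norm
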