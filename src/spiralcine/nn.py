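"""Minimal NumPy neural-network core with hand-written backward passes.

Implements exactly the layers needed by the 2D+t score U-Net: 3x3/1x1
convolutions, group normalization, SiLU, average-pool down / nearest-up
sampling, dense layers, FiLM conditioning on the noise level, and
variable-length temporal self-attention.  Every layer caches what its
backward pass needs; ``backward`` returns the gradient with respect to the
input and accumulates parameter gradients, which is sufficient both for
training and for the input-VJPs required by posterior-sampling guidance.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def params(self) -> list:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class SiLU(Layer):
    def forward(self, x):
        self._x = x
        return x * _sigmoid(x)

    def backward(self, dy):
        s = _sigmoid(self._x)
        return dy * (s * (1.0 + self._x * (1.0 - s)))


class Conv2d(Layer):
    """Same-padding stride-1 2D convolution on (N, C, H, W)."""

    def __init__(self, cin, cout, ksize=3, rng=None, zero_init=False,
                 dtype=np.float64, recompute=False):
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize * ksize
        if zero_init:
            w = np.zeros((cout, fan_in), dtype=dtype)
        else:
            w = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.W = Param(w)
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.recompute = recompute

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        k, p = self.k, self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        v = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        return v.transpose(0, 2, 3, 1, 4, 5).reshape(-1, self.cin * k * k)

    def forward(self, x):
        n, _, h, w = x.shape
        col = self._im2col(x)
        self._shape = (n, h, w)
        if self.recompute:
            self._x, self._col = x, None
        else:
            self._x, self._col = None, col
        y = col @ self.W.value.T + self.b.value
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, h, w = self._shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        col = self._col if self._col is not None else self._im2col(self._x)
        self.W.grad += dyf.T @ col
        self.b.grad += dyf.sum(axis=0)
        # dx: correlate dy with spatially flipped, in/out-transposed kernels
        k = self.k
        Wt = (
            self.W.value.reshape(self.cout, self.cin, k, k)[:, :, ::-1, ::-1]
            .transpose(1, 0, 2, 3)
            .reshape(self.cin, self.cout * k * k)
        )
        p = k // 2
        dyp = dy
        if p:
            dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        v = sliding_window_view(dyp, (k, k), axis=(2, 3))
        colg = v.transpose(0, 2, 3, 1, 4, 5).reshape(-1, self.cout * k * k)
        dx = (colg @ Wt.T).reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)
        self._col = None
        return dx


class Dense(Layer):
    def __init__(self, cin, cout, rng, zero_init=False, dtype=np.float64):
        if zero_init:
            w = np.zeros((cout, cin), dtype=dtype)
        else:
            w = (rng.standard_normal((cout, cin)) * np.sqrt(1.0 / cin)).astype(dtype)
        self.W = Param(w)
        self.b = Param(np.zeros(cout, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += dy2.T @ x2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value


class GroupNorm(Layer):
    def __init__(self, groups, channels, dtype=np.float64, eps=1e-5):
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.g, self.c, self.eps = groups, channels, eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        n, c, h, w = x.shape
        xg = x.reshape(n, self.g, c // self.g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = xg.var(axis=(2, 3, 4), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (xg - mu) * self._inv
        out = self._xhat.reshape(n, c, h, w)
        self._shape = (n, c, h, w)
        return out * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]

    def backward(self, dy):
        n, c, h, w = self._shape
        self.gamma.grad += (dy * self._xhat.reshape(n, c, h, w)).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.gamma.value[None, :, None, None]).reshape(
            n, self.g, c // self.g, h, w
        )
        m1 = dxhat.mean(axis=(2, 3, 4), keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=(2, 3, 4), keepdims=True)
        dx = self._inv * (dxhat - m1 - self._xhat * m2)
        return dx.reshape(n, c, h, w)


class AvgPool2(Layer):
    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be even for pooling")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25


class NearestUp2(Layer):
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class FiLM(Layer):
    """Per-channel scale/shift from the noise embedding: h*(1+s)+t."""

    def __init__(self, emb_dim, channels, rng, dtype=np.float64):
        self.lin = Dense(emb_dim, 2 * channels, rng, zero_init=True, dtype=dtype)
        self.c = channels

    def params(self):
        return self.lin.params()

    def forward(self, h, emb):
        st = self.lin.forward(emb)  # (2c,)
        self._s = st[: self.c]
        self._t = st[self.c :]
        self._h = h
        return h * (1.0 + self._s)[None, :, None, None] + self._t[None, :, None, None]

    def backward(self, dy):
        ds = (dy * self._h).sum(axis=(0, 2, 3))
        dt = dy.sum(axis=(0, 2, 3))
        self._demb = self.lin.backward(np.concatenate([ds, dt]))
        return dy * (1.0 + self._s)[None, :, None, None]


def _groups_for(channels: int, target: int = 8) -> int:
    g = min(target, channels)
    while channels % g:
        g -= 1
    return g


class TemporalAttention(Layer):
    """Single-head self-attention across frames, per spatial location.

    Input (F, C, H, W); the frame axis is the sequence, so any clip length
    is accepted.  Residual connection included.
    """

    def __init__(self, channels, rng, dtype=np.float64):
        self.c = channels
        self.norm = GroupNorm(_groups_for(channels), channels, dtype=dtype)
        self.Wq = Dense(channels, channels, rng, dtype=dtype)
        self.Wk = Dense(channels, channels, rng, dtype=dtype)
        self.Wv = Dense(channels, channels, rng, dtype=dtype)
        self.Wo = Dense(channels, channels, rng, zero_init=True, dtype=dtype)

    def params(self):
        ps = self.norm.params()
        for lin in (self.Wq, self.Wk, self.Wv, self.Wo):
            ps += lin.params()
        return ps

    def forward(self, x):
        f, c, h, w = x.shape
        self._inshape = x.shape
        xn = self.norm.forward(x)
        seq = xn.transpose(2, 3, 0, 1).reshape(h * w, f, c)  # (P, F, C)
        q = self.Wq.forward(seq)
        k = self.Wk.forward(seq)
        v = self.Wv.forward(seq)
        logits = q @ k.transpose(0, 2, 1) / np.sqrt(c)
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        a = e / e.sum(axis=-1, keepdims=True)
        o = a @ v
        y = self.Wo.forward(o)
        self._cache = (q, k, v, a)
        return x + y.reshape(h, w, f, c).transpose(2, 3, 0, 1)

    def backward(self, dy):
        f, c, h, w = self._inshape
        q, k, v, a = self._cache
        dyseq = dy.transpose(2, 3, 0, 1).reshape(h * w, f, c)
        do = self.Wo.backward(dyseq)
        da = do @ v.transpose(0, 2, 1)
        dv = a.transpose(0, 2, 1) @ do
        dlogits = a * (da - (da * a).sum(axis=-1, keepdims=True))
        dq = dlogits @ k / np.sqrt(c)
        dk = dlogits.transpose(0, 2, 1) @ q / np.sqrt(c)
        dseq = self.Wq.backward(dq) + self.Wk.backward(dk) + self.Wv.backward(dv)
        dxn = dseq.reshape(h, w, f, c).transpose(2, 3, 0, 1)
        return dy + self.norm.backward(dxn)


class ResBlock(Layer):
    """GN-SiLU-Conv, FiLM(noise emb), GN-SiLU-Conv with additive skip."""

    def __init__(self, cin, cout, emb_dim, rng, groups=8, dtype=np.float64,
                 recompute=False):
        g1 = _groups_for(cin, groups)
        g2 = _groups_for(cout, groups)
        self.gn1 = GroupNorm(g1, cin, dtype=dtype)
        self.act1 = SiLU()
        self.conv1 = Conv2d(cin, cout, 3, rng, dtype=dtype, recompute=recompute)
        self.film = FiLM(emb_dim, cout, rng, dtype=dtype)
        self.gn2 = GroupNorm(g2, cout, dtype=dtype)
        self.act2 = SiLU()
        self.conv2 = Conv2d(cout, cout, 3, rng, zero_init=True, dtype=dtype,
                            recompute=recompute)
        self.skip = None
        if cin != cout:
            self.skip = Conv2d(cin, cout, 1, rng, dtype=dtype)

    def params(self):
        ps = []
        for lyr in (self.gn1, self.conv1, self.film, self.gn2, self.conv2):
            ps += lyr.params()
        if self.skip is not None:
            ps += self.skip.params()
        return ps

    def forward(self, x, emb):
        h = self.conv1.forward(self.act1.forward(self.gn1.forward(x)))
        h = self.film.forward(h, emb)
        h = self.conv2.forward(self.act2.forward(self.gn2.forward(h)))
        s = x if self.skip is None else self.skip.forward(x)
        return s + h

    def backward(self, dy):
        dh = self.gn2.backward(self.act2.backward(self.conv2.backward(dy)))
        dh = self.film.backward(dh)
        dx = self.gn1.backward(self.act1.backward(self.conv1.backward(dh)))
        ds = dy if self.skip is None else self.skip.backward(dy)
        return dx + ds


def sinusoidal_embedding(log_sigma: float, dim: int) -> np.ndarray:
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(1000.0), half))
    ang = log_sigma * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)])


class ScoreUNet(Layer):
    """2D+t U-Net predicting the noise ε̂(x_σ, σ) for a clip (F, 2, H, W).

    ``temporal=False`` removes every temporal-attention layer, giving the
    per-frame 2D baseline with an identical parameter count to a 2D model;
    frames then never interact.  Addition-based skip connections keep the
    backward pass simple.  Spatial sizes must be divisible by
    2**(levels - 1); any frame count >= 1 is accepted.
    """

    def __init__(self, in_ch=2, base=16, mults=(1, 2), emb_dim=32,
                 temporal=True, seed=0, dtype=np.float64, recompute=False):
        rng = np.random.default_rng(seed)
        self.in_ch, self.base, self.mults = in_ch, base, tuple(mults)
        self.emb_dim, self.temporal = emb_dim, temporal
        self.dtype = dtype
        chans = [base * m for m in mults]
        self.chans = chans
        self.emb1 = Dense(emb_dim, emb_dim, rng, dtype=dtype)
        self.emb_act = SiLU()
        self.emb2 = Dense(emb_dim, emb_dim, rng, dtype=dtype)
        self.stem = Conv2d(in_ch, chans[0], 3, rng, dtype=dtype, recompute=recompute)

        self.down_blocks, self.down_attn, self.pools = [], [], []
        cprev = chans[0]
        for i, ch in enumerate(chans):
            self.down_blocks.append(
                ResBlock(cprev, ch, emb_dim, rng, dtype=dtype, recompute=recompute)
            )
            self.down_attn.append(
                TemporalAttention(ch, rng, dtype=dtype) if temporal else None
            )
            if i < len(chans) - 1:
                self.pools.append(AvgPool2())
            cprev = ch
        self.mid = ResBlock(cprev, cprev, emb_dim, rng, dtype=dtype, recompute=recompute)
        self.mid_attn = TemporalAttention(cprev, rng, dtype=dtype) if temporal else None

        self.ups, self.lateral, self.up_blocks, self.up_attn = [], [], [], []
        for i in range(len(chans) - 2, -1, -1):
            self.ups.append(NearestUp2())
            self.lateral.append(Conv2d(chans[i + 1], chans[i], 1, rng, dtype=dtype))
            self.up_blocks.append(
                ResBlock(chans[i], chans[i], emb_dim, rng, dtype=dtype,
                         recompute=recompute)
            )
            self.up_attn.append(
                TemporalAttention(chans[i], rng, dtype=dtype) if temporal else None
            )
        self.out_norm = GroupNorm(min(8, chans[0]), chans[0], dtype=dtype)
        self.out_act = SiLU()
        self.out_conv = Conv2d(chans[0], in_ch, 3, rng, zero_init=True, dtype=dtype,
                               recompute=recompute)

    # ------------------------------------------------------------------
    def _layers(self):
        ls = [self.emb1, self.emb2, self.stem]
        ls += self.down_blocks + [a for a in self.down_attn if a]
        ls += [self.mid] + ([self.mid_attn] if self.mid_attn else [])
        ls += self.lateral + self.up_blocks + [a for a in self.up_attn if a]
        ls += [self.out_norm, self.out_conv]
        return ls

    def params(self):
        ps = []
        for lyr in self._layers():
            ps += lyr.params()
        return ps

    def downsample_factor(self) -> int:
        return 2 ** (len(self.chans) - 1)

    def forward(self, x: np.ndarray, sigma: float) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.in_ch:
            raise ValueError("expected input of shape (F, C, H, W)")
        f = self.downsample_factor()
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"spatial size must be divisible by {f}; pad to the next multiple"
            )
        emb = sinusoidal_embedding(float(np.log(sigma)), self.emb_dim).astype(self.dtype)
        emb = self.emb2.forward(self.emb_act.forward(self.emb1.forward(emb)))
        self._emb = emb

        h = self.stem.forward(x)
        skips = []
        for i, blk in enumerate(self.down_blocks):
            h = blk.forward(h, emb)
            if self.down_attn[i] is not None:
                h = self.down_attn[i].forward(h)
            skips.append(h)
            if i < len(self.pools):
                h = self.pools[i].forward(h)
        h = self.mid.forward(h, emb)
        if self.mid_attn is not None:
            h = self.mid_attn.forward(h)
        for j in range(len(self.up_blocks)):
            h = self.lateral[j].forward(self.ups[j].forward(h))
            h = h + skips[len(self.chans) - 2 - j]
            h = self.up_blocks[j].forward(h, self._emb)
            if self.up_attn[j] is not None:
                h = self.up_attn[j].forward(h)
        return self.out_conv.forward(self.out_act.forward(self.out_norm.forward(h)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.out_norm.backward(self.out_act.backward(self.out_conv.backward(dy)))
        dskips = [None] * len(self.chans)
        for j in range(len(self.up_blocks) - 1, -1, -1):
            if self.up_attn[j] is not None:
                dh = self.up_attn[j].backward(dh)
            dh = self.up_blocks[j].backward(dh)
            idx = len(self.chans) - 2 - j
            dskips[idx] = dh.copy()
            dh = self.ups[j].backward(self.lateral[j].backward(dh))
        if self.mid_attn is not None:
            dh = self.mid_attn.backward(dh)
        dh = self.mid.backward(dh)
        for i in range(len(self.down_blocks) - 1, -1, -1):
            if i < len(self.pools):
                dh = self.pools[i].backward(dh)
            if dskips[i] is not None:
                dh = dh + dskips[i]
            if self.down_attn[i] is not None:
                dh = self.down_attn[i].backward(dh)
            dh = self.down_blocks[i].backward(dh)
        dx = self.stem.backward(dh)
        # propagate noise-embedding gradients through the shared MLP
        demb = 0.0
        for blk in self.down_blocks + [self.mid] + self.up_blocks:
            demb = demb + blk.film._demb
        self.emb1.backward(self.emb_act.backward(self.emb2.backward(demb)))
        return dx

    # ------------------------------------------------------------------
    def get_weights(self) -> list:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list) -> None:
        ps = self.params()
        if len(ps) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(ps, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value[...] = w

    def config_dict(self) -> dict:
        return {
            "in_ch": self.in_ch,
            "base": self.base,
            "mults": list(self.mults),
            "emb_dim": self.emb_dim,
            "temporal": self.temporal,
            "dtype": np.dtype(self.dtype).name,
        }


class Adam:
    def __init__(self, params: list, lr=2e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
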