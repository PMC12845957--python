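"""Minimal feed-forward network stack in numpy.

Implements exactly the layer set the two classifier architectures need:
convolution (im2col + GEMM), max pooling, batch/layer normalization,
dropout, dense layers, multi-head self-attention and an AdamW optimizer.
All math is float32; layers follow the NHWC / (batch, tokens, embed)
conventions.  Each layer caches what its backward pass needs, so the usage
pattern is strictly forward-then-backward per batch.

Weight initialization is Glorot-uniform from a caller-supplied generator;
two builds from the same seed produce identical weights.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

F32 = np.float32


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state that checkpoints must capture (e.g. BN stats)."""
        return []

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


# ---------------------------------------------------------------------------
# dense / activations
# ---------------------------------------------------------------------------

class Dense(Layer):
    """Affine map over the last axis (leading axes are flattened for GEMM)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Parameter(glorot_uniform(rng, (n_in, n_out), n_in, n_out), "dense/w")
        self.b = Parameter(np.zeros(n_out), "dense/b")

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        self._x2 = x.reshape(-1, x.shape[-1])
        y = self._x2 @ self.w.value + self.b.value
        return y.reshape(*x.shape[:-1], self.w.value.shape[1])

    def backward(self, dy):
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.w.grad += self._x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dx = dy2 @ self.w.value.T
        return dx.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Tanh(Layer):
    def forward(self, x, training=False, rng=None):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class GELU(Layer):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x, training=False, rng=None):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0, dtype=F32)))
        return (x * self._cdf).astype(F32)

    def backward(self, dy):
        pdf = np.exp(-0.5 * self._x**2) * F32(1.0 / math.sqrt(2.0 * math.pi))
        return (dy * (self._cdf + self._x * pdf)).astype(F32)


class Softmax(Layer):
    """Row softmax over the last axis (the model's probability head)."""

    def forward(self, x, training=False, rng=None):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(np.maximum(z, -60.0))
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, dy):
        dot = (dy * self._p).sum(axis=-1, keepdims=True)
        return self._p * (dy - dot)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = rng.random(x.shape, dtype=np.float32) >= self.rate
        self._mask = keep.astype(F32) / F32(1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


# ---------------------------------------------------------------------------
# convolution / pooling / batch norm (NHWC)
# ---------------------------------------------------------------------------

class Conv2D(Layer):
    """Stride-1 cross-correlation with 'same' padding.

    Computed one kernel *row* at a time: for row i the window over
    ``(width offset, channel)`` is contiguous in NHWC memory, so the im2col
    copy is cheap and the GEMM contraction axis is ``kw * c_in``.  The
    padded input is cached and the row columns are re-derived in backward
    (trading a little recompute for a much smaller activation footprint).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kh = self.kw = kernel
        fan_in = kernel * kernel * c_in
        self.w = Parameter(
            glorot_uniform(rng, (kernel, kernel, c_in, c_out), fan_in, kernel * kernel * c_out),
            "conv/w",
        )
        self.b = Parameter(np.zeros(c_out), "conv/b")

    def parameters(self):
        return [self.w, self.b]

    def _row_col(self, xp, i, h, w, c):
        """(n, h, w, kw*c) windows for kernel row i, contiguous for GEMM."""
        xi = xp[:, i : i + h, :, :]
        win = sliding_window_view(xi.reshape(xi.shape[0], h, -1), self.kw * c, axis=2)[:, :, :: c]
        return np.ascontiguousarray(win[:, :, :w, :])

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        self._in_shape = x.shape
        pt, pl = (self.kh - 1) // 2, (self.kw - 1) // 2
        pb, pr = self.kh - 1 - pt, self.kw - 1 - pl
        self._pads = (pt, pb, pl, pr)
        self._xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))).astype(F32, copy=False)
        y = np.empty((n * h * w, self.w.value.shape[-1]), dtype=F32)
        y[:] = self.b.value
        for i in range(self.kh):
            col = self._row_col(self._xp, i, h, w, c).reshape(n * h * w, self.kw * c)
            y += col @ self.w.value[i].reshape(self.kw * c, -1)
        return y.reshape(n, h, w, -1)

    def backward(self, dy, need_dx: bool = True):
        n, h, w, f = dy.shape
        c = self._in_shape[3]
        dy2 = dy.reshape(-1, f)
        self.b.grad += dy2.sum(axis=0)
        pt, pb, pl, pr = self._pads
        dxp = np.zeros_like(self._xp) if need_dx else None
        for i in range(self.kh):
            col = self._row_col(self._xp, i, h, w, c).reshape(n * h * w, self.kw * c)
            self.w.grad[i] += (col.T @ dy2).reshape(self.kw, c, f)
            if not need_dx:
                continue
            dcol = (dy2 @ self.w.value[i].reshape(self.kw * c, f).T).reshape(n, h, w, self.kw, c)
            for j in range(self.kw):
                dxp[:, i : i + h, j : j + w, :] += dcol[:, :, :, j, :]
        if not need_dx:
            return None
        return dxp[:, pt : pt + h, pl : pl + w, :]


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        quads = (
            x[:, 0 : h2 * 2 : 2, 0 : w2 * 2 : 2, :],
            x[:, 0 : h2 * 2 : 2, 1 : w2 * 2 : 2, :],
            x[:, 1 : h2 * 2 : 2, 0 : w2 * 2 : 2, :],
            x[:, 1 : h2 * 2 : 2, 1 : w2 * 2 : 2, :],
        )
        out = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        # route gradient to the first position attaining the max (tie-break)
        masks = []
        taken = np.zeros(out.shape, dtype=bool)
        for q in quads:
            m = (q == out) & ~taken
            taken |= m
            masks.append(m)
        self._masks = masks
        return out

    def backward(self, dy):
        n, h2, w2, c = dy.shape
        dx = np.zeros(self._in_shape, dtype=F32)
        slices = ((0, 0), (0, 1), (1, 0), (1, 1))
        for (di, dj), m in zip(slices, self._masks):
            dx[:, di : h2 * 2 : 2, dj : w2 * 2 : 2, :] += dy * m
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization (channels on the last axis).

    The running-statistics momentum defaults to 0.9 so the inference
    statistics converge within the few hundred optimizer steps of a
    CPU-scale run; a slower 0.99 decay needs thousands of steps before the
    running mean/variance reflect the data.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = Parameter(np.ones(channels), "bn/gamma")
        self.beta = Parameter(np.zeros(channels), "bn/beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._refresh = False

    def parameters(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def start_refresh(self) -> None:
        """Begin exact re-estimation of the inference statistics."""
        self._refresh = True
        self._acc_n = 0
        self._acc_sum = np.zeros_like(self.running_mean, dtype=np.float64)
        self._acc_sumsq = np.zeros_like(self.running_var, dtype=np.float64)

    def finish_refresh(self) -> None:
        mean = self._acc_sum / max(self._acc_n, 1)
        var = self._acc_sumsq / max(self._acc_n, 1) - mean**2
        self.running_mean[...] = mean.astype(F32)
        self.running_var[...] = np.maximum(var, 0.0).astype(F32)
        self._refresh = False

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if self._refresh:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self._acc_n += x.size // x.shape[-1]
            self._acc_sum += x.astype(np.float64).sum(axis=tuple(range(x.ndim - 1)))
            self._acc_sumsq += (x.astype(np.float64) ** 2).sum(axis=tuple(range(x.ndim - 1)))
        elif training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._invstd
        self._m = x.size // x.shape[-1]
        self._training = training
        return (self.gamma.value * self._xhat + self.beta.value).astype(F32)

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        if not self._training:
            return (dxhat * self._invstd).astype(F32)
        m = self._m
        term = m * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        return (self._invstd / m * term).astype(F32)


class LayerNorm(Layer):
    """Normalization over the last (embedding) axis with learned scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim), "ln/gamma")
        self.beta = Parameter(np.zeros(dim), "ln/beta")
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False, rng=None):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._invstd
        return (self.gamma.value * self._xhat + self.beta.value).astype(F32)

    def backward(self, dy):
        d = dy.shape[-1]
        self.gamma.grad += (dy * self._xhat).sum(axis=tuple(range(dy.ndim - 1)))
        self.beta.grad += dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gamma.value
        term = (
            d * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=-1, keepdims=True)
        )
        return (self._invstd / d * term).astype(F32)


# ---------------------------------------------------------------------------
# attention / ViT pieces
# ---------------------------------------------------------------------------

class MultiHeadAttention(Layer):
    """Self-attention over (batch, tokens, embed) with per-head key dim."""

    def __init__(
        self,
        embed_dim: int,
        n_heads: int,
        key_dim: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        self.h, self.dk = n_heads, key_dim
        inner = n_heads * key_dim
        self.wq = Parameter(glorot_uniform(rng, (embed_dim, inner), embed_dim, inner), "mha/wq")
        self.wk = Parameter(glorot_uniform(rng, (embed_dim, inner), embed_dim, inner), "mha/wk")
        self.wv = Parameter(glorot_uniform(rng, (embed_dim, inner), embed_dim, inner), "mha/wv")
        self.wo = Parameter(glorot_uniform(rng, (inner, embed_dim), inner, embed_dim), "mha/wo")
        self.bq = Parameter(np.zeros(inner), "mha/bq")
        self.bk = Parameter(np.zeros(inner), "mha/bk")
        self.bv = Parameter(np.zeros(inner), "mha/bv")
        self.bo = Parameter(np.zeros(embed_dim), "mha/bo")
        self.dropout = dropout

    def parameters(self):
        return [self.wq, self.wk, self.wv, self.wo, self.bq, self.bk, self.bv, self.bo]

    def _split(self, x):  # (n,t,h*dk) -> (n,h,t,dk)
        n, t, _ = x.shape
        return x.reshape(n, t, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (n,h,t,dk) -> (n,t,h*dk)
        n, h, t, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dk)

    def forward(self, x, training=False, rng=None):
        self._x = x
        q = self._split(x @ self.wq.value + self.bq.value)
        k = self._split(x @ self.wk.value + self.bk.value)
        v = self._split(x @ self.wv.value + self.bv.value)
        scale = F32(1.0 / math.sqrt(self.dk))  # keep the whole attention path float32
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        scores -= scores.max(axis=-1, keepdims=True)
        # clamp so exp never produces float32 subnormals (severe CPU slowdown)
        e = np.exp(np.maximum(scores, F32(-60.0)))
        attn = e / e.sum(axis=-1, keepdims=True)
        if training and self.dropout > 0.0:
            keep = rng.random(attn.shape, dtype=np.float32) >= self.dropout
            self._dropmask = keep.astype(F32) / F32(1.0 - self.dropout)
        else:
            self._dropmask = None
        attn_d = attn * self._dropmask if self._dropmask is not None else attn
        out = attn_d @ v
        merged = self._merge(out)
        self._cache = (q, k, v, attn, attn_d, merged, scale)
        return (merged @ self.wo.value + self.bo.value).astype(F32)

    def backward(self, dy):
        q, k, v, attn, attn_d, merged, scale = self._cache
        n, t, _ = dy.shape
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.wo.grad += merged.reshape(-1, merged.shape[-1]).T @ dy2
        self.bo.grad += dy2.sum(axis=0)
        dmerged = (dy @ self.wo.value.T).reshape(n, t, self.h, self.dk).transpose(0, 2, 1, 3)
        dattn_d = dmerged @ v.transpose(0, 1, 3, 2)
        dv = attn_d.transpose(0, 1, 3, 2) @ dmerged
        dattn = dattn_d * self._dropmask if self._dropmask is not None else dattn_d
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores *= scale
        dq = dscores @ k
        dk_ = dscores.transpose(0, 1, 3, 2) @ q
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dx = np.zeros_like(self._x)
        for grad_heads, wp, bp in ((dq, self.wq, self.bq), (dk_, self.wk, self.bk), (dv, self.wv, self.bv)):
            g2 = self._merge(grad_heads).reshape(-1, self.h * self.dk)
            wp.grad += x2.T @ g2
            bp.grad += g2.sum(axis=0)
            dx += (g2 @ wp.value.T).reshape(self._x.shape)
        return dx.astype(F32)


class PatchExtract(Layer):
    """Non-overlapping p x p patches in raster order, flattened to tokens.

    Remainder rows/columns that do not fill a whole patch are dropped
    (VALID-style tiling), e.g. 125x50 with p=8 -> 15x6 = 90 patches of
    length 8*8*3 = 192.
    """

    def __init__(self, patch: int = 8):
        self.p = patch

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        p = self.p
        gh, gw = h // p, w // p
        self._in_shape = x.shape
        xc = x[:, : gh * p, : gw * p, :]
        tokens = (
            xc.reshape(n, gh, p, gw, p, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, gh * gw, p * p * c)
        )
        return np.ascontiguousarray(tokens)

    def backward(self, dy):
        n, h, w, c = self._in_shape
        p = self.p
        gh, gw = h // p, w // p
        dx = np.zeros(self._in_shape, dtype=F32)
        dx[:, : gh * p, : gw * p, :] = (
            dy.reshape(n, gh, gw, p, p, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, gh * p, gw * p, c)
        )
        return dx


class PositionalEmbedding(Layer):
    """Learned additive embedding, one vector per token index."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(n_tokens, dim)), "pos")

    def parameters(self):
        return [self.pos]

    def forward(self, x, training=False, rng=None):
        self._n = x.shape[0]
        return (x + self.pos.value).astype(F32)

    def backward(self, dy):
        self.pos.grad += dy.sum(axis=0)
        return dy


class GlobalAveragePool1D(Layer):
    """Mean over the token axis: (n, t, e) -> (n, e)."""

    def forward(self, x, training=False, rng=None):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._t, axis=1) / self._t


class Residual(Layer):
    """y = x + inner(x), with `inner` a list of sub-layers."""

    def __init__(self, inner: list[Layer]):
        self.inner = inner

    def parameters(self):
        return [p for l in self.inner for p in l.parameters()]

    def buffers(self):
        return [b for l in self.inner for b in l.buffers()]

    def forward(self, x, training=False, rng=None):
        h = x
        for layer in self.inner:
            h = layer.forward(h, training=training, rng=rng)
        return (x + h).astype(F32)

    def backward(self, dy):
        dh = dy
        for layer in reversed(self.inner):
            dh = layer.backward(dh)
        return (dy + dh).astype(F32)


# ---------------------------------------------------------------------------
# model container, loss, optimizer
# ---------------------------------------------------------------------------

class Model:
    """A layer stack ending in Softmax; trains on logits, predicts probabilities."""

    def __init__(self, layers: list[Layer], name: str = "model"):
        if not isinstance(layers[-1], Softmax):
            raise ValueError("model must end with a Softmax layer")
        self.layers = layers
        self.name = name

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def forward_logits(self, x, training=False, rng=None):
        h = np.asarray(x, dtype=F32)
        for layer in self.layers[:-1]:
            h = layer.forward(h, training=training, rng=rng)
        return h

    def backward_from_logits(self, dlogits):
        dh = dlogits
        first = self.layers[0]
        for layer in reversed(self.layers[1:-1]):
            dh = layer.backward(dh)
        # the input gradient of the very first layer is never consumed
        if isinstance(first, Conv2D):
            return first.backward(dh, need_dx=False)
        if isinstance(first, PatchExtract):
            return None
        return first.backward(dh)

    def predict_proba(self, x):
        logits = self.forward_logits(x, training=False)
        return self.layers[-1].forward(logits)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def _batchnorms(self) -> list["BatchNorm"]:
        found = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                found.append(layer)
            elif isinstance(layer, Residual):
                found.extend(l for l in layer.inner if isinstance(l, BatchNorm))
        return found

    def refresh_batchnorm_stats(self, x, batch_size: int = 128, max_images: int = 1024) -> None:
        """Re-estimate BN inference statistics for the current weights.

        Running statistics collected under momentum lag whenever the run has
        few optimizer steps per epoch; a short exact pass (dropout off,
        batch statistics for normalization) recalibrates them, the same
        recipe weight-averaging methods use before evaluation.
        """
        bns = self._batchnorms()
        if not bns:
            return
        for bn in bns:
            bn.start_refresh()
        n = min(len(x), max_images)
        for i in range(0, n, batch_size):
            self.forward_logits(x[i : i + batch_size], training=False)
        for bn in bns:
            bn.finish_refresh()

    def _buffers(self) -> list[np.ndarray]:
        return [b for l in self.layers for b in l.buffers()]

    def get_weights(self) -> list[np.ndarray]:
        """Trainable parameters plus normalization buffers, in layer order."""
        return [p.value.copy() for p in self.parameters()] + [b.copy() for b in self._buffers()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        buffers = self._buffers()
        if len(weights) != len(params) + len(buffers):
            raise ValueError("weight list does not match this architecture")
        for p, w in zip(params, weights[: len(params)]):
            p.value[...] = w
        for b, w in zip(buffers, weights[len(params) :]):
            b[...] = w

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def summary(self) -> str:
        lines = [f"{self.name}: {self.n_parameters():,} parameters"]
        for layer in self.layers:
            n = sum(p.value.size for p in layer.parameters())
            lines.append(f"  {type(layer).__name__:<22s} params={n}")
        return "\n".join(lines)


def sparse_categorical_crossentropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and the gradient w.r.t. the logits (softmax folded in)."""
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    n = logits.shape[0]
    loss = float(np.mean(logsumexp - z[np.arange(n), labels]))
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    p[np.arange(n), labels] -= 1.0
    return loss, (p / n).astype(F32)


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(
        self,
        params: list[Parameter],
        weight_decay: float = 0.004,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = params
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.value -= lr * self.wd * p.value
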