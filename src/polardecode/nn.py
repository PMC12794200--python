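"""Minimal neural-network layer library with explicit backpropagation.

Implements exactly the layer set the EEG decoders need — 2-D and
depthwise convolutions, batch normalization, ELU/square/log activations,
average and max pooling, dropout, dense heads and stacked LSTMs — on
plain numpy arrays, together with an Adam optimizer and an MSE loss.
Every layer's backward pass is hand-derived and is verified against
finite differences in the test suite.

Conventions
-----------
* Feature maps are channels-last: ``(batch, height, width, features)``.
  EEG windows enter as ``(batch, n_electrodes, n_times, 1)``.
* All parameters and activations use :data:`DTYPE` (float32 by default;
  switch to float64 for gradient checking via :func:`set_dtype`).
* Determinism: parameter initialization and dropout draw from generators
  seeded explicitly, so a fixed seed reproduces training bit-for-bit.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Set the global parameter/activation dtype (float32 or float64)."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: stateless unless it holds :class:`Param` attributes."""

    def params(self) -> list[Param]:
        return [v for v in vars(self).values() if isinstance(v, Param)]

    def init(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _pad_amounts(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k - 1 - (k - 1) // 2


class Conv2d(Layer):
    """2-D convolution, stride 1, 'valid' or 'same' padding.

    Weights are ``(kh, kw, in_features, out_features)``.  Forward and
    backward run as one BLAS GEMM per batch chunk over an im2col buffer;
    chunking keeps the buffer near :data:`COL_BUFFER_FLOATS` elements, so
    peak memory stays bounded regardless of batch size.
    """

    COL_BUFFER_FLOATS = 2 ** 24  # ~64 MB at float32

    def __init__(self, in_f: int, out_f: int, kernel: tuple[int, int],
                 padding: str = "valid", bias: bool = True):
        self.in_f, self.out_f = in_f, out_f
        self.kh, self.kw = kernel
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.padding = padding
        self.w = Param(np.zeros((self.kh, self.kw, in_f, out_f)))
        self.b = Param(np.zeros(out_f)) if bias else None

    def init(self, rng):
        fan_in = self.kh * self.kw * self.in_f
        fan_out = self.kh * self.kw * self.out_f
        self.w.data = glorot_uniform(rng, self.w.data.shape, fan_in, fan_out).astype(DTYPE)

    def _pad(self, x):
        if self.padding == "valid":
            return x, (0, 0, 0, 0)
        ph0, ph1 = _pad_amounts(self.kh)
        pw0, pw1 = _pad_amounts(self.kw)
        return np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0))), (ph0, ph1, pw0, pw1)

    def _im2col(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        """(bs, H, W, C) -> (bs*oh*ow, kh*kw*C) patch matrix (one copy)."""
        bs = xp.shape[0]
        s0, sh, sw, sc = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, (bs, oh, ow, self.kh, self.kw, self.in_f),
            (s0, sh, sw, sh, sw, sc), writeable=False)
        return np.ascontiguousarray(view).reshape(bs * oh * ow, -1)

    def _chunk(self, oh: int, ow: int) -> int:
        per_item = oh * ow * self.kh * self.kw * self.in_f
        return max(1, self.COL_BUFFER_FLOATS // max(per_item, 1))

    @property
    def _use_fft(self) -> bool:
        # wide time-axis kernels on a single input feature: FFT beats im2col
        return self.kh == 1 and self.in_f == 1 and self.kw >= 25

    def forward(self, x, training=False):
        xp, pads = self._pad(np.asarray(x, dtype=DTYPE))
        self._xp, self._pads, self._in_shape = xp, pads, x.shape
        B, H, W, _ = xp.shape
        oh, ow = H - self.kh + 1, W - self.kw + 1
        self._out_hw = (oh, ow)
        if self._use_fft:
            out = self._forward_fft(xp, ow)
        else:
            w2 = self.w.data.reshape(-1, self.out_f)
            out = np.empty((B, oh, ow, self.out_f), dtype=DTYPE)
            step = self._chunk(oh, ow)
            for b0 in range(0, B, step):
                xb = xp[b0:b0 + step]
                col = self._im2col(xb, oh, ow)
                out[b0:b0 + step] = (col @ w2).reshape(xb.shape[0], oh, ow, self.out_f)
        if self.b is not None:
            out += self.b.data
        return out

    def backward(self, grad):
        grad = np.asarray(grad, dtype=DTYPE)
        oh, ow = self._out_hw
        xp = self._xp
        if self._use_fft:
            dxp = self._backward_fft(grad, ow)
        else:
            w2 = self.w.data.reshape(-1, self.out_f)
            dw2 = np.zeros_like(w2)
            dxp = np.zeros_like(xp)
            step = self._chunk(oh, ow)
            for b0 in range(0, len(xp), step):
                xb = xp[b0:b0 + step]
                bs = xb.shape[0]
                g2 = grad[b0:b0 + step].reshape(bs * oh * ow, self.out_f)
                col = self._im2col(xb, oh, ow)  # recomputed: not cached, saves memory
                dw2 += col.T @ g2
                dcol = (g2 @ w2.T).reshape(bs, oh, ow, self.kh, self.kw, self.in_f)
                db = dxp[b0:b0 + step]
                for u in range(self.kh):
                    for v in range(self.kw):
                        db[:, u:u + oh, v:v + ow, :] += dcol[:, :, :, u, v, :]
            self.w.grad += dw2.reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 1, 2))
        ph0, ph1, pw0, pw1 = self._pads
        _, H, W, _ = self._in_shape
        return dxp[:, ph0:ph0 + H, pw0:pw0 + W, :]

    # -- FFT path (kh == 1, in_f == 1): correlation via the frequency domain

    def _fft_plan(self, wp: int):
        from scipy.fft import next_fast_len

        # n >= padded width covers forward correlation, dw and dx without wrap
        return next_fast_len(wp)

    def _forward_fft(self, xp: np.ndarray, ow: int) -> np.ndarray:
        from scipy.fft import irfft, rfft

        B, H, wp, _ = xp.shape
        n = self._fft_plan(wp)
        xf = rfft(xp[..., 0], n=n, axis=2)              # (B, H, F)
        wf = rfft(self.w.data[0, :, 0, :], n=n, axis=0)  # (F, O)
        self._xf, self._wf, self._nfft = xf, wf, n
        wfc = np.conj(wf)
        out = np.empty((B, H, ow, self.out_f), dtype=DTYPE)
        step = max(1, self.COL_BUFFER_FLOATS // (H * n * self.out_f * 2))
        for b0 in range(0, B, step):
            prod = xf[b0:b0 + step, :, :, None] * wfc    # (bs, H, F, O)
            out[b0:b0 + step] = irfft(prod, n=n, axis=2)[:, :, :ow, :]
        return out

    def _backward_fft(self, grad: np.ndarray, ow: int) -> np.ndarray:
        from scipy.fft import irfft, rfft

        xf, wf, n = self._xf, self._wf, self._nfft
        B, H, wp, _ = self._xp.shape
        dwf = np.zeros((xf.shape[-1], self.out_f), dtype=xf.dtype)
        dxp = np.empty((B, H, wp, 1), dtype=DTYPE)
        step = max(1, self.COL_BUFFER_FLOATS // (H * n * self.out_f * 2))
        for b0 in range(0, B, step):
            gf = rfft(grad[b0:b0 + step], n=n, axis=2)   # (bs, H, F, O)
            # dw[v, o] = sum_{b,h,t} x[t+v] g[t]  (correlation with the gradient)
            dwf += np.einsum("bhf,bhfo->fo", xf[b0:b0 + step], np.conj(gf))
            # dx[s] = sum_{t} g[t] w[s - t]  (plain convolution)
            dxf = np.einsum("bhfo,fo->bhf", gf, wf)
            dxp[b0:b0 + step, :, :, 0] = irfft(dxf, n=n, axis=2)[:, :, :wp]
        dw = irfft(dwf, n=n, axis=0)[: self.kw, :]
        self.w.grad += dw.reshape(self.w.data.shape).astype(DTYPE)
        return dxp


class DepthwiseConv2d(Layer):
    """Depthwise 2-D convolution with a channel multiplier.

    Weights are ``(kh, kw, in_features, mult)``; output features are
    ordered ``(in_feature, mult)`` flattened, matching the usual
    depthwise convention.
    """

    def __init__(self, in_f: int, mult: int, kernel: tuple[int, int],
                 padding: str = "valid", bias: bool = False):
        self.in_f, self.mult = in_f, mult
        self.kh, self.kw = kernel
        self.padding = padding
        self.w = Param(np.zeros((self.kh, self.kw, in_f, mult)))
        self.b = Param(np.zeros(in_f * mult)) if bias else None

    def init(self, rng):
        fan_in = self.kh * self.kw
        fan_out = self.kh * self.kw * self.mult
        self.w.data = glorot_uniform(rng, self.w.data.shape, fan_in, fan_out).astype(DTYPE)

    def _pad(self, x):
        if self.padding == "valid":
            return x, (0, 0, 0, 0)
        ph0, ph1 = _pad_amounts(self.kh)
        pw0, pw1 = _pad_amounts(self.kw)
        return np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0))), (ph0, ph1, pw0, pw1)

    def _spatial_case(self, oh: int) -> bool:
        # full-height spatial filter (kw == 1, output height 1): one einsum
        return self.kw == 1 and oh == 1

    def forward(self, x, training=False):
        xp, pads = self._pad(np.asarray(x, dtype=DTYPE))
        self._xp, self._pads, self._in_shape = xp, pads, x.shape
        B, H, W, C = xp.shape
        oh, ow = H - self.kh + 1, W - self.kw + 1
        self._out_hw = (oh, ow)
        if self._spatial_case(oh):
            out = np.einsum("buwc,ucm->bwcm", xp, self.w.data[:, 0],
                            optimize=True)[:, None]
            out = np.ascontiguousarray(out, dtype=DTYPE)
        else:
            out = np.zeros((B, oh, ow, C, self.mult), dtype=DTYPE)
            for u in range(self.kh):
                for v in range(self.kw):
                    out += xp[:, u:u + oh, v:v + ow, :, None] * self.w.data[u, v]
        out = out.reshape(B, oh, ow, C * self.mult)
        if self.b is not None:
            out += self.b.data
        return out

    def backward(self, grad):
        grad = np.asarray(grad, dtype=DTYPE)
        oh, ow = self._out_hw
        xp = self._xp
        B = xp.shape[0]
        g5 = grad.reshape(B, oh, ow, self.in_f, self.mult)
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 1, 2))
        if self._spatial_case(oh):
            g4 = g5[:, 0]
            self.w.grad[:, 0] += np.einsum("buwc,bwcm->ucm", xp, g4, optimize=True)
            dxp = np.ascontiguousarray(
                np.einsum("bwcm,ucm->buwc", g4, self.w.data[:, 0], optimize=True),
                dtype=DTYPE)
            ph0, ph1, pw0, pw1 = self._pads
            _, H, W, _ = self._in_shape
            return dxp[:, ph0:ph0 + H, pw0:pw0 + W, :]
        dxp = np.zeros_like(xp)
        for u in range(self.kh):
            for v in range(self.kw):
                xs = xp[:, u:u + oh, v:v + ow, :]
                self.w.grad[u, v] += np.einsum("bijc,bijcm->cm", xs, g5)
                dxp[:, u:u + oh, v:v + ow, :] += (g5 * self.w.data[u, v]).sum(axis=-1)
        ph0, ph1, pw0, pw1 = self._pads
        _, H, W, _ = self._in_shape
        return dxp[:, ph0:ph0 + H, pw0:pw0 + W, :]


class FusedTemporalSpatial(Layer):
    """Temporal conv (shared per feature) + depthwise spatial filter, fused.

    Computes ``z[b, f*M+m, t] = sum_h spat[h, f, m] * (x[b, h] * kern[:, f])``
    for input ``(B, n_elec, T)``, emitting ``(B, 1, T, F*M)``.  Because both
    operations are linear and the temporal kernel does not depend on the
    electrode, the electrode collapse can be applied *first*, which shrinks
    the temporal convolution by the electrode count.  A batch-norm layer
    between the two stages would be inert here: its per-feature affine is
    absorbed exactly by the batch norm that follows the fused block, so the
    loss surface (and all gradients) are unchanged by fusing — verified
    numerically in the tests.  Temporal padding is 'same'; no biases
    (matching the convention of the surrounding architecture).
    """

    def __init__(self, n_elec: int, n_filters: int, mult: int, k_temp: int):
        self.n_elec, self.f, self.mult, self.kw = n_elec, n_filters, mult, k_temp
        self.kern = Param(np.zeros((k_temp, n_filters)))
        self.spat = Param(np.zeros((n_elec, n_filters, mult)))

    def init(self, rng):
        # match the initializers of the unfused conv pair
        self.kern.data = glorot_uniform(rng, (self.kw, self.f),
                                        self.kw, self.kw * self.f).astype(DTYPE)
        self.spat.data = glorot_uniform(rng, (self.n_elec, self.f, self.mult),
                                        self.n_elec,
                                        self.n_elec * self.mult).astype(DTYPE)

    def _fft_len(self, wp: int) -> int:
        from scipy.fft import next_fast_len

        return next_fast_len(wp)

    def forward(self, x, training=False):
        from scipy.fft import irfft, rfft

        x = np.asarray(x, dtype=DTYPE)
        B, H, W = x.shape
        self._x = x
        # electrode collapse: (B, H, W) x (H, F, M) -> (B, F, M, W)
        y = np.einsum("bhw,hfm->bfmw", x, self.spat.data, optimize=True)
        p0, p1 = _pad_amounts(self.kw)
        yp = np.pad(y, ((0, 0), (0, 0), (0, 0), (p0, p1)))
        n = self._fft_len(W + self.kw - 1)
        yf = rfft(yp, n=n, axis=3)                    # (B, F, M, Fr)
        kf = rfft(self.kern.data, n=n, axis=0)        # (Fr, F)
        self._yf, self._kf, self._n, self._pads = yf, kf, n, (p0, p1)
        out = irfft(yf * np.conj(kf.T)[None, :, None, :], n=n, axis=3)[..., :W]
        out = np.ascontiguousarray(out, dtype=DTYPE)  # (B, F, M, W)
        return out.reshape(B, self.f * self.mult, W).transpose(0, 2, 1)[:, None]

    def backward(self, grad):
        from scipy.fft import irfft, rfft

        x = self._x
        B, H, W = x.shape
        yf, kf, n = self._yf, self._kf, self._n
        p0, p1 = self._pads
        g = np.asarray(grad, dtype=DTYPE)[:, 0].transpose(0, 2, 1)  # (B, FM, W)
        g = g.reshape(B, self.f, self.mult, W)
        gf = rfft(g, n=n, axis=3)                     # (B, F, M, Fr)
        # dkern[v, f] = sum_{b,m,t} g[t] y[t+v]  (correlation)
        dkf = np.einsum("bfmr,bfmr->rf", yf, np.conj(gf))
        self.kern.grad += irfft(dkf, n=n, axis=0)[: self.kw].astype(DTYPE)
        # dy = g convolved with kern (adjoint of correlation)
        dyf = gf * kf.T[None, :, None, :]
        dyp = irfft(dyf, n=n, axis=3)[..., : W + self.kw - 1]
        dy = dyp[..., p0 : p0 + W].astype(DTYPE)      # (B, F, M, W)
        self.spat.grad += np.einsum("bhw,bfmw->hfm", x, dy, optimize=True)
        return np.einsum("bfmw,hfm->bhw", dy, self.spat.data, optimize=True)


# ---------------------------------------------------------------------------
# normalization, activations, regularization
# ---------------------------------------------------------------------------

class BatchNorm(Layer):
    """Batch normalization over all axes except the last (features).

    Training-mode statistics and gradients are computed through fused
    two-term affine passes (``x * a + b``) and single-pass einsum
    reductions, avoiding large temporaries on wide feature maps.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        c = x.shape[-1]
        x2 = x.reshape(-1, c)
        if training:
            mu = x2.mean(axis=0)
            sq = np.einsum("nc,nc->c", x2, x2) / x2.shape[0]
            var = np.maximum(sq - mu * mu, 0.0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        self._x, self._mu, self._inv = x, mu.astype(DTYPE), inv.astype(DTYPE)
        self._training = training
        a = (self.gamma.data * inv).astype(DTYPE)
        b = (self.beta.data - mu * a).astype(DTYPE)
        out = x * a
        out += b
        return out

    def backward(self, grad):
        grad = np.asarray(grad, dtype=DTYPE)
        x, mu, inv = self._x, self._mu, self._inv
        c = x.shape[-1]
        g2 = grad.reshape(-1, c)
        x2 = x.reshape(-1, c)
        n = g2.shape[0]
        dbeta = g2.sum(axis=0)
        # dgamma = sum(g * xhat) without materializing xhat
        gx = np.einsum("nc,nc->c", g2, x2)
        dgamma = (gx - mu * dbeta) * inv
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        a = (self.gamma.data * inv).astype(DTYPE)
        if not self._training:
            # running statistics are constants w.r.t. the input
            return grad * a
        c2 = (-a * dgamma * inv / n).astype(DTYPE)
        c3 = (-a * dbeta / n - c2 * mu).astype(DTYPE)
        dx = grad * a
        dx += x * c2
        dx += c3
        return dx


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        out = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._out, self._pos = out, x > 0
        return out

    def backward(self, grad):
        return grad * np.where(self._pos, 1.0, self._out + self.alpha).astype(DTYPE)


class Square(Layer):
    def forward(self, x, training=False):
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x ** 2

    def backward(self, grad):
        return 2.0 * self._x * grad


class SafeLog(Layer):
    """log(max(x, eps)) — the log-variance nonlinearity of the shallow net."""

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def forward(self, x, training=False):
        self._xc = np.maximum(np.asarray(x, dtype=DTYPE), self.eps)
        return np.log(self._xc)

    def backward(self, grad):
        return grad / self._xc


class Dropout(Layer):
    """Inverted dropout; draws from the model's generator during training."""

    def __init__(self, p: float):
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        if not training or self.p <= 0:
            self._mask = None
            return x
        rng = self.rng or np.random.default_rng(0)
        self._mask = (rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


# ---------------------------------------------------------------------------
# pooling and shape
# ---------------------------------------------------------------------------

class AvgPoolW(Layer):
    """Average pooling along the width (time) axis; supports overlap."""

    def __init__(self, pool: int, stride: int | None = None):
        self.pool = pool
        self.stride = stride or pool

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        B, H, W, C = x.shape
        ow = (W - self.pool) // self.stride + 1
        if ow < 1:
            raise ValueError(f"pool {self.pool} exceeds width {W}")
        starts = np.arange(ow) * self.stride
        out = np.zeros((B, H, ow, C), dtype=DTYPE)
        for j in range(self.pool):
            out += x[:, :, starts + j, :]
        self._in_shape, self._starts = x.shape, starts
        return out / self.pool

    def backward(self, grad):
        grad = np.asarray(grad, dtype=DTYPE) / self.pool
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for j in range(self.pool):
            dx[:, :, self._starts + j, :] += grad
        return dx


class MaxPoolW(Layer):
    """Non-overlapping max pooling along the width (time) axis."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        B, H, W, C = x.shape
        ow = W // self.pool
        if ow < 1:
            raise ValueError(f"pool {self.pool} exceeds width {W}")
        self._in_shape = x.shape
        xr = x[:, :, : ow * self.pool, :].reshape(B, H, ow, self.pool, C)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad):
        B, H, W, C = self._in_shape
        ow = W // self.pool
        dxr = np.zeros((B, H, ow, self.pool, C), dtype=DTYPE)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :],
                          np.asarray(grad, dtype=DTYPE)[:, :, :, None, :], axis=3)
        dx = np.zeros((B, H, W, C), dtype=DTYPE)
        dx[:, :, : ow * self.pool, :] = dxr.reshape(B, H, ow * self.pool, C)
        return dx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return np.asarray(x, dtype=DTYPE).reshape(x.shape[0], -1)

    def backward(self, grad):
        return np.asarray(grad, dtype=DTYPE).reshape(self._shape)


class ToSequence(Layer):
    """(B, H, W, C) -> (B, W, H*C): time becomes the sequence axis."""

    def forward(self, x, training=False):
        self._shape = x.shape
        B, H, W, C = x.shape
        return np.ascontiguousarray(
            np.asarray(x, dtype=DTYPE).transpose(0, 2, 1, 3)
        ).reshape(B, W, H * C)

    def backward(self, grad):
        B, H, W, C = self._shape
        return np.asarray(grad, dtype=DTYPE).reshape(B, W, H, C).transpose(0, 2, 1, 3)


# ---------------------------------------------------------------------------
# dense and recurrent
# ---------------------------------------------------------------------------

class Dense(Layer):
    def __init__(self, in_f: int, out_f: int):
        self.in_f, self.out_f = in_f, out_f
        self.w = Param(np.zeros((in_f, out_f)))
        self.b = Param(np.zeros(out_f))

    def init(self, rng):
        self.w.data = glorot_uniform(rng, (self.in_f, self.out_f),
                                     self.in_f, self.out_f).astype(DTYPE)

    def forward(self, x, training=False):
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x @ self.w.data + self.b.data

    def backward(self, grad):
        grad = np.asarray(grad, dtype=DTYPE)
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.data.T


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Single LSTM layer over (B, T, F) input; gate order (i, f, g, o).

    ``return_sequences`` controls whether the full hidden sequence
    (B, T, H) or only the final state (B, H) is emitted.  The forget-gate
    bias is initialized to 1.
    """

    def __init__(self, in_f: int, units: int, return_sequences: bool = False):
        self.in_f, self.units = in_f, units
        self.return_sequences = return_sequences
        self.wx = Param(np.zeros((in_f, 4 * units)))
        self.wh = Param(np.zeros((units, 4 * units)))
        self.b = Param(np.zeros(4 * units))

    def init(self, rng):
        self.wx.data = glorot_uniform(rng, (self.in_f, 4 * self.units),
                                      self.in_f, self.units).astype(DTYPE)
        self.wh.data = glorot_uniform(rng, (self.units, 4 * self.units),
                                      self.units, self.units).astype(DTYPE)
        b = np.zeros(4 * self.units, dtype=DTYPE)
        b[self.units:2 * self.units] = 1.0  # forget bias
        self.b.data = b

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        B, T, _ = x.shape
        if T < 2:
            raise ValueError("LSTM input must have sequence length >= 2")
        H = self.units
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        self._cache = []
        hs = np.zeros((B, T, H), dtype=DTYPE)
        for t in range(T):
            z = x[:, t] @ self.wx.data + h @ self.wh.data + self.b.data
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((x[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t] = h
        self._hs = hs
        self._T = T
        return hs if self.return_sequences else h

    def backward(self, grad):
        grad = np.asarray(grad, dtype=DTYPE)
        H = self.units
        T = self._T
        B = grad.shape[0]
        dx = np.zeros((B, T, self.in_f), dtype=DTYPE)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += grad[:, t]
            elif t == T - 1:
                dh += grad
            dc = dc_next + dh * o * (1 - tanh_c ** 2)
            di = dc * g * i * (1 - i)
            df = dc * c_prev * f * (1 - f)
            dg = dc * i * (1 - g ** 2)
            do = dh * tanh_c * o * (1 - o)
            dz = np.concatenate([di, df, dg, do], axis=1)
            self.wx.grad += x_t.T @ dz
            self.wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.wx.data.T
            dh_next = dz @ self.wh.data.T
            dc_next = dc * f
        return dx


# ---------------------------------------------------------------------------
# model container, loss, optimizer
# ---------------------------------------------------------------------------

class Sequential:
    """A plain layer stack with shared init/dropout generators."""

    def __init__(self, layers: list[Layer], seed: int = 0):
        self.layers = layers
        rng = np.random.default_rng(seed)
        for layer in layers:
            layer.init(rng)
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(rng.integers(2 ** 31))

    def forward(self, x, training: bool = False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    __call__ = forward

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.data = w.astype(DTYPE)

    def summary(self) -> str:
        lines = [f"{type(l).__name__:<16s} params={sum(p.data.size for p in l.params())}"
                 for l in self.layers]
        lines.append(f"total params: {self.n_params()}")
        return "\n".join(lines)


class MSELoss:
    """Mean squared error over a batch of scalar predictions."""

    def forward(self, pred: np.ndarray, target: np.ndarray) -> float:
        pred = pred.reshape(-1)
        target = np.asarray(target, dtype=DTYPE).reshape(-1)
        self._diff = pred - target
        return float(np.mean(self._diff ** 2))

    def backward(self) -> np.ndarray:
        n = self._diff.size
        return (2.0 / n * self._diff).astype(DTYPE).reshape(-1, 1)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999), no weight decay."""

    def __init__(self, params: list[Param], lr: float = 0.002,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
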