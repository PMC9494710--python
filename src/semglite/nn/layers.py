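"""Layers with forward/backward passes, float32, batch-first.

Convolution inputs are ``(B, H, W, C)`` with H the time axis and W the
channel axis of the sEMG tensor; LSTM inputs are ``(B, T, F)``.  Gradients
are accumulated into ``Param.grad`` by ``backward`` and consumed by the
optimizers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32

# x86 FPUs fall off the fast path on denormal floats, and the LSTM's
# multiplicative chains (cell-state decay, 181-step BPTT products) generate
# them in bulk.  Adding and subtracting this constant rounds anything below
# ~1e-31 to exactly zero at negligible cost and error.
_FLUSH = F32(1e-24)


def flush_denormals(a: np.ndarray) -> np.ndarray:
    """Round denormal-range float32 values to zero, in place."""
    a += _FLUSH
    a -= _FLUSH
    return a


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _pad_amount(mode: str, k: int) -> tuple[int, int]:
    """Stride-1 padding for one axis: 'same' keeps length, 'valid' adds none."""
    if mode == "valid":
        return 0, 0
    total = k - 1
    return total // 2, total - total // 2


# im2col trades memory for large GEMMs; the column matrix is rebuilt per
# batch, so for the layer shapes used here (<= ~400 MB at batch 32) this is
# the fast path on a single CPU.  A kernel-position loop remains as the
# fallback for shapes where columns would not fit.
_IM2COL_MAX_COLS_BYTES = 1 << 29


class Conv2D(Layer):
    """Stride-1 2-D convolution (cross-correlation), bias included.

    ``padding`` is ``"same"`` (both axes), ``"valid"`` (both axes) or
    ``"same_time"`` (same along H, valid along W — used when a kernel spans
    the full channel axis and collapses it).
    """

    def __init__(
        self,
        kernel_h: int,
        kernel_w: int,
        c_in: int,
        c_out: int,
        padding: str = "valid",
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        if padding not in ("same", "valid", "same_time"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng(0)
        self.kh, self.kw, self.c_in, self.c_out = kernel_h, kernel_w, c_in, c_out
        self.padding = padding
        fan_in = kernel_h * kernel_w * c_in
        self.w = Param(
            glorot(rng, (kernel_h, kernel_w, c_in, c_out), fan_in, c_out), f"{name}.w"
        )
        self.b = Param(np.zeros(c_out, dtype=F32), f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _pads(self) -> tuple[tuple[int, int], tuple[int, int]]:
        mode_h = "same" if self.padding in ("same", "same_time") else "valid"
        mode_w = "same" if self.padding == "same" else "valid"
        return _pad_amount(mode_h, self.kh), _pad_amount(mode_w, self.kw)

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        (pt, pb), (pl, pr) = self._pads()
        return h + pt + pb - self.kh + 1, w + pl + pr - self.kw + 1

    def forward(self, x, train, rng):
        x = np.ascontiguousarray(x, dtype=F32)
        (pt, pb), (pl, pr) = self._pads()
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if pt + pb + pl + pr else x
        b, hp, wp, _ = xp.shape
        ho, wo = hp - self.kh + 1, wp - self.kw + 1
        patch = self.kh * self.kw * self.c_in
        wmat = self.w.value.reshape(patch, self.c_out)
        wide = wo == 1 and patch > 1024  # full-width kernel, large patch
        if not wide and b * ho * wo * patch * 4 <= _IM2COL_MAX_COLS_BYTES:
            # patch layout (kh, kw, C) matches wmat's flattening; inner runs
            # of kw*C floats are contiguous in xp, so the copy streams well
            cols = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
            cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3)).reshape(
                b * ho * wo, patch
            )
            out = (cols @ wmat).reshape(b, ho, wo, self.c_out)
            self._cache = ("im2col", xp, cols, (b, ho, wo))
        elif wide:
            # kernel spans the (padded) width: fold width x channels into one
            # feature axis and slide over time only, one GEMM per kernel row
            xf = xp.reshape(b, hp, self.kw * self.c_in)
            wf = self.w.value.reshape(self.kh, self.kw * self.c_in, self.c_out)
            acc = np.zeros((b, ho, self.c_out), dtype=F32)
            for i in range(self.kh):
                acc += xf[:, i : i + ho, :] @ wf[i]
            out = acc.reshape(b, ho, 1, self.c_out)
            self._cache = ("wide", xp, None, (b, ho, wo))
        else:
            out = np.zeros((b, ho, wo, self.c_out), dtype=F32)
            for i in range(self.kh):
                for j in range(self.kw):
                    out += xp[:, i : i + ho, j : j + wo, :] @ self.w.value[i, j]
            self._cache = ("loop", xp, None, (b, ho, wo))
        return out + self.b.value

    def backward(self, dout):
        mode, xp, cols, (b, ho, wo) = self._cache
        dout = np.ascontiguousarray(dout, dtype=F32)
        dflat = dout.reshape(b * ho * wo, self.c_out)
        self.b.grad += dflat.sum(axis=0)
        dxp = np.zeros_like(xp)
        if mode == "im2col":
            self.w.grad += (cols.T @ dflat).reshape(self.w.value.shape)
            dcols = dflat @ self.w.value.reshape(-1, self.c_out).T
            # col2im: kernel-position-major transpose makes every source
            # slice contiguous, so the overlap-add loop is bandwidth-bound
            dcols = np.ascontiguousarray(
                dcols.reshape(b, ho, wo, self.kh, self.kw, self.c_in).transpose(
                    3, 4, 0, 1, 2, 5
                )
            )
            if self.c_in == 1:
                dxp3, dc5 = dxp[..., 0], dcols[..., 0]
                for i in range(self.kh):
                    for j in range(self.kw):
                        dxp3[:, i : i + ho, j : j + wo] += dc5[i, j]
            else:
                for i in range(self.kh):
                    for j in range(self.kw):
                        dxp[:, i : i + ho, j : j + wo, :] += dcols[i, j]
        elif mode == "wide":
            # Both weight and input gradients reduce to full-correlation
            # GEMMs against time windows of the (small) upstream gradient:
            #   dW[i,f,m]  = sum_{b,s} xf[b,s,f] * dr[b,s-i,m]
            #   dxf[b,s,f] = sum_{i,m} dr[b,s-i,m] * wf[i,f,m]
            # so one (B*H, kh*c_out) column matrix of dr serves both.
            kh, f, m = self.kh, self.kw * self.c_in, self.c_out
            hp = xp.shape[1]
            xf = xp.reshape(b, hp, f)
            dr = dout.reshape(b, ho, m)
            drp = np.zeros((b, ho + 2 * (kh - 1), m), dtype=F32)
            drp[:, kh - 1 : kh - 1 + ho, :] = dr
            # window index i' maps to kernel row i = kh-1-i'
            cols_d = sliding_window_view(drp, kh, axis=1)  # (b, hp, m, kh)
            cols_d = np.ascontiguousarray(cols_d.transpose(0, 1, 3, 2)).reshape(
                b * hp, kh * m
            )
            wg = (xf.reshape(b * hp, f).T @ cols_d).reshape(f, kh, m)[:, ::-1, :]
            self.w.grad += wg.transpose(1, 0, 2).reshape(self.w.value.shape)
            wflip = (
                self.w.value.reshape(kh, f, m)[::-1].transpose(0, 2, 1).reshape(kh * m, f)
            )
            dxp = (cols_d @ wflip).reshape(xp.shape)
        else:
            dr = dout
            for i in range(self.kh):
                for j in range(self.kw):
                    patch = xp[:, i : i + ho, j : j + wo, :].reshape(-1, self.c_in)
                    self.w.grad[i, j] += patch.T @ dflat
                    dxp[:, i : i + ho, j : j + wo, :] += dr @ self.w.value[i, j].T
        (pt, pb), (pl, pr) = self._pads()
        h, w = xp.shape[1] - pt - pb, xp.shape[2] - pl - pr
        return dxp[:, pt : pt + h, pl : pl + w, :]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; pool size 1 is the identity."""

    def __init__(self, pool_h: int = 1, pool_w: int = 1) -> None:
        if pool_h < 1 or pool_w < 1:
            raise ValueError("pool sizes must be >= 1")
        self.ph, self.pw = pool_h, pool_w
        self._cache = None

    def forward(self, x, train, rng):
        if self.ph == 1 and self.pw == 1:
            self._cache = ("id", x.shape)
            return x
        b, h, w, c = x.shape
        ho, wo = h // self.ph, w // self.pw
        xv = x[:, : ho * self.ph, : wo * self.pw, :].reshape(b, ho, self.ph, wo, self.pw, c)
        out = xv.max(axis=(2, 4))
        mask = xv == out[:, :, None, :, None, :]
        self._cache = ("pool", x.shape, mask)
        return out

    def backward(self, dout):
        if self._cache[0] == "id":
            return dout
        _, xshape, mask = self._cache
        b, h, w, c = xshape
        ho, wo = h // self.ph, w // self.pw
        dx = np.zeros(xshape, dtype=F32)
        spread = mask * dout[:, :, None, :, None, :]
        dx[:, : ho * self.ph, : wo * self.pw, :] = spread.reshape(
            b, ho * self.ph, wo * self.pw, c
        )
        return dx


class Reshape(Layer):
    """Per-sample reshape (e.g. 181x1x8 feature maps -> a 181x8 sequence)."""

    def __init__(self, out_shape: tuple[int, ...]) -> None:
        self.out_shape = tuple(out_shape)
        self._in_shape = None

    def forward(self, x, train, rng):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.out_shape)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class LSTM(Layer):
    """Single LSTM layer over ``(B, T, F)``; returns the last hidden state,
    or the full hidden sequence when ``return_sequences`` is set.

    Gate order i, f, g, o; the forget-gate bias starts at 1 so early
    gradients flow through time.
    """

    def __init__(
        self,
        n_in: int,
        hidden: int,
        return_sequences: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "lstm",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.n_in, self.hidden = n_in, hidden
        self.return_sequences = return_sequences
        self.wx = Param(glorot(rng, (n_in, 4 * hidden), n_in, hidden), f"{name}.wx")
        self.wh = Param(glorot(rng, (hidden, 4 * hidden), hidden, hidden), f"{name}.wh")
        b = np.zeros(4 * hidden, dtype=F32)
        b[hidden : 2 * hidden] = 1.0
        self.b = Param(b, f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.wx, self.wh, self.b]

    def forward(self, x, train, rng):
        x = np.ascontiguousarray(x, dtype=F32)
        bsz, t, _ = x.shape
        hdim = self.hidden
        h = np.zeros((bsz, hdim), dtype=F32)
        c = np.zeros((bsz, hdim), dtype=F32)
        steps = []
        hs = np.empty((bsz, t, hdim), dtype=F32)
        for k in range(t):
            z = x[:, k, :] @ self.wx.value + h @ self.wh.value + self.b.value
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim : 2 * hdim])
            g = np.tanh(z[:, 2 * hdim : 3 * hdim])
            o = _sigmoid(z[:, 3 * hdim :])
            c_new = flush_denormals(f * c + i * g)
            tc = np.tanh(c_new)
            h_new = flush_denormals(o * tc)
            steps.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, k, :] = h
        self._cache = (x, steps)
        return hs if self.return_sequences else h

    def backward(self, dout):
        x, steps = self._cache
        bsz, t, _ = x.shape
        hdim = self.hidden
        if self.return_sequences:
            dh_seq = np.ascontiguousarray(dout, dtype=F32)
            dh = np.zeros((bsz, hdim), dtype=F32)
        else:
            dh_seq = None
            dh = np.ascontiguousarray(dout, dtype=F32)
        dc = np.zeros((bsz, hdim), dtype=F32)
        dx = np.empty_like(x)
        for k in range(t - 1, -1, -1):
            if dh_seq is not None:
                dh = dh + dh_seq[:, k, :]
            h_prev, c_prev, i, f, g, o, tc = steps[k]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.wx.grad += x[:, k, :].T @ dz
            self.wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, k, :] = dz @ self.wx.value.T
            dh = flush_denormals(dz @ self.wh.value.T)
            dc = flush_denormals(dc * f)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float = 0.2) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator | None = None,
        name: str = "dense",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.w = Param(glorot(rng, (n_in, n_out), n_in, n_out), f"{name}.w")
        self.b = Param(np.zeros(n_out, dtype=F32), f"{name}.b")
        self._x = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x, train, rng):
        self._x = np.ascontiguousarray(x, dtype=F32)
        return self._x @ self.w.value + self.b.value

    def backward(self, dout):
        dout = np.ascontiguousarray(dout, dtype=F32)
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01) -> None:
        self.alpha = F32(alpha)
        self._x = None

    def forward(self, x, train, rng):
        self._x = x
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._x > 0, dout, self.alpha * dout)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clip keeps exp in float32 range; saturation is exact there anyway
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
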