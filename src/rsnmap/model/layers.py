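"""Minimal reverse-mode autodiff over numpy arrays, channels-last layout.

Only the operations the dense-residual volumetric classifier needs are
implemented. Activations are (N, X, Y, Z, C); convolution weights are
(k, k, k, C_in, C_out) and convolutions are stride-1 with same padding,
realized as a sum of per-offset matrix products (no giant im2col buffer).
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


class Tensor:
    """Node of the computation graph: value, gradient, and backward closure."""

    __slots__ = ("data", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.bwd is not None and t.grad is not None:
                t.bwd(t.grad)


class Parameter(Tensor):
    """Learnable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad += g


def conv3d(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Same-padding stride-1 3D convolution: x (N,X,Y,Z,C) * w (k,k,k,C,F) + b (F,).

    Kernels of width >= 5 go through the spectral path (mathematically
    identical, far fewer operations on desk-scale grids); small kernels use
    the direct per-offset form.
    """
    if w.data.shape[0] >= 5:
        return _conv3d_fft(x, w, b)
    return _conv3d_direct(x, w, b)


def _conv3d_direct(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    k = w.data.shape[0]
    pad = k // 2
    n, xs, ys, zs, _ = x.data.shape
    f = w.data.shape[-1]
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((n, xs, ys, zs, f), dtype=x.data.dtype)
    for dx in range(k):
        for dy in range(k):
            for dz in range(k):
                out += xp[:, dx : dx + xs, dy : dy + ys, dz : dz + zs, :] @ w.data[dx, dy, dz]
    out += b.data

    def bwd(g: np.ndarray) -> None:
        _accum(b, g.sum(axis=(0, 1, 2, 3)))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for dx in range(k):
            for dy in range(k):
                for dz in range(k):
                    patch = xp[:, dx : dx + xs, dy : dy + ys, dz : dz + zs, :]
                    _accum_w = np.tensordot(patch, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[dx, dy, dz] += _accum_w
                    if gxp is not None:
                        gxp[:, dx : dx + xs, dy : dy + ys, dz : dz + zs, :] += (
                            g @ w.data[dx, dy, dz].T
                        )
        if gxp is not None:
            if pad:
                _accum(x, gxp[:, pad:-pad, pad:-pad, pad:-pad, :])
            else:
                _accum(x, gxp)

    return Tensor(out, (x, w, b), bwd)


def _conv3d_fft(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Spectral same-padding cross-correlation (exact up to FFT round-off).

    Forward: out = crop(IFFT(FFT(x) . FFT(flip(w)))). Gradients use the
    matching convolution/correlation theorems, so forward and backward agree
    with the direct path to floating-point precision.
    """
    k = w.data.shape[0]
    pad = k // 2
    n, xs, ys, zs, c = x.data.shape
    f = w.data.shape[-1]
    s = tuple(sfft.next_fast_len(d + k - 1) for d in (xs, ys, zs))

    xf = sfft.rfftn(x.data, s=s, axes=(1, 2, 3))  # (N, S0, S1, S2r, C)
    wf = sfft.rfftn(np.ascontiguousarray(w.data[::-1, ::-1, ::-1]), s=s, axes=(0, 1, 2))

    # per-frequency-bin matmul over channels: (..., N, C) @ (..., C, F)
    pf = np.moveaxis(np.moveaxis(xf, 0, 3) @ wf, 3, 0)
    full = sfft.irfftn(pf, s=s, axes=(1, 2, 3))
    out = full[:, pad : pad + xs, pad : pad + ys, pad : pad + zs, :].astype(x.data.dtype)
    out += b.data

    def bwd(g: np.ndarray) -> None:
        _accum(b, g.sum(axis=(0, 1, 2, 3)))
        gf = sfft.rfftn(g, s=s, axes=(1, 2, 3))
        if x.requires_grad:
            wf2 = sfft.rfftn(w.data, s=s, axes=(0, 1, 2))
            # grad_x[q, c] = sum_f sum_d g[q - d + pad, f] w[d, c, f]
            pb = np.moveaxis(np.moveaxis(gf, 0, 3) @ np.swapaxes(wf2, 3, 4), 3, 0)
            gx = sfft.irfftn(pb, s=s, axes=(1, 2, 3))
            _accum(
                x,
                gx[:, pad : pad + xs, pad : pad + ys, pad : pad + zs, :].astype(x.data.dtype),
            )
        # grad_w[d, c, f] = sum_n sum_p x[p + d - pad, c] g[p, f]  (corr theorem)
        hf = np.swapaxes(np.moveaxis(xf, 0, 3), 3, 4) @ np.conj(np.moveaxis(gf, 0, 3))
        h = sfft.irfftn(hf, s=s, axes=(0, 1, 2))  # (S0, S1, S2, C, F)
        lags = [np.array([(d - pad) % sd for d in range(k)]) for sd in s]
        gw = h[np.ix_(lags[0], lags[1], lags[2])]
        if w.grad is None:
            w.grad = np.zeros_like(w.data)
        w.grad += gw.astype(w.data.dtype)

    return Tensor(out, (x, w, b), bwd)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, slope * x.data)

    def bwd(g: np.ndarray) -> None:
        _accum(x, np.where(pos, g, slope * g))

    return Tensor(out, (x,), bwd)


class BatchNorm:
    """Batch normalization over all but the channel axis, with running stats."""

    def __init__(self, n_channels: int, dtype=np.float32, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_channels, dtype=dtype))
        self.beta = Parameter(np.zeros(n_channels, dtype=dtype))
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        if training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = self.gamma.data * xhat + self.beta.data
        m = x.data.size // x.data.shape[-1]

        def bwd(g: np.ndarray) -> None:
            _accum(self.beta, g.sum(axis=axes))
            _accum(self.gamma, (g * xhat).sum(axis=axes))
            if x.requires_grad:
                if training:
                    gsum = g.sum(axis=axes)
                    gx_sum = (g * xhat).sum(axis=axes)
                    dx = (self.gamma.data * inv / m) * (m * g - gsum - xhat * gx_sum)
                else:
                    dx = self.gamma.data * inv * g
                _accum(x, dx)

        return Tensor(out.astype(x.data.dtype), (x, self.gamma, self.beta), bwd)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


def concat_channels(parts: list[Tensor]) -> Tensor:
    out = np.concatenate([p.data for p in parts], axis=-1)
    sizes = [p.data.shape[-1] for p in parts]
    edges = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for p, a, b in zip(parts, edges[:-1], edges[1:]):
            _accum(p, g[..., a:b])

    return Tensor(out, tuple(parts), bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bwd(g: np.ndarray) -> None:
        _accum(a, g)
        _accum(b, g)

    return Tensor(out, (a, b), bwd)


def dual_pool(x: Tensor) -> Tensor:
    """Mean of max-pooling and average-pooling, window 2^3, stride 2.

    Odd spatial dims are cropped by one trailing plane; dims < 2 are an error.
    """
    n, xs, ys, zs, c = x.data.shape
    if min(xs, ys, zs) < 2:
        raise ValueError("spatial dims must be >= 2 to pool")
    cx, cy, cz = (xs // 2) * 2, (ys // 2) * 2, (zs // 2) * 2
    xc = x.data[:, :cx, :cy, :cz, :]
    win = xc.reshape(n, cx // 2, 2, cy // 2, 2, cz // 2, 2, c)
    mx = win.max(axis=(2, 4, 6))
    av = win.mean(axis=(2, 4, 6))
    out = 0.5 * (mx + av)
    mxb = mx[:, :, None, :, None, :, None, :]
    is_max = win == mxb
    n_max = is_max.sum(axis=(2, 4, 6), keepdims=True)

    def bwd(g: np.ndarray) -> None:
        gb = g[:, :, None, :, None, :, None, :]
        gwin = 0.5 * gb * is_max / n_max + 0.5 * gb / 8.0
        gx = np.zeros_like(x.data)
        gx[:, :cx, :cy, :cz, :] = gwin.reshape(n, cx, cy, cz, c)
        _accum(x, gx)

    return Tensor(out, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, X, Y, Z, C) -> (N, C) spatial mean."""
    n, xs, ys, zs, c = x.data.shape
    m = xs * ys * zs
    out = x.data.mean(axis=(1, 2, 3))

    def bwd(g: np.ndarray) -> None:
        _accum(x, np.broadcast_to(g[:, None, None, None, :] / m, x.data.shape))

    return Tensor(out, (x,), bwd)


def dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out = x.data * keep

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * keep)

    return Tensor(out.astype(x.data.dtype), (x,), bwd)


def linear(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    out = x.data @ w.data + b.data

    def bwd(g: np.ndarray) -> None:
        _accum(w, x.data.T @ g)
        _accum(b, g.sum(axis=0))
        _accum(x, g @ w.data.T)

    return Tensor(out, (x, w, b), bwd)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray, class_weights: np.ndarray) -> Tensor:
    """Class-weighted softmax cross entropy, normalized by the summed weights.

    With weights w_c = N/(K n_c) each class contributes equally in expectation.
    """
    p = softmax(logits.data)
    n = logits.data.shape[0]
    w = np.asarray(class_weights, dtype=logits.data.dtype)[labels]
    wsum = w.sum()
    logp = np.log(np.maximum(p[np.arange(n), labels], 1e-30))
    out = -(w * logp).sum() / wsum

    def bwd(g: np.ndarray) -> None:
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        grad *= (w / wsum)[:, None]
        _accum(logits, g * grad)

    return Tensor(np.asarray(out), (logits,), bwd)
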