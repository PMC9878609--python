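"""Multiscale structural similarity (MS-SSIM) for 3D volumes.

Similarity between two volumes is measured at a pyramid of box-average
downsamplings (factors 2, 4, 8, 16, 32 by default). At each scale, windowed
luminance/contrast/structure statistics are combined into the standard SSIM
score with a Gaussian local window (width 7, SD 1.5, clipped to the volume),
and per-scale mean scores are averaged with Gaussian weights peaked at the
middle factor. Stability constants follow the usual c1 = (0.01 L)^2,
c2 = (0.03 L)^2 with L the joint dynamic range of the two volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class VolumeTooSmallError(ValueError):
    """A spatial dim is smaller than the largest downsampling factor."""


@dataclass(frozen=True)
class MssiSpec:
    scale_factors: tuple[int, ...] = (2, 4, 8, 16, 32)
    scale_weights: tuple[float, ...] | None = None  # default: Gaussian over index, SD 1
    window_width: int = 7
    window_sd: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float | None = None  # default: joint max - joint min

    def __post_init__(self) -> None:
        f = self.scale_factors
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("scale_factors must be strictly increasing")
        if self.scale_weights is not None:
            w = np.asarray(self.scale_weights, dtype=float)
            if w.size != len(f):
                raise ValueError("one weight per scale factor required")
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("scale_weights must be nonnegative and sum to 1")

    def weights(self) -> np.ndarray:
        if self.scale_weights is not None:
            return np.asarray(self.scale_weights, dtype=float)
        m = len(self.scale_factors)
        idx = np.arange(m, dtype=float)
        w = np.exp(-0.5 * (idx - (m - 1) / 2.0) ** 2)  # SD of 1 factor-index
        return w / w.sum()


def fitting_scale_factors(
    shape: tuple[int, ...], factors: tuple[int, ...] = (2, 4, 8, 16, 32)
) -> tuple[int, ...]:
    """The subset of factors whose decimated volume keeps every dim >= 2."""
    keep = tuple(f for f in factors if min(shape) // f >= 2)
    if not keep:
        raise VolumeTooSmallError(f"no factor of {factors} fits shape {shape}")
    return keep


def box_downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    """Box-average decimation by an integer factor (trailing remainder cropped)."""
    if factor == 1:
        return vol
    dims = [(s // factor) * factor for s in vol.shape]
    if min(d // factor for d in dims) < 1:
        raise VolumeTooSmallError(f"cannot downsample shape {vol.shape} by {factor}")
    v = vol[tuple(slice(0, d) for d in dims)]
    for ax, d in enumerate(dims):
        shape = v.shape[:ax] + (d // factor, factor) + v.shape[ax + 1 :]
        v = v.reshape(shape).mean(axis=ax + 1)
    return v


def _gaussian_kernel(width: int, sd: float) -> np.ndarray:
    ax = np.arange(width) - (width - 1) / 2.0
    g = np.exp(-0.5 * (ax / sd) ** 2)
    g3 = g[:, None, None] * g[None, :, None] * g[None, None, :]
    return g3 / g3.sum()


def ssim_volume(
    a: np.ndarray,
    b: np.ndarray,
    window_width: int = 7,
    window_sd: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float | None = None,
) -> float:
    """Mean single-scale SSIM over all fully-contained Gaussian windows."""
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    w = min(window_width, min(a.shape))
    kern = _gaussian_kernel(w, window_sd)
    if dynamic_range is None:
        dynamic_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    if dynamic_range == 0:
        dynamic_range = 1.0
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2

    wa = sliding_window_view(a, (w, w, w))
    wb = sliding_window_view(b, (w, w, w))
    mu_a = np.tensordot(wa, kern, axes=3)
    mu_b = np.tensordot(wb, kern, axes=3)
    ea2 = np.tensordot(wa * wa, kern, axes=3)
    eb2 = np.tensordot(wb * wb, kern, axes=3)
    eab = np.tensordot(wa * wb, kern, axes=3)
    var_a = ea2 - mu_a**2
    var_b = eb2 - mu_b**2
    cov = eab - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float((num / den).mean())


def mssi(vol_a: np.ndarray, vol_b: np.ndarray, spec: MssiSpec = MssiSpec()) -> float:
    """Gaussian-weighted mean of per-scale SSIM scores; 1 for identical volumes."""
    a = np.asarray(vol_a, dtype=float)
    b = np.asarray(vol_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    largest = max(spec.scale_factors)
    if min(a.shape) < largest:
        raise VolumeTooSmallError(
            f"every dim of {a.shape} must be >= the largest factor {largest}; "
            f"use fitting_scale_factors() to drop large factors"
        )
    dr = spec.dynamic_range
    if dr is None:
        dr = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    weights = spec.weights()
    score = 0.0
    for wgt, f in zip(weights, spec.scale_factors):
        da, db = box_downsample(a, f), box_downsample(b, f)
        score += wgt * ssim_volume(
            da, db, spec.window_width, spec.window_sd, spec.k1, spec.k2, dynamic_range=dr
        )
    return float(score)
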