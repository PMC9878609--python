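"""Spectral building blocks shared by the simulator and the evaluation protocols."""

from __future__ import annotations

import numpy as np


def pink_noise_matrix(
    n_series: int,
    n_frames: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
) -> np.ndarray:
    """Zero-mean, unit-SD 1/f^exponent noise, one series per row.

    Generated by spectral shaping: a white complex Gaussian spectrum is
    multiplied by f^(-exponent/2) (so power goes as 1/f^exponent), inverse
    transformed, then standardized per series. The DC bin is zeroed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    freqs = np.fft.rfftfreq(n_frames)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_series, freqs.size))
        + 1j * rng.standard_normal((n_series, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=n_frames, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def pink_noise_series(n_frames: int, rng_seed: int, exponent: float = 1.0) -> np.ndarray:
    """One zero-mean pink-noise series; deterministic given ``rng_seed``."""
    rng = np.random.default_rng(rng_seed)
    return pink_noise_matrix(1, n_frames, rng, exponent=exponent)[0]


def lowpass_hard(x: np.ndarray, tr: float, cutoff_hz: float) -> np.ndarray:
    """Hard frequency-domain low-pass along the last axis.

    Components at or above ``cutoff_hz`` are zeroed outright (ideal brick-wall
    filter); the DC component is kept and removed later by mean-centering.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be > 0")
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    spec = np.fft.rfft(x, axis=-1)
    spec[..., freqs >= cutoff_hz] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def log_spectral_slope(x: np.ndarray, f_lo: float = 0.01, f_hi: float = 0.4) -> float:
    """Least-squares slope of log-power vs log-frequency over mid frequencies.

    Frequencies are in cycles/sample; the default band avoids the DC bin and
    the Nyquist edge. Used to verify 1/f spectra (slope approximately -1).
    """
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n)
    power = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    if power.ndim > 1:
        power = power.mean(axis=tuple(range(power.ndim - 1)))
    band = (freqs >= f_lo) & (freqs <= f_hi) & (power > 0)
    coef = np.polyfit(np.log(freqs[band]), np.log(power[band]), 1)
    return float(coef[0])
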