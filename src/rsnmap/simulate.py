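"""Synthetic preprocessed-equivalent resting-state BOLD with planted network structure.

The simulator emulates the *output* of a standard resting-state preprocessing
chain (mean-centered voxel series, band-limited below ~0.1 Hz, optional
global-signal regression) rather than raw scanner data. Each network owns a
latent band-limited time course; latents are correlated across networks
according to a user-supplied correlation matrix. ROI voxels carry their
network's latent at full amplitude, background (non-ROI, in-mask) voxels carry
weak random mixtures of all latents so that label confirmation is non-trivial,
and every voxel receives independent 1/f (pink) noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import PhantomAtlas
from .signals import lowpass_hard, pink_noise_matrix

#: Amplitude of background latent mixtures relative to within_network_weight.
BACKGROUND_MIX_SCALE = 0.3


class InvalidSpecError(ValueError):
    """Raised for an inconsistent simulation specification (e.g. non-PSD correlations)."""


@dataclass(frozen=True)
class SimulationSpec:
    """Knobs of the planted-covariance BOLD model.

    Parameters
    ----------
    within_network_weight
        Amplitude of the shared network latent in its ROI voxels (unitless).
    cross_network_corr
        K x K latent-signal correlation matrix; identity means independent
        networks. Must be symmetric, unit-diagonal, PSD.
    noise_sd
        SD of the per-voxel pink noise (unitless; the latent has unit SD, so
        within_network_weight / noise_sd is the per-voxel SNR).
    lowpass_hz
        Brick-wall low-pass cutoff applied to latents, Hz.
    subject_jitter
        Relative SD of the per-subject multiplicative amplitude perturbation.
    pink_exponent
        Spectral exponent of the voxel noise (1 = pink).
    global_signal_regression
        If True, the spatial-mean series over the mask is regressed out of
        every in-mask voxel, emulating global signal regression (this pushes
        between-network correlations negative, as it does in real data).
    """

    within_network_weight: float = 1.0
    cross_network_corr: np.ndarray | None = None
    noise_sd: float = 1.0
    lowpass_hz: float = 0.1
    subject_jitter: float = 0.1
    pink_exponent: float = 1.0
    global_signal_regression: bool = False

    def corr_matrix(self, k: int) -> np.ndarray:
        c = self.cross_network_corr
        if c is None:
            return np.eye(k)
        c = np.asarray(c, dtype=float)
        if c.shape != (k, k):
            raise InvalidSpecError(f"cross_network_corr must be {k}x{k}")
        if not np.allclose(c, c.T, atol=1e-12):
            raise InvalidSpecError("cross_network_corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise InvalidSpecError("cross_network_corr must have unit diagonal")
        if np.abs(c).max() > 1 + 1e-12:
            raise InvalidSpecError("cross_network_corr entries must lie in [-1, 1]")
        evals = np.linalg.eigvalsh(c)
        if evals.min() < -1e-10:
            raise InvalidSpecError("cross_network_corr must be positive semidefinite")
        return c

    def validate(self, k: int) -> None:
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.lowpass_hz <= 0:
            raise InvalidSpecError("lowpass_hz must be > 0")
        if self.subject_jitter < 0:
            raise InvalidSpecError("subject_jitter must be >= 0")
        self.corr_matrix(k)


@dataclass(frozen=True)
class BoldScan:
    """One subject's 4D BOLD volume (X, Y, Z, T) with TR and gray-matter mask."""

    data: np.ndarray
    tr: float
    mask: np.ndarray
    subject_id: str = "sub-000"

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def validate(self) -> None:
        if self.data.ndim != 4 or self.data.shape[3] < 2:
            raise ValueError("data must be 4D with T >= 2")
        if not np.isfinite(self.data).all():
            raise ValueError("data must be finite")
        if self.mask.shape != self.data.shape[:3] or self.mask.dtype != bool:
            raise ValueError("mask must be boolean with the scan's spatial shape")
        if self.data[~self.mask].any():
            raise ValueError("voxels outside the mask must be exactly zero")
        if self.tr <= 0:
            raise ValueError("tr must be positive seconds")

    def series(self, voxels: np.ndarray) -> np.ndarray:
        """Time series at the given (n, 3) voxel coordinates, shape (n, T)."""
        voxels = np.asarray(voxels, dtype=np.intp)
        return self.data[voxels[:, 0], voxels[:, 1], voxels[:, 2], :]


def _subject_rng(rng_seed: int, subject_index: int) -> np.random.Generator:
    # Named substream: reproducible per subject independent of cohort size.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=rng_seed, spawn_key=(subject_index,))
    )


def simulate_scan(
    atlas: PhantomAtlas,
    spec: SimulationSpec,
    n_frames: int = 300,
    tr: float = 2.2,
    subject_id: str = "sub-000",
    rng_seed: int = 0,
    _rng: np.random.Generator | None = None,
    _amplitude: float | None = None,
) -> BoldScan:
    """Simulate one subject's preprocessed-equivalent scan on a phantom atlas.

    In-mask ROI voxels receive ``within_network_weight x latent_k + noise``;
    background in-mask voxels receive weak random latent mixtures plus noise;
    every voxel series is mean-centered and out-of-mask voxels are exactly 0.
    Deterministic given ``rng_seed``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    k = atlas.n_networks
    spec.validate(k)
    rng = _rng if _rng is not None else np.random.default_rng(rng_seed)
    corr = spec.corr_matrix(k)

    # Correlated, band-limited, unit-SD latents (one per network). The factor
    # comes from an eigendecomposition so rank-deficient (e.g. all-ones)
    # correlation matrices are handled exactly.
    evals, evecs = np.linalg.eigh(corr)
    factor = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0)))
    white = rng.standard_normal((k, n_frames))
    latents = factor @ white
    latents = lowpass_hard(latents, tr=tr, cutoff_hz=spec.lowpass_hz)
    latents -= latents.mean(axis=1, keepdims=True)
    sd = latents.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    latents /= sd

    amp = spec.within_network_weight if _amplitude is None else _amplitude

    mask_idx = np.argwhere(atlas.mask)
    n_vox = len(mask_idx)
    flat = np.zeros((n_vox, n_frames))

    # map voxel coordinate -> row in flat
    row_of = np.full(atlas.grid_shape, -1, dtype=np.intp)
    row_of[tuple(mask_idx.T)] = np.arange(n_vox)

    is_roi = np.zeros(n_vox, dtype=bool)
    for roi in atlas.rois:
        rows = row_of[tuple(roi.voxels.T)]
        flat[rows] = amp * latents[roi.network_index]
        is_roi[rows] = True

    bg_rows = np.flatnonzero(~is_roi)
    if len(bg_rows):
        mix = rng.standard_normal((len(bg_rows), k))
        norms = np.linalg.norm(mix, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        mix /= norms
        flat[bg_rows] = (BACKGROUND_MIX_SCALE * amp) * (mix @ latents)

    if spec.noise_sd > 0:
        flat += spec.noise_sd * pink_noise_matrix(
            n_vox, n_frames, rng, exponent=spec.pink_exponent
        )

    if spec.global_signal_regression:
        g = flat.mean(axis=0)
        g = g - g.mean()
        denom = float(g @ g)
        if denom > 0:
            beta = flat @ g / denom
            flat -= np.outer(beta, g)

    flat -= flat.mean(axis=1, keepdims=True)

    data = np.zeros(atlas.grid_shape + (n_frames,))
    data[tuple(mask_idx.T)] = flat
    scan = BoldScan(data=data, tr=tr, mask=atlas.mask.copy(), subject_id=subject_id)
    scan.validate()
    return scan


def simulate_cohort(
    atlas: PhantomAtlas,
    spec: SimulationSpec,
    n_subjects: int,
    n_frames: int = 300,
    tr: float = 2.2,
    rng_seed: int = 0,
) -> list[BoldScan]:
    """One scan per subject with independent noise and per-subject amplitude jitter.

    Subject substreams are derived from the master seed by name, so subject i's
    scan does not change when the cohort size changes.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    scans = []
    for i in range(n_subjects):
        rng = _subject_rng(rng_seed, i)
        jit = 1.0 + spec.subject_jitter * rng.standard_normal()
        jit = max(jit, 0.1)  # amplitudes stay positive
        scans.append(
            simulate_scan(
                atlas,
                spec,
                n_frames=n_frames,
                tr=tr,
                subject_id=f"sub-{i:03d}",
                rng_seed=rng_seed,
                _rng=rng,
                _amplitude=jit * spec.within_network_weight,
            )
        )
    return scans
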