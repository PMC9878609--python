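"""Seed-similarity training samples.

A training sample is a whole-brain, 2-channel similarity volume computed
against the mean signal of a random subset of one network's ROIs: channel 0 is
the voxelwise Pearson correlation with the seed, channel 1 the Euclidean
distance between z-scored series scaled by 1/sqrt(T) (so truncated scans keep
the same input distribution). The sample's label is the seeding network, kept
only after confirming that the seed correlates best with that network's own
mean signal. Training samples are augmented by small random 3D affine
transforms, intensity scaling, and additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

from .phantom import PhantomAtlas, Roi
from .simulate import BoldScan


class LabelTieError(RuntimeError):
    """Two networks are exactly tied for the highest seed correlation."""


class SampleExhaustionError(RuntimeError):
    """Label-confirmation redraw budget consumed; the phantom looks unlearnable."""


@dataclass(frozen=True)
class SimilaritySample:
    """2-channel similarity volume with its confirmed network label."""

    channels: np.ndarray  # (2, X, Y, Z)
    label: int
    subject_id: str

    def validate(self, mask: np.ndarray | None = None, n_networks: int | None = None) -> None:
        if self.channels.ndim != 4 or self.channels.shape[0] != 2:
            raise ValueError("channels must have shape (2, X, Y, Z)")
        if not np.isfinite(self.channels).all():
            raise ValueError("channels must be finite")
        if n_networks is not None and not 0 <= self.label < n_networks:
            raise ValueError("label out of range")
        if mask is not None:
            if self.channels[:, ~mask].any():
                raise ValueError("channels must be exactly 0 outside the mask")
            r = self.channels[0][mask]
            if r.size and (r.min() < -1 - 1e-9 or r.max() > 1 + 1e-9):
                raise ValueError("correlation channel must lie in [-1, 1]")
        if self.channels[1].min() < -1e-9:
            raise ValueError("distance channel must be >= 0")


@dataclass(frozen=True)
class AugmentParams:
    """Bounds of the random augmentation transforms.

    Defaults: rotations within +-5 degrees per axis, translations within
    +-3 voxels per axis, shears within +-3 degrees, multiplicative intensity
    scaling in [0.9, 1.1], additive Gaussian noise with SD 0.01.
    """

    rot_deg: float = 5.0
    trans_vox: float = 3.0
    shear_deg: float = 3.0
    intensity_range: tuple[float, float] = (0.9, 1.1)
    gauss_sd: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.intensity_range
        if min(self.rot_deg, self.trans_vox, self.shear_deg, self.gauss_sd) < 0:
            raise ValueError("augmentation bounds must be >= 0")
        if not lo <= 1.0 <= hi:
            raise ValueError("intensity_range must contain 1")


@dataclass
class TrainingSet:
    """Confirmed-label samples with a subject-disjoint train/validation split."""

    samples: list[SimilaritySample]
    split: list[str]  # "train" | "val" per sample
    class_counts: np.ndarray
    class_weights: np.ndarray
    networks: tuple[str, ...] = ()
    mask: np.ndarray | None = None

    def indices(self, which: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.split) == which)

    def validate(self) -> None:
        train_subj = {self.samples[i].subject_id for i in self.indices("train")}
        val_subj = {self.samples[i].subject_id for i in self.indices("val")}
        if train_subj & val_subj:
            raise ValueError("validation subjects must be disjoint from training")
        prods = self.class_weights * self.class_counts
        if not np.allclose(prods, prods[0]):
            raise ValueError("class_weights x class_counts must be constant")
        for which in ("train", "val"):
            labels = {self.samples[i].label for i in self.indices(which)}
            if len(labels) < len(self.class_counts):
                raise ValueError(f"every network must appear in the {which} split")


def subsample_network_rois(
    atlas: PhantomAtlas, network_index: int, n_rois: int, rng_seed: int | np.random.Generator
) -> list[Roi]:
    """Draw ``n_rois`` distinct ROIs of one network, deterministic given the seed."""
    rois = atlas.rois_of_network(network_index)
    if not 1 <= n_rois <= len(rois):
        raise ValueError(
            f"n_rois must be in [1, {len(rois)}] for network {network_index}, got {n_rois}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pick = rng.choice(len(rois), size=n_rois, replace=False)
    return [rois[i] for i in sorted(pick)]


def mean_seed_signal(scan: BoldScan, voxels: np.ndarray) -> np.ndarray:
    """Framewise arithmetic mean of the series at the given voxels."""
    voxels = np.asarray(voxels, dtype=np.intp)
    if voxels.size == 0:
        raise ValueError("voxel set must be non-empty")
    if not scan.mask[tuple(voxels.T)].all():
        raise ValueError("all seed voxels must lie inside the mask")
    return scan.series(voxels).mean(axis=0)


def _zscore(x: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Sample (ddof=1) z-score along ``axis``; returns (z, sd). Zero-SD rows yield z = 0."""
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True, ddof=1)
    safe = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / safe
    z = np.where(sd == 0, 0.0, z)
    return z, sd


def similarity_map(scan: BoldScan, seed_series: np.ndarray) -> np.ndarray:
    """Whole-brain 2-channel similarity volume for one seed series.

    Channel 0: Pearson r(seed, voxel). Channel 1: ||z(seed) - z(voxel)|| / sqrt(T),
    with z-scores using the sample SD (ddof=1). Zero-variance voxel series get
    r = 0 by convention and are compared against a zero vector for the
    distance. Both channels are 0 outside the mask.
    """
    seed_series = np.asarray(seed_series, dtype=float)
    t = seed_series.size
    if t != scan.n_frames:
        raise ValueError("seed series length must equal the scan's frame count")
    if seed_series.std() == 0:
        raise ValueError("seed series has zero variance")

    mask_idx = np.argwhere(scan.mask)
    series = scan.data[tuple(mask_idx.T)]  # (V, T)
    zs = (seed_series - seed_series.mean()) / seed_series.std(ddof=1)
    zv, sd = _zscore(series, axis=1)

    r = zv @ zs / (t - 1)
    r = np.clip(r, -1.0, 1.0)
    r[sd[:, 0] == 0] = 0.0
    dist = np.linalg.norm(zv - zs[None, :], axis=1) / np.sqrt(t)

    out = np.zeros((2,) + scan.mask.shape)
    out[0][tuple(mask_idx.T)] = r
    out[1][tuple(mask_idx.T)] = dist
    return out


def confirm_label(scan: BoldScan, seed_series: np.ndarray, atlas: PhantomAtlas) -> int:
    """Index of the network whose mean signal correlates best with the seed.

    Raises LabelTieError on an exact tie for the maximum.
    """
    seed_series = np.asarray(seed_series, dtype=float)
    if seed_series.std() == 0:
        raise ValueError("seed series has zero variance")
    corrs = np.empty(atlas.n_networks)
    for k in range(atlas.n_networks):
        net_mean = mean_seed_signal(scan, atlas.network_voxels(k))
        if net_mean.std() == 0:
            corrs[k] = 0.0
        else:
            corrs[k] = np.corrcoef(seed_series, net_mean)[0, 1]
    best = int(np.argmax(corrs))
    if (corrs == corrs[best]).sum() > 1:
        raise LabelTieError("two networks are exactly tied for the best correlation")
    return best


def _augment_matrix(params: AugmentParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random affine (matrix, translation) within the parameter bounds."""
    ang = np.deg2rad(rng.uniform(-params.rot_deg, params.rot_deg, size=3))
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    shear = np.eye(3)
    # one shear angle per coordinate plane (xy, xz, yz)
    sh = np.tan(np.deg2rad(rng.uniform(-params.shear_deg, params.shear_deg, size=3)))
    shear[0, 1], shear[0, 2], shear[1, 2] = sh
    mat = rx @ ry @ rz @ shear
    trans = rng.uniform(-params.trans_vox, params.trans_vox, size=3)
    return mat, trans


def augment_sample(
    sample: SimilaritySample,
    params: AugmentParams,
    rng_seed: int | np.random.Generator,
    mask: np.ndarray | None = None,
) -> SimilaritySample:
    """Random affine + intensity scale + Gaussian noise; label preserved.

    Interpolation is trilinear with zero fill outside the volume; the
    correlation channel is re-clipped to [-1, 1], the distance channel to
    >= 0, and (when a mask is given) out-of-mask voxels are re-zeroed so the
    sample invariants survive augmentation. Deterministic given the seed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    mat, trans = _augment_matrix(params, rng)
    scale = rng.uniform(*params.intensity_range)

    center = (np.array(sample.channels.shape[1:]) - 1) / 2.0
    offset = center - mat @ center - trans
    identity = (
        params.rot_deg == 0
        and params.trans_vox == 0
        and params.shear_deg == 0
    )
    out = np.empty_like(sample.channels)
    for c in range(2):
        if identity:
            out[c] = sample.channels[c]
        else:
            out[c] = affine_transform(
                sample.channels[c], mat, offset=offset, order=1, mode="constant", cval=0.0
            )
    out *= scale
    if params.gauss_sd > 0:
        out += rng.normal(0.0, params.gauss_sd, size=out.shape)
    out[0] = np.clip(out[0], -1.0, 1.0)
    out[1] = np.maximum(out[1], 0.0)
    if mask is not None:
        out[:, ~mask] = 0.0
    return SimilaritySample(channels=out, label=sample.label, subject_id=sample.subject_id)


def make_sample(
    scan: BoldScan,
    atlas: PhantomAtlas,
    network_index: int,
    n_rois: int,
    rng: np.random.Generator,
) -> SimilaritySample | None:
    """One confirmed-label sample, or None if confirmation rejects the draw."""
    rois = subsample_network_rois(atlas, network_index, n_rois, rng)
    voxels = np.concatenate([r.voxels for r in rois], axis=0)
    seed = mean_seed_signal(scan, voxels)
    if seed.std() == 0:
        return None
    try:
        confirmed = confirm_label(scan, seed, atlas)
    except LabelTieError:
        return None
    if confirmed != network_index:
        return None
    return SimilaritySample(
        channels=similarity_map(scan, seed),
        label=network_index,
        subject_id=scan.subject_id,
    )


def compute_class_weights(class_counts: np.ndarray) -> np.ndarray:
    """Balanced loss weights w_c = N / (K * n_c), so each class contributes equally."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts <= 0).any():
        raise ValueError("all class counts must be > 0")
    return counts.sum() / (counts.size * counts)


def build_training_set(
    scans: list[BoldScan],
    atlas: PhantomAtlas,
    samples_per_network: int = 150,
    n_rois_range: tuple[int, int] = (1, 3),
    val_subject_fraction: float = 0.25,
    aug: AugmentParams | None = AugmentParams(),
    rng_seed: int = 0,
    max_redraw_factor: int = 20,
) -> TrainingSet:
    """Build a confirmed-label, subject-split, augmented training corpus.

    Per network, exactly ``samples_per_network`` samples are drawn by cycling
    over subjects; samples whose confirmed label disagrees with the seeded
    network are discarded and redrawn (budget ``max_redraw_factor x
    samples_per_network`` draws per network). Whole subjects are held out for
    validation; training-split samples are augmented in place, validation
    samples stay clean.
    """
    if len(scans) < 2:
        raise ValueError("need >= 2 subjects for a subject-disjoint split")
    rng = np.random.default_rng(rng_seed)
    k = atlas.n_networks

    subjects = [s.subject_id for s in scans]
    n_val = max(1, round(val_subject_fraction * len(subjects)))
    if n_val >= len(subjects):
        raise ValueError("val_subject_fraction leaves no training subjects")
    val_subjects = set(rng.choice(subjects, size=n_val, replace=False).tolist())

    lo, hi = n_rois_range
    samples: list[SimilaritySample] = []
    split: list[str] = []
    n_discarded = 0
    for net in range(k):
        max_rois = len(atlas.rois_of_network(net))
        budget = max_redraw_factor * samples_per_network
        got = 0
        s_idx = 0
        while got < samples_per_network:
            if budget <= 0:
                raise SampleExhaustionError(
                    f"network {net}: redraw budget exhausted "
                    f"({n_discarded} discards) — phantom may be unlearnable"
                )
            budget -= 1
            scan = scans[s_idx % len(scans)]
            s_idx += 1
            n_rois = int(rng.integers(min(lo, max_rois), min(hi, max_rois) + 1))
            sample = make_sample(scan, atlas, net, n_rois, rng)
            if sample is None:
                n_discarded += 1
                continue
            which = "val" if scan.subject_id in val_subjects else "train"
            if which == "train" and aug is not None:
                sample = augment_sample(sample, aug, rng, mask=atlas.mask)
            samples.append(sample)
            split.append(which)
            got += 1

    class_counts = np.bincount([s.label for s in samples], minlength=k)
    tset = TrainingSet(
        samples=samples,
        split=split,
        class_counts=class_counts,
        class_weights=compute_class_weights(class_counts),
        networks=atlas.networks,
        mask=atlas.mask.copy(),
    )
    tset.n_discarded = n_discarded  # type: ignore[attr-defined]
    tset.validate()
    return tset
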