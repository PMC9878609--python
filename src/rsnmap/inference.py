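"""Voxelwise network-membership probability maps and group characterizations.

Every in-mask voxel acts as its own seed: its time series is correlated with
the whole brain to form the 2-channel similarity volume, the trained
classifier is applied, and the final-head softmax vector is stored at that
voxel. Group maps are the voxelwise mean, sample SD, and mean/SD across
subjects; winner-take-all (WTA) segmentation and per-network summary measures
follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model.training import TrainedModel
from .phantom import PhantomAtlas
from .simulate import BoldScan


@dataclass(frozen=True)
class ProbabilityMaps:
    """Per-subject K x X x Y x Z stack of softmax membership probabilities."""

    probs: np.ndarray
    subject_id: str
    mask: np.ndarray
    networks: tuple[str, ...] = ()

    @property
    def n_networks(self) -> int:
        return self.probs.shape[0]

    def validate(self) -> None:
        if self.probs.ndim != 4 or self.probs.shape[1:] != self.mask.shape:
            raise ValueError("probs must be (K, X, Y, Z) matching the mask")
        inm = self.probs[:, self.mask]
        if inm.min() < -1e-9 or inm.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(inm.sum(axis=0), 1.0, atol=1e-4):
            raise ValueError("probabilities must sum to 1 at every in-mask voxel")
        if self.probs[:, ~self.mask].any():
            raise ValueError("probabilities must be 0 outside the mask")


@dataclass(frozen=True)
class GroupMaps:
    """Voxelwise mean, sample SD, and mean/SD across subjects, per network."""

    mean: np.ndarray
    std: np.ndarray
    snr: np.ndarray
    networks: tuple[str, ...] = ()

    def validate(self) -> None:
        if not (self.mean.shape == self.std.shape == self.snr.shape):
            raise ValueError("mean/std/snr shapes must match")
        if self.std.min() < 0:
            raise ValueError("std must be >= 0")
        if not np.isfinite(self.snr).all():
            raise ValueError("snr must be finite everywhere")


@dataclass(frozen=True)
class SegmentationVolume:
    """Integer labels: 0 = unassigned, 1..K = network index + 1."""

    labels: np.ndarray
    threshold: float


def voxelwise_similarity_channels(scan: BoldScan) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-voxel similarity channels: (R, D, zero_variance_rows).

    R[i, j] is the Pearson correlation between in-mask voxels i and j; D is
    the matching ddof-1 z-scored Euclidean distance / sqrt(T), computed
    through the exact identity ||z_i - z_j|| = sqrt(2 (T-1) (1 - r_ij)).
    Zero-variance voxels follow the r = 0 / distance-vs-zero-vector convention.
    """
    mask_idx = np.argwhere(scan.mask)
    series = scan.data[tuple(mask_idx.T)]
    t = series.shape[1]
    sd = series.std(axis=1, ddof=1)
    degenerate = sd == 0
    safe = np.where(degenerate, 1.0, sd)
    z = (series - series.mean(axis=1, keepdims=True)) / safe[:, None]
    z[degenerate] = 0.0
    r = np.clip(z @ z.T / (t - 1), -1.0, 1.0)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    d = np.sqrt(np.maximum(2.0 * (1.0 - r) * (t - 1) / t, 0.0))
    # zero-variance rows/cols: distance to the zero vector is ||z||/sqrt(T)
    d[degenerate, :] = np.sqrt((t - 1) / t)
    d[:, degenerate] = np.sqrt((t - 1) / t)
    d[np.ix_(degenerate, degenerate)] = 0.0
    np.fill_diagonal(d, 0.0)
    r[np.diag_indices_from(r)] = np.where(degenerate, 0.0, 1.0)
    return r, d, degenerate


def voxelwise_probability_maps(
    model: TrainedModel,
    scan: BoldScan,
    mask: np.ndarray | None = None,
    networks: tuple[str, ...] = (),
    batch_size: int = 32,
) -> ProbabilityMaps:
    """Classify every in-mask voxel's own-seed similarity map.

    Voxels with zero-variance series receive the uniform vector 1/K.
    """
    mask = scan.mask if mask is None else np.asarray(mask, dtype=bool)
    mask_idx = np.argwhere(mask)
    n_vox = len(mask_idx)
    k = model.config.n_classes
    r, d, degenerate = voxelwise_similarity_channels(
        scan if mask is scan.mask else BoldScan(scan.data * mask[..., None], scan.tr, mask, scan.subject_id)
    )

    probs_flat = np.full((n_vox, k), 1.0 / k)
    valid = np.flatnonzero(~degenerate)
    shape = mask.shape
    for start in range(0, len(valid), batch_size):
        rows = valid[start : start + batch_size]
        batch = np.zeros((len(rows),) + shape + (2,), dtype=np.float32)
        for bi, row in enumerate(rows):
            batch[bi, ..., 0][tuple(mask_idx.T)] = r[row]
            batch[bi, ..., 1][tuple(mask_idx.T)] = d[row]
        probs_flat[rows] = model.model.predict_proba(batch, batch_size=batch_size)

    probs = np.zeros((k,) + shape)
    probs[:, mask_idx[:, 0], mask_idx[:, 1], mask_idx[:, 2]] = probs_flat.T
    pm = ProbabilityMaps(probs=probs, subject_id=scan.subject_id, mask=mask, networks=networks)
    pm.validate()
    return pm


def wta_segmentation(pm: ProbabilityMaps, threshold: float = 0.0) -> SegmentationVolume:
    """Winner-take-all: label = argmax + 1 where the max probability reaches the
    threshold, else 0; exact ties break to the lowest network index."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    winner = pm.probs.argmax(axis=0)  # argmax breaks ties toward the lowest index
    peak = pm.probs.max(axis=0)
    labels = np.where(pm.mask & (peak >= threshold), winner + 1, 0).astype(np.int32)
    return SegmentationVolume(labels=labels, threshold=float(threshold))


def group_statistics(pms: list[ProbabilityMaps]) -> GroupMaps:
    """Voxelwise mean and sample SD (n-1 denominator) across subjects.

    snr = mean/SD where SD > 0, else 0 (degenerate voxels are flagged as 0
    rather than infinite so group maps stay finite).
    """
    if len(pms) < 2:
        raise ValueError("group statistics require >= 2 subjects")
    shapes = {pm.probs.shape for pm in pms}
    if len(shapes) != 1:
        raise ValueError("all probability maps must share one shape")
    stack = np.stack([pm.probs for pm in pms])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    # voxels with (numerically) zero spread get snr 0 rather than +inf
    nonzero = std > 1e-12
    snr = np.divide(mean, std, out=np.zeros_like(mean), where=nonzero) * nonzero
    gm = GroupMaps(mean=mean, std=std, snr=snr, networks=pms[0].networks)
    gm.validate()
    return gm


def network_summary(
    gm: GroupMaps, seg: SegmentationVolume, mask: np.ndarray
) -> pd.DataFrame:
    """Per-network mean probability and mean/SD over its WTA region, plus the
    area fraction (WTA voxels / mask voxels). Empty regions yield NaN summaries."""
    k = gm.mean.shape[0]
    n_mask = int(mask.sum())
    rows = []
    for net in range(k):
        region = (seg.labels == net + 1) & mask
        n = int(region.sum())
        name = gm.networks[net] if net < len(gm.networks) else f"net{net}"
        if n == 0:
            rows.append((name, np.nan, np.nan, 0.0, 0))
        else:
            rows.append(
                (
                    name,
                    float(gm.mean[net][region].mean()),
                    float(gm.snr[net][region].mean()),
                    n / n_mask,
                    n,
                )
            )
    return pd.DataFrame(
        rows, columns=["network", "mean_prob", "mean_over_std", "area_fraction", "n_voxels"]
    )


def suprathreshold_counts(
    probs: np.ndarray, mask: np.ndarray, thresholds
) -> pd.DataFrame:
    """In-mask voxel counts with probs[k] >= t, per network and threshold."""
    thresholds = list(thresholds)
    if any(t < 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    k = probs.shape[0]
    inm = probs[:, mask]
    rows = []
    for net in range(k):
        for t in thresholds:
            rows.append((net, t, int((inm[net] >= t).sum())))
    return pd.DataFrame(rows, columns=["network", "threshold", "count"])


def dice_vs_planted(
    seg: SegmentationVolume, atlas: PhantomAtlas, restrict_to_rois: bool = True
) -> dict[str, float]:
    """Per-network Dice between WTA labels and the planted network labels.

    By default the comparison runs over the ROI support only: background
    (non-ROI) in-mask voxels carry deliberate latent mixtures and have no
    planted label, so they are not counted against recovery.
    """
    truth = atlas.network_label_volume()
    support = truth > 0 if restrict_to_rois else atlas.mask
    out = {}
    for net in range(atlas.n_networks):
        a = (seg.labels == net + 1) & support
        b = truth == net + 1
        denom = int(a.sum() + b.sum())
        out[atlas.networks[net]] = 2.0 * int((a & b).sum()) / denom if denom else np.nan
    return out
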