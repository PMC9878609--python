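"""Robustness protocols and connectivity matrices.

Frame truncation and per-voxel pink-noise injection probe how stable the
voxelwise probability maps are when the scan is shortened or corrupted; map
agreement is scored by network-averaged MS-SSIM against the maps from the
full, clean scan. Softmax-probability correlation matrices put the
classifier's outputs side by side with conventional time-series functional
connectivity at the voxel and ROI level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import ProbabilityMaps, voxelwise_probability_maps
from .model.training import TrainedModel
from .mssi import MssiSpec, fitting_scale_factors, mssi
from .phantom import PhantomAtlas
from .signals import pink_noise_matrix, pink_noise_series  # noqa: F401  (re-export)
from .simulate import BoldScan


@dataclass(frozen=True)
class NoiseSpec:
    """Pink-noise injection: ``fraction`` is the noise share of the mixed signal."""

    fraction: float
    pink_exponent: float = 1.0
    per_voxel: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("noise fraction must lie in [0, 1)")


@dataclass
class RobustnessCurve:
    levels: list
    values: list[float]
    per_network: dict[str, list[float]] = field(default_factory=dict)
    reference: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"level": self.levels, "mssi": self.values})
        for name, vals in self.per_network.items():
            df[f"mssi_{name}"] = vals
        return df


@dataclass(frozen=True)
class ConnMatrix:
    matrix: np.ndarray
    node_networks: np.ndarray  # network index per node, in node order
    kind: str  # "softmax" | "timeseries"
    level: str  # "voxel" | "roi"

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")

    def block_means(self) -> tuple[float, float]:
        """(mean within-network off-diagonal value, mean between-network value)."""
        nets = self.node_networks
        same = nets[:, None] == nets[None, :]
        off = ~np.eye(len(nets), dtype=bool)
        return (
            float(self.matrix[same & off].mean()),
            float(self.matrix[~same].mean()),
        )


def _rescale_to(x: np.ndarray, bound: float) -> np.ndarray:
    """Affine map of [min, max] onto [-bound, +bound] per row; constant rows -> 0."""
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(x)
    np.divide(x - lo, span, out=out, where=span > 0)
    return (2.0 * out - 1.0) * bound * (span > 0)


def truncate_scan(scan: BoldScan, n_frames: int) -> BoldScan:
    """Keep the first ``n_frames`` frames (the scan is unchanged if n >= T)."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if n_frames >= scan.n_frames:
        return scan
    return BoldScan(
        data=scan.data[..., :n_frames].copy(),
        tr=scan.tr,
        mask=scan.mask,
        subject_id=scan.subject_id,
    )


def inject_noise(scan: BoldScan, spec: NoiseSpec, rng_seed: int = 0) -> BoldScan:
    """Interval-rescaling pink-noise injection.

    Per in-mask voxel the signal is affinely rescaled so its min/max hit
    +-(1 - f), an independent pink-noise series is rescaled to +-f, and the
    two are summed (e.g. f = 0.1: signal in [-0.9, 0.9], noise in
    [-0.1, 0.1]). Constant-series voxels pass through as pure noise.
    """
    f = spec.fraction
    mask_idx = np.argwhere(scan.mask)
    series = scan.data[tuple(mask_idx.T)]
    out = _rescale_to(series, 1.0 - f)
    if f > 0:
        rng = np.random.default_rng(rng_seed)
        noise = pink_noise_matrix(
            len(mask_idx), scan.n_frames, rng, exponent=spec.pink_exponent
        )
        out = out + _rescale_to(noise, f)
    data = np.zeros_like(scan.data)
    data[tuple(mask_idx.T)] = out
    return BoldScan(data=data, tr=scan.tr, mask=scan.mask, subject_id=scan.subject_id)


def _network_averaged_mssi(
    pm_a: ProbabilityMaps, pm_b: ProbabilityMaps, spec: MssiSpec | None
) -> tuple[float, list[float]]:
    if spec is None:
        factors = fitting_scale_factors(pm_a.mask.shape)
        spec = MssiSpec(scale_factors=factors)
    per_net = [
        mssi(pm_a.probs[k], pm_b.probs[k], spec) for k in range(pm_a.n_networks)
    ]
    return float(np.mean(per_net)), per_net


def robustness_frames(
    model: TrainedModel,
    scan: BoldScan,
    mask: np.ndarray | None = None,
    frame_grid: tuple[int, ...] = (150, 300, 600),
    mssi_spec: MssiSpec | None = None,
    reference_pm: ProbabilityMaps | None = None,
) -> RobustnessCurve:
    """MS-SSIM of probability maps from truncated scans vs the full scan."""
    if max(frame_grid) > scan.n_frames:
        raise ValueError("frame_grid entries must not exceed the scan length")
    ref = reference_pm or voxelwise_probability_maps(model, scan, mask)
    nets = ref.networks or tuple(f"net{k}" for k in range(ref.n_networks))
    values, per_net = [], {n: [] for n in nets}
    for n in frame_grid:
        pm = voxelwise_probability_maps(model, truncate_scan(scan, n), mask)
        avg, by_net = _network_averaged_mssi(pm, ref, mssi_spec)
        values.append(avg)
        for name, v in zip(nets, by_net):
            per_net[name].append(v)
    return RobustnessCurve(
        levels=list(frame_grid),
        values=values,
        per_network=per_net,
        reference=f"full scan ({scan.n_frames} frames)",
    )


def robustness_noise(
    model: TrainedModel,
    scan: BoldScan,
    mask: np.ndarray | None = None,
    fraction_grid: tuple[float, ...] = (0.1, 0.25, 0.5),
    rng_seed: int = 0,
    mssi_spec: MssiSpec | None = None,
    reference_pm: ProbabilityMaps | None = None,
) -> RobustnessCurve:
    """MS-SSIM of probability maps from noise-injected scans vs the clean scan."""
    ref = reference_pm or voxelwise_probability_maps(model, scan, mask)
    nets = ref.networks or tuple(f"net{k}" for k in range(ref.n_networks))
    values, per_net = [], {n: [] for n in nets}
    for i, f in enumerate(fraction_grid):
        noisy = inject_noise(scan, NoiseSpec(fraction=f), rng_seed=rng_seed + i)
        pm = voxelwise_probability_maps(model, noisy, mask)
        avg, by_net = _network_averaged_mssi(pm, ref, mssi_spec)
        values.append(avg)
        for name, v in zip(nets, by_net):
            per_net[name].append(v)
    return RobustnessCurve(
        levels=list(fraction_grid),
        values=values,
        per_network=per_net,
        reference="clean scan",
    )


def _roi_node_order(atlas: PhantomAtlas) -> tuple[np.ndarray, np.ndarray]:
    """ROI voxel coordinates and network index per voxel, ordered by network."""
    coords, nets = [], []
    order = sorted(atlas.rois, key=lambda r: (r.network_index, r.roi_id))
    for roi in order:
        coords.append(roi.voxels)
        nets.extend([roi.network_index] * len(roi.voxels))
    return np.concatenate(coords, axis=0), np.asarray(nets)


def _corr(rows: np.ndarray, kind_msg: str) -> np.ndarray:
    sd = rows.std(axis=1)
    if (sd == 0).any():
        raise ValueError(f"degenerate (constant) {kind_msg} — cannot correlate")
    m = np.corrcoef(rows)
    np.fill_diagonal(m, 1.0)
    return np.clip((m + m.T) / 2.0, -1.0, 1.0)


def softmax_connectivity(
    pms: ProbabilityMaps | list[ProbabilityMaps],
    atlas: PhantomAtlas,
    level: str = "roi",
) -> ConnMatrix:
    """Correlate per-voxel (or ROI-averaged) softmax probability vectors.

    Nodes are the atlas ROI voxels (which carry a network identity), ordered
    by network; for a list of subjects the per-subject correlation matrices
    are averaged.
    """
    if isinstance(pms, ProbabilityMaps):
        pms = [pms]
    coords, nets = _roi_node_order(atlas)
    mats = []
    for pm in pms:
        vecs = pm.probs[:, coords[:, 0], coords[:, 1], coords[:, 2]].T  # (nodes, K)
        if level == "roi":
            rois = sorted(atlas.rois, key=lambda r: (r.network_index, r.roi_id))
            rows, rnets, start = [], [], 0
            for roi in rois:
                rows.append(vecs[start : start + len(roi.voxels)].mean(axis=0))
                rnets.append(roi.network_index)
                start += len(roi.voxels)
            mats.append(_corr(np.asarray(rows), "ROI probability vector"))
            node_nets = np.asarray(rnets)
        elif level == "voxel":
            mats.append(_corr(vecs, "voxel probability vector"))
            node_nets = nets
        else:
            raise ValueError("level must be 'voxel' or 'roi'")
    cm = ConnMatrix(
        matrix=np.mean(mats, axis=0), node_networks=node_nets, kind="softmax", level=level
    )
    return cm


def timeseries_connectivity(
    scan: BoldScan, atlas: PhantomAtlas, level: str = "roi"
) -> ConnMatrix:
    """Pearson correlation of voxel or ROI-mean BOLD series, network-ordered."""
    coords, nets = _roi_node_order(atlas)
    series = scan.series(coords)
    if level == "roi":
        rois = sorted(atlas.rois, key=lambda r: (r.network_index, r.roi_id))
        rows, rnets, start = [], [], 0
        for roi in rois:
            rows.append(series[start : start + len(roi.voxels)].mean(axis=0))
            rnets.append(roi.network_index)
            start += len(roi.voxels)
        return ConnMatrix(
            matrix=_corr(np.asarray(rows), "ROI series"),
            node_networks=np.asarray(rnets),
            kind="timeseries",
            level=level,
        )
    if level == "voxel":
        return ConnMatrix(
            matrix=_corr(series, "voxel series"),
            node_networks=nets,
            kind="timeseries",
            level=level,
        )
    raise ValueError("level must be 'voxel' or 'roi'")
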