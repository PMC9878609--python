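"""Phantom atlases: planted network/ROI geometry for fully synthetic experiments.

A phantom atlas plays the role a network-labeled ROI parcellation plays for real
resting-state data: it fixes a gray-matter mask, a set of K named networks, and a
collection of spherical seed ROIs, each owned by exactly one network. Everything
downstream (simulation, training-sample construction, recovery scoring) refers to
this planted geometry as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 13 canonical resting-state network names used for full-size atlases:
#: dorsal/lateral somatomotor, cinguloopercular, auditory, default mode, parietal
#: memory, visual, frontoparietal, salience, ventral/dorsal attention, medial
#: temporal, reward.
CANONICAL_NETWORKS = (
    "SMD", "SML", "CON", "AUD", "DMN", "PMN", "VIS",
    "FPN", "SAL", "VAN", "DAN", "MTL", "REW",
)


class PlacementError(RuntimeError):
    """Raised when disjoint ROI spheres cannot be placed in the requested grid."""


@dataclass(frozen=True)
class Roi:
    """One spherical seed region: id, owning network index, and voxel coordinates."""

    roi_id: int
    network_index: int
    voxels: np.ndarray  # (n_vox, 3) int array of 0-based voxel indices

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.intp)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
            raise ValueError("Roi.voxels must be a non-empty (n, 3) index array")
        object.__setattr__(self, "voxels", v)


@dataclass(frozen=True)
class PhantomAtlas:
    """Planted spatial structure: mask, ordered networks, and disjoint ROIs."""

    grid_shape: tuple[int, int, int]
    mask: np.ndarray
    networks: tuple[str, ...]
    rois: tuple[Roi, ...] = field(default_factory=tuple)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def rois_of_network(self, network_index: int) -> list[Roi]:
        return [r for r in self.rois if r.network_index == network_index]

    def network_voxels(self, network_index: int) -> np.ndarray:
        """All voxel coordinates of a network's ROIs, stacked."""
        rois = self.rois_of_network(network_index)
        if not rois:
            return np.empty((0, 3), dtype=np.intp)
        return np.concatenate([r.voxels for r in rois], axis=0)

    def label_volume(self) -> np.ndarray:
        """ROI-id volume (0 = no ROI, ids are 1-based)."""
        lab = np.zeros(self.grid_shape, dtype=np.int32)
        for roi in self.rois:
            lab[tuple(roi.voxels.T)] = roi.roi_id
        return lab

    def network_label_volume(self) -> np.ndarray:
        """Planted network volume (0 = background, 1..K = network index + 1)."""
        lab = np.zeros(self.grid_shape, dtype=np.int32)
        for roi in self.rois:
            lab[tuple(roi.voxels.T)] = roi.network_index + 1
        return lab

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.mask.shape != tuple(self.grid_shape) or self.mask.dtype != bool:
            raise ValueError("mask must be a boolean volume of grid_shape")
        k = self.n_networks
        seen: set[tuple[int, int, int]] = set()
        per_net = np.zeros(k, dtype=int)
        for roi in self.rois:
            if not 0 <= roi.network_index < k:
                raise ValueError(f"ROI {roi.roi_id}: network index out of range")
            per_net[roi.network_index] += 1
            if not self.mask[tuple(roi.voxels.T)].all():
                raise ValueError(f"ROI {roi.roi_id} leaves the mask")
            vox = set(map(tuple, roi.voxels.tolist()))
            if vox & seen:
                raise ValueError(f"ROI {roi.roi_id} overlaps another ROI")
            seen |= vox
        if (per_net == 0).any():
            raise ValueError("every network must own at least one ROI")


def _sphere_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def make_phantom_atlas(
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    n_networks: int = 4,
    rois_per_network: int = 3,
    roi_radius: int = 1,
    rng_seed: int = 0,
    mask: np.ndarray | None = None,
    max_attempts: int = 5000,
) -> PhantomAtlas:
    """Place ``n_networks x rois_per_network`` disjoint spheres inside a mask.

    The mask defaults to an ellipsoidal "brain" filling the grid. Sphere centers
    are drawn uniformly from mask-interior candidate positions (rejection
    sampling), so placement is deterministic given ``rng_seed``.

    Raises
    ------
    PlacementError
        If the requested number of disjoint spheres cannot be placed within
        ``max_attempts`` draws (capacity exceeded).
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 1:
        raise ValueError("grid_shape must be 3 positive integers")
    if n_networks < 1 or rois_per_network < 1 or roi_radius < 0:
        raise ValueError("n_networks, rois_per_network >= 1; roi_radius >= 0")

    if mask is None:
        c = (np.array(grid_shape) - 1) / 2.0
        semi = np.maximum(np.array(grid_shape) / 2.0 - 0.5, 0.5)
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
        mask = ((ii - c[0]) / semi[0]) ** 2 + ((jj - c[1]) / semi[1]) ** 2 + (
            (kk - c[2]) / semi[2]
        ) ** 2 <= 1.0
    mask = np.asarray(mask, dtype=bool)

    if n_networks <= len(CANONICAL_NETWORKS):
        networks = CANONICAL_NETWORKS[:n_networks]
    else:
        networks = CANONICAL_NETWORKS + tuple(
            f"NET{i}" for i in range(len(CANONICAL_NETWORKS), n_networks)
        )

    offsets = _sphere_offsets(roi_radius)
    rng = np.random.default_rng(rng_seed)

    # candidate centers: sphere fully inside mask
    centers = np.argwhere(mask)
    fits = np.ones(len(centers), dtype=bool)
    for i, ctr in enumerate(centers):
        pts = ctr + offsets
        if (pts < 0).any() or (pts >= np.array(grid_shape)).any():
            fits[i] = False
        elif not mask[tuple(pts.T)].all():
            fits[i] = False
    candidates = centers[fits]
    if len(candidates) == 0:
        raise PlacementError("no sphere of this radius fits inside the mask")

    occupied = np.zeros(grid_shape, dtype=bool)
    rois: list[Roi] = []
    roi_id = 1
    attempts = 0
    for net in range(n_networks):
        for _ in range(rois_per_network):
            while True:
                attempts += 1
                if attempts > max_attempts:
                    raise PlacementError(
                        f"could not place {n_networks * rois_per_network} disjoint "
                        f"spheres of radius {roi_radius} in grid {grid_shape} "
                        f"after {max_attempts} attempts"
                    )
                ctr = candidates[rng.integers(len(candidates))]
                pts = ctr + offsets
                if occupied[tuple(pts.T)].any():
                    continue
                occupied[tuple(pts.T)] = True
                rois.append(Roi(roi_id=roi_id, network_index=net, voxels=pts))
                roi_id += 1
                break

    atlas = PhantomAtlas(
        grid_shape=grid_shape, mask=mask, networks=tuple(networks), rois=tuple(rois)
    )
    atlas.validate()
    return atlas
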