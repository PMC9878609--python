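"""Standard-format I/O: NIfTI-1 volumes, TSV tables, HDF5 sample stores.

Phantoms use an identity affine and 0-based voxel indexing throughout; 4D
arrays are ordered (x, y, z, t-or-network).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomAtlas, Roi
from .similarity import SimilaritySample
from .simulate import BoldScan


class MalformedFileError(IOError):
    """The file could not be parsed as a NIfTI-1 volume."""


def write_nifti(volume: np.ndarray, path, tr: float | None = None) -> None:
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    if tr is not None and vol.ndim == 4:
        img.header["pixdim"][4] = tr
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Return (data, affine, header summary); round-trips write_nifti bit-exactly."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise MalformedFileError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    header = {
        "dim": int(img.header["dim"][0]),
        "shape": tuple(img.shape),
        "dtype": str(data.dtype),
        "pixdim": tuple(float(x) for x in img.header["pixdim"][1:5]),
    }
    return data, img.affine, header


def save_scan(scan: BoldScan, path) -> None:
    write_nifti(scan.data, path, tr=scan.tr)


def load_scan(path, mask: np.ndarray, subject_id: str | None = None) -> BoldScan:
    data, _, header = read_nifti(path)
    tr = header["pixdim"][3] or 1.0
    return BoldScan(
        data=np.asarray(data, dtype=float),
        tr=float(tr),
        mask=np.asarray(mask, dtype=bool),
        subject_id=subject_id or Path(str(path)).stem,
    )


def save_atlas(atlas: PhantomAtlas, label_path, tsv_path, mask_path=None) -> None:
    """ROI-label NIfTI (ids 1-based) + ``roi_id<TAB>network_name`` TSV."""
    write_nifti(atlas.label_volume(), label_path)
    rows = [(r.roi_id, atlas.networks[r.network_index]) for r in atlas.rois]
    pd.DataFrame(rows, columns=["roi_id", "network_name"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    if mask_path is not None:
        write_nifti(atlas.mask, mask_path)


def load_atlas(label_path, tsv_path, mask_path=None) -> PhantomAtlas:
    labels, _, _ = read_nifti(label_path)
    labels = np.asarray(labels).astype(np.int32)
    table = pd.read_csv(tsv_path, sep="\t")
    networks = tuple(dict.fromkeys(table["network_name"]))  # first-seen order
    net_index = {n: i for i, n in enumerate(networks)}
    rois = []
    for roi_id, net in zip(table["roi_id"], table["network_name"]):
        voxels = np.argwhere(labels == roi_id)
        rois.append(Roi(roi_id=int(roi_id), network_index=net_index[net], voxels=voxels))
    if mask_path is not None:
        mask, _, _ = read_nifti(mask_path)
        mask = np.asarray(mask).astype(bool)
    else:
        mask = labels > 0
    atlas = PhantomAtlas(
        grid_shape=labels.shape, mask=mask, networks=networks, rois=tuple(rois)
    )
    atlas.validate()
    return atlas


def save_samples(samples: list[SimilaritySample], path) -> None:
    """HDF5 container with ``channels``, ``label`` and ``subject_id`` datasets."""
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "channels", data=np.stack([s.channels for s in samples]).astype(np.float32)
        )
        f.create_dataset("label", data=np.array([s.label for s in samples]))
        f.create_dataset(
            "subject_id",
            data=np.array([s.subject_id for s in samples], dtype=h5py.string_dtype()),
        )


def load_samples(path) -> list[SimilaritySample]:
    with h5py.File(path, "r") as f:
        channels = f["channels"][:]
        labels = f["label"][:]
        subjects = [s.decode() for s in f["subject_id"][:]]
    return [
        SimilaritySample(channels=c.astype(float), label=int(l), subject_id=s)
        for c, l, s in zip(channels, labels, subjects)
    ]


def write_sidecar(path, seed: int, config: dict, stage: str) -> None:
    """JSON provenance sidecar written next to every pipeline artifact."""
    payload = {"stage": stage, "seed": seed, "config": config}
    Path(str(path)).write_text(json.dumps(payload, indent=2, default=str))
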