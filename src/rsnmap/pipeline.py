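"""End-to-end pipeline: simulate -> samples -> train -> infer -> group stats -> evaluate.

Every stage writes its artifacts with a JSON sidecar recording the stage name,
the master seed, and the stage configuration; re-running with the same
configuration reproduces all deterministic artifacts. The master seed fans
out into fixed named substreams per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from .evaluation import robustness_frames, robustness_noise
from .inference import (
    group_statistics,
    network_summary,
    voxelwise_probability_maps,
    wta_segmentation,
)
from .model import CnnConfig, DenseResNet3D, TrainSchedule, save_model, train_model
from .phantom import make_phantom_atlas
from .similarity import AugmentParams, build_training_set
from .simulate import SimulationSpec, simulate_cohort

log = logging.getLogger("rsnmap")

# fixed per-stage seed offsets fanned out from the master seed
_STAGE_OFFSETS = {"atlas": 1, "cohort": 2, "samples": 3, "train": 4, "noise": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    return int((master_seed * 1009 + _STAGE_OFFSETS[stage]) % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full phantom run (desk-scale defaults)."""

    out_dir: str = "rsnmap_run"
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_networks: int = 4
    rois_per_network: int = 3
    roi_radius: int = 1
    n_subjects: int = 3
    n_frames: int = 300
    tr: float = 2.2
    samples_per_network: int = 50
    val_subject_fraction: float = 0.34
    wta_threshold: float = 0.2
    frame_grid: tuple[int, ...] = (150, 300)
    noise_grid: tuple[float, ...] = (0.1, 0.25)
    rng_seed: int = 0
    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    augment: AugmentParams = field(default_factory=AugmentParams)
    cnn: dict = field(default_factory=dict)  # CnnConfig overrides
    schedule: dict = field(default_factory=dict)  # TrainSchedule overrides

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, run_evaluation: bool = True) -> Path:
    """Execute every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    (out / "run_config.json").write_text(json.dumps(cfg_dict, indent=2, default=str))

    log.info("stage: simulate")
    atlas = make_phantom_atlas(
        config.grid_shape,
        config.n_networks,
        config.rois_per_network,
        config.roi_radius,
        rng_seed=stage_seed(config.rng_seed, "atlas"),
    )
    rio.save_atlas(atlas, out / "atlas_rois.nii", out / "atlas_rois.tsv", out / "mask.nii")
    rio.write_sidecar(out / "atlas_rois.json", config.rng_seed, cfg_dict, "simulate")
    scans = simulate_cohort(
        atlas,
        config.simulation,
        config.n_subjects,
        n_frames=config.n_frames,
        tr=config.tr,
        rng_seed=stage_seed(config.rng_seed, "cohort"),
    )
    for scan in scans:
        rio.save_scan(scan, out / f"{scan.subject_id}_bold.nii")

    log.info("stage: build-samples")
    tset = build_training_set(
        scans,
        atlas,
        samples_per_network=config.samples_per_network,
        val_subject_fraction=config.val_subject_fraction,
        aug=config.augment,
        rng_seed=stage_seed(config.rng_seed, "samples"),
    )
    rio.save_samples(tset.samples, out / "samples.h5")
    rio.write_sidecar(out / "samples.json", config.rng_seed, cfg_dict, "build-samples")

    log.info("stage: train")
    cnn = CnnConfig(n_classes=atlas.n_networks, **config.cnn)
    sched = TrainSchedule(
        rng_seed=stage_seed(config.rng_seed, "train"), **config.schedule
    )
    model = DenseResNet3D(cnn, rng_seed=sched.rng_seed)
    trained = train_model(model, tset, sched)
    save_model(trained.model, out / "model.npz")
    trained.history_frame().to_csv(out / "history.tsv", sep="\t", index=False)
    rio.write_sidecar(out / "model.json", config.rng_seed, cfg_dict, "train")

    log.info("stage: infer + group-stats")
    pms = [
        voxelwise_probability_maps(trained, scan, networks=atlas.networks)
        for scan in scans
    ]
    for pm in pms:
        rio.write_nifti(np.moveaxis(pm.probs, 0, -1), out / f"{pm.subject_id}_probs.nii")
    (out / "networks.json").write_text(json.dumps(list(atlas.networks)))
    gm = group_statistics(pms) if len(pms) > 1 else None
    if gm is not None:
        rio.write_nifti(np.moveaxis(gm.mean, 0, -1), out / "group_mean.nii")
        rio.write_nifti(np.moveaxis(gm.std, 0, -1), out / "group_std.nii")
        rio.write_nifti(np.moveaxis(gm.snr, 0, -1), out / "group_snr.nii")
        mean_pm = ProbabilityMapsFromGroup(gm, pms[0].mask)
        seg = wta_segmentation(mean_pm, threshold=0.0)
        rio.write_nifti(seg.labels, out / "wta.nii")
        summary = network_summary(gm, seg, pms[0].mask)
        summary.to_csv(out / "network_summary.tsv", sep="\t", index=False)
    rio.write_sidecar(out / "group_maps.json", config.rng_seed, cfg_dict, "group-stats")

    if run_evaluation:
        log.info("stage: evaluate")
        scan = scans[0]
        frames = tuple(n for n in config.frame_grid if n <= scan.n_frames)
        rf = robustness_frames(trained, scan, frame_grid=frames)
        rf.to_frame().to_csv(out / "robustness_frames.tsv", sep="\t", index=False)
        rn = robustness_noise(
            trained,
            scan,
            fraction_grid=config.noise_grid,
            rng_seed=stage_seed(config.rng_seed, "noise"),
        )
        rn.to_frame().to_csv(out / "robustness_noise.tsv", sep="\t", index=False)
        rio.write_sidecar(out / "evaluate.json", config.rng_seed, cfg_dict, "evaluate")
    return out


def ProbabilityMapsFromGroup(gm, mask):
    """View the group-mean maps as a ProbabilityMaps (the mean of simplex
    vectors is a simplex vector, so the invariants carry over)."""
    from .inference import ProbabilityMaps

    return ProbabilityMaps(probs=gm.mean, subject_id="group-mean", mask=mask, networks=gm.networks)


def make_fixtures(out_dir, size: str = "tiny", rng_seed: int = 0) -> Path:
    """Self-contained fixture bundle: atlas, cohort, samples, golden outputs."""
    presets = {
        "tiny": dict(grid_shape=(12, 12, 12), n_networks=3, n_subjects=2,
                     n_frames=120, samples_per_network=6, val_subject_fraction=0.5),
        "small": dict(grid_shape=(16, 16, 16), n_networks=4, n_subjects=3,
                      n_frames=200, samples_per_network=20, val_subject_fraction=0.34),
    }
    if size not in presets:
        raise ValueError("size must be 'tiny' or 'small'")
    p = presets[size]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = make_phantom_atlas(
        p["grid_shape"], p["n_networks"], 3, 1, rng_seed=stage_seed(rng_seed, "atlas")
    )
    rio.save_atlas(atlas, out / "atlas_rois.nii", out / "atlas_rois.tsv", out / "mask.nii")
    scans = simulate_cohort(
        atlas, SimulationSpec(), p["n_subjects"], n_frames=p["n_frames"],
        rng_seed=stage_seed(rng_seed, "cohort"),
    )
    for scan in scans:
        rio.save_scan(scan, out / f"{scan.subject_id}_bold.nii")
    tset = build_training_set(
        scans, atlas, samples_per_network=p["samples_per_network"],
        val_subject_fraction=p["val_subject_fraction"],
        rng_seed=stage_seed(rng_seed, "samples"),
    )
    rio.save_samples(tset.samples, out / "samples.h5")
    # golden similarity map for oracle regression: first sample regenerated
    np.save(out / "golden_sample0.npy", tset.samples[0].channels)
    rio.write_sidecar(out / "fixtures.json", rng_seed, {"size": size}, "make-fixtures")
    return out
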