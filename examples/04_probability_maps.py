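"""Per-voxel network membership maps, WTA segmentation, and group statistics.

Every in-mask voxel acts as its own seed: its similarity map is classified and
the softmax vector stored at that voxel. Group maps aggregate subjects into
voxelwise mean, SD, and mean/SD; the winner-take-all segmentation and network
summary mirror a probabilistic atlas workflow.
"""
import numpy as np

import rsnmap as rm
from rsnmap.model import CnnConfig, DenseResNet3D, TrainSchedule, train_model

atlas = rm.make_phantom_atlas((16, 16, 16), 3, 3, roi_radius=1, rng_seed=5)
spec = rm.SimulationSpec()
cohort = rm.simulate_cohort(atlas, spec, 4, n_frames=200, rng_seed=5)
tset = rm.build_training_set(cohort, atlas, samples_per_network=60,
                             val_subject_fraction=0.25, rng_seed=5)
trained = train_model(DenseResNet3D(CnnConfig(n_classes=3), rng_seed=5), tset,
                      TrainSchedule(max_epochs=8, rng_seed=5))

pms = [rm.voxelwise_probability_maps(trained, s, networks=atlas.networks)
       for s in cohort]
gm = rm.group_statistics(pms)
seg = rm.wta_segmentation(pms[0], threshold=0.0)
dice = rm.dice_vs_planted(seg, atlas)
print("per-network Dice of WTA labels vs planted ROI labels:",
      {k: round(v, 3) for k, v in dice.items()})

from rsnmap.inference import ProbabilityMaps
group_pm = ProbabilityMaps(gm.mean, "group", pms[0].mask, atlas.networks)
summary = rm.network_summary(gm, rm.wta_segmentation(group_pm, 0.0), atlas.mask)
print("\ngroup summary (mean probability / mean over SD / area fraction):")
print(summary.to_string(index=False))
print("\n(high mean with low SD marks core network voxels; area fractions over "
      "the WTA partition sum to <= 1)")
counts = rm.suprathreshold_counts(gm.mean, atlas.mask, [0.2, 0.5, 0.8])
print("\nsuprathreshold voxel counts (non-increasing in the threshold):")
print(counts.pivot(index="network", columns="threshold", values="count"))
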