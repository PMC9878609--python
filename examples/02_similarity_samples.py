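"""Build labeled seed-similarity training samples from a synthetic cohort.

Each sample correlates the mean signal of a random subset of one network's
ROIs with every voxel (Pearson channel) and records the z-scored Euclidean
distance (second channel); the label is kept only if the seed correlates best
with its own network's mean signal.
"""
import numpy as np

import rsnmap as rm

atlas = rm.make_phantom_atlas((16, 16, 16), 4, 3, roi_radius=1, rng_seed=0)
cohort = rm.simulate_cohort(atlas, rm.SimulationSpec(), 3, n_frames=300, rng_seed=0)

tset = rm.build_training_set(cohort, atlas, samples_per_network=20,
                             val_subject_fraction=0.34, rng_seed=0)
print(f"samples: {len(tset.samples)}  (train {len(tset.indices('train'))}, "
      f"validation {len(tset.indices('val'))}; whole subjects held out)")
print(f"class counts : {tset.class_counts.tolist()}")
print(f"class weights: {tset.class_weights.round(3).tolist()} "
      "(N/(K*count): balanced counts give 1.0)")
print(f"discarded by label confirmation: {tset.n_discarded}")

s = tset.samples[0]
r = s.channels[0][atlas.mask]
print(f"sample 0: network {atlas.networks[s.label]}, subject {s.subject_id}")
print(f"  Pearson channel range  [{r.min():+.2f}, {r.max():+.2f}] "
      "(1.0 at the seed region itself)")
print(f"  distance channel range [{s.channels[1][atlas.mask].min():.2f}, "
      f"{s.channels[1][atlas.mask].max():.2f}] (0 at the seed)")
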