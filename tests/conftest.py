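import numpy as np
import pytest

import rsnmap as rm


@pytest.fixture(scope="session")
def tiny_atlas():
    return rm.make_phantom_atlas((12, 12, 12), n_networks=3, rois_per_network=2,
                                 roi_radius=1, rng_seed=5)


@pytest.fixture(scope="session")
def tiny_scan(tiny_atlas):
    return rm.simulate_scan(tiny_atlas, rm.SimulationSpec(), n_frames=120, tr=2.2,
                            subject_id="sub-000", rng_seed=3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_atlas):
    return rm.simulate_cohort(tiny_atlas, rm.SimulationSpec(), n_subjects=3,
                              n_frames=120, tr=2.2, rng_seed=3)


@pytest.fixture(scope="session")
def clean_scan(tiny_atlas):
    """Noise-free scan with independent network latents (planted structure exact)."""
    spec = rm.SimulationSpec(noise_sd=0.0, subject_jitter=0.0)
    return rm.simulate_scan(tiny_atlas, spec, n_frames=120, tr=2.2,
                            subject_id="clean", rng_seed=9)
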