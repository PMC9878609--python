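import numpy as np
import pytest

import rsnmap as rm
from rsnmap.similarity import (
    LabelTieError,
    compute_class_weights,
    make_sample,
    _augment_matrix,
)
from rsnmap.simulate import BoldScan


def _toy_scan(series_by_voxel, shape=(3, 3, 3)):
    """Scan whose first in-mask voxels carry the given series (rest zero-masked)."""
    t = len(next(iter(series_by_voxel.values())))
    data = np.zeros(shape + (t,))
    mask = np.zeros(shape, dtype=bool)
    for vox, series in series_by_voxel.items():
        data[vox] = np.asarray(series, dtype=float)
        mask[vox] = True
    return BoldScan(data=data, tr=1.0, mask=mask, subject_id="toy")


class TestMeanSeedSignal:
    def test_single_voxel_is_identity(self):
        scan = _toy_scan({(0, 0, 0): [1.0, 2.0, 5.0]})
        out = rm.mean_seed_signal(scan, np.array([[0, 0, 0]]))
        np.testing.assert_array_equal(out, [1.0, 2.0, 5.0])

    def test_two_voxel_arithmetic_mean(self):
        scan = _toy_scan({(0, 0, 0): [1.0, 2.0], (1, 0, 0): [3.0, 4.0]})
        out = rm.mean_seed_signal(scan, np.array([[0, 0, 0], [1, 0, 0]]))
        np.testing.assert_allclose(out, [2.0, 3.0])

    def test_empty_and_out_of_mask_rejected(self, tiny_scan):
        with pytest.raises(ValueError):
            rm.mean_seed_signal(tiny_scan, np.empty((0, 3), dtype=int))
        outside = np.argwhere(~tiny_scan.mask)[:1]
        with pytest.raises(ValueError):
            rm.mean_seed_signal(tiny_scan, outside)


class TestSimilarityMap:
    def test_identical_voxel_r1_d0(self):
        scan = _toy_scan({(0, 0, 0): [1.0, 2.0, 3.0], (1, 1, 1): [1.0, 2.0, 3.0]})
        sm = rm.similarity_map(scan, np.array([1.0, 2.0, 3.0]))
        assert sm[0, 1, 1, 1] == pytest.approx(1.0)
        assert sm[1, 1, 1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_voxel(self):
        scan = _toy_scan({(0, 0, 0): [3.0, 2.0, 1.0]})
        sm = rm.similarity_map(scan, np.array([1.0, 2.0, 3.0]))
        assert sm[0, 0, 0, 0] == pytest.approx(-1.0)

    def test_hand_computed_distance(self):
        # z-scores [-1,0,1] vs [1,0,-1]: ||diff|| = sqrt(8), / sqrt(3)
        scan = _toy_scan({(0, 0, 0): [3.0, 2.0, 1.0]})
        sm = rm.similarity_map(scan, np.array([1.0, 2.0, 3.0]))
        assert sm[1, 0, 0, 0] == pytest.approx(np.sqrt(8 / 3), rel=1e-12)

    def test_zero_variance_voxel_convention(self):
        scan = _toy_scan({(0, 0, 0): [5.0, 5.0, 5.0]})
        sm = rm.similarity_map(scan, np.array([1.0, 2.0, 3.0]))
        assert sm[0, 0, 0, 0] == 0.0
        # distance against the zero vector: ||z_seed|| / sqrt(T) = sqrt((T-1)/T)
        assert sm[1, 0, 0, 0] == pytest.approx(np.sqrt(2 / 3))

    def test_zero_variance_seed_rejected(self, tiny_scan):
        with pytest.raises(ValueError):
            rm.similarity_map(tiny_scan, np.zeros(tiny_scan.n_frames))

    def test_matches_brute_force_pearson(self):
        """Oracle equivalence on a 6^3 grid at 1e-10."""
        rng = np.random.default_rng(0)
        shape = (6, 6, 6)
        mask = rng.random(shape) > 0.3
        data = np.where(mask[..., None], rng.standard_normal(shape + (40,)), 0.0)
        scan = BoldScan(data=data, tr=1.0, mask=mask, subject_id="rnd")
        seed = rng.standard_normal(40)
        sm = rm.similarity_map(scan, seed)
        for vox in np.argwhere(mask):
            r_brute = np.corrcoef(seed, data[tuple(vox)])[0, 1]
            assert sm[0][tuple(vox)] == pytest.approx(r_brute, abs=1e-10)

    def test_outside_mask_zero(self, tiny_scan, tiny_atlas):
        seed = rm.mean_seed_signal(tiny_scan, tiny_atlas.network_voxels(0))
        sm = rm.similarity_map(tiny_scan, seed)
        assert not sm[:, ~tiny_scan.mask].any()


class TestConfirmLabel:
    def test_planted_network_wins_noise_free(self, tiny_atlas, clean_scan):
        for net in range(tiny_atlas.n_networks):
            seed = rm.mean_seed_signal(clean_scan, tiny_atlas.network_voxels(net))
            assert rm.confirm_label(clean_scan, seed, tiny_atlas) == net

    def test_network_mean_correlates_perfectly_with_itself(self, tiny_atlas, clean_scan):
        seed = rm.mean_seed_signal(clean_scan, tiny_atlas.network_voxels(1))
        mean1 = rm.mean_seed_signal(clean_scan, tiny_atlas.network_voxels(1))
        assert np.corrcoef(seed, mean1)[0, 1] == pytest.approx(1.0)

    def test_identical_latents_tie_error(self, tiny_atlas):
        ones = np.ones((3, 3))  # all three networks share one latent
        spec = rm.SimulationSpec(cross_network_corr=ones, noise_sd=0.0)
        scan = rm.simulate_scan(tiny_atlas, spec, n_frames=60, rng_seed=1)
        seed = rm.mean_seed_signal(scan, tiny_atlas.network_voxels(0))
        with pytest.raises(LabelTieError):
            rm.confirm_label(scan, seed, tiny_atlas)


class TestAugmentation:
    def _sample(self, tiny_scan, tiny_atlas):
        seed = rm.mean_seed_signal(tiny_scan, tiny_atlas.network_voxels(0))
        return rm.SimilaritySample(
            channels=rm.similarity_map(tiny_scan, seed), label=0, subject_id="sub-000"
        )

    def test_identity_bounds_return_input(self, tiny_scan, tiny_atlas):
        s = self._sample(tiny_scan, tiny_atlas)
        params = rm.AugmentParams(rot_deg=0, trans_vox=0, shear_deg=0,
                                  intensity_range=(1.0, 1.0), gauss_sd=0.0)
        out = rm.augment_sample(s, params, rng_seed=0)
        np.testing.assert_allclose(out.channels, s.channels, atol=1e-12)

    def test_label_and_subject_preserved(self, tiny_scan, tiny_atlas):
        s = self._sample(tiny_scan, tiny_atlas)
        out = rm.augment_sample(s, rm.AugmentParams(), rng_seed=3)
        assert out.label == s.label and out.subject_id == s.subject_id

    def test_output_satisfies_sample_invariants(self, tiny_scan, tiny_atlas):
        s = self._sample(tiny_scan, tiny_atlas)
        out = rm.augment_sample(s, rm.AugmentParams(), rng_seed=3, mask=tiny_scan.mask)
        out.validate(mask=tiny_scan.mask, n_networks=3)

    def test_sampled_rotations_respect_bounds(self):
        """Brute-force check of the transform sampler over many draws."""
        params = rm.AugmentParams(rot_deg=5.0, trans_vox=3.0, shear_deg=3.0)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            mat, trans = _augment_matrix(params, rng)
            assert np.abs(trans).max() <= 3.0
            assert np.isfinite(mat).all()
        # rotation-only matrices stay orthogonal with bounded angle
        p_rot = rm.AugmentParams(rot_deg=5.0, trans_vox=0.0, shear_deg=0.0)
        for _ in range(1000):
            mat, _ = _augment_matrix(p_rot, rng)
            np.testing.assert_allclose(mat @ mat.T, np.eye(3), atol=1e-10)
            angle = np.degrees(np.arccos(np.clip((np.trace(mat) - 1) / 2, -1, 1)))
            assert angle <= 3 * 5.0 + 1e-6  # three compounded +-5 deg rotations

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            rm.AugmentParams(rot_deg=-1)
        with pytest.raises(ValueError):
            rm.AugmentParams(intensity_range=(1.1, 1.2))


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        np.testing.assert_allclose(compute_class_weights([10, 10, 10]), [1, 1, 1])

    def test_direct_formula(self):
        np.testing.assert_allclose(compute_class_weights([100, 50]), [0.75, 1.5])

    def test_balance_identity_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(1, 500, size=rng.integers(2, 10))
            w = compute_class_weights(counts)
            prods = w * counts
            np.testing.assert_allclose(prods, prods[0])
            assert (w * counts / counts.sum()).sum() == pytest.approx(1.0)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights([5, 0])


@pytest.fixture(scope="module")
def tset(tiny_cohort, tiny_atlas):
    return rm.build_training_set(
        tiny_cohort, tiny_atlas, samples_per_network=9,
        val_subject_fraction=0.34, rng_seed=2,
    )


class TestBuildTrainingSet:
    def test_counts_and_weights(self, tset, tiny_atlas):
        assert len(tset.samples) == 9 * tiny_atlas.n_networks
        np.testing.assert_array_equal(tset.class_counts, [9, 9, 9])
        np.testing.assert_allclose(tset.class_weights, 1.0)

    def test_split_is_subject_disjoint(self, tset):
        tset.validate()
        train = {tset.samples[i].subject_id for i in tset.indices("train")}
        val = {tset.samples[i].subject_id for i in tset.indices("val")}
        assert train and val and not (train & val)

    def test_all_samples_pass_validator(self, tset, tiny_atlas):
        for s in tset.samples:
            s.validate(mask=tiny_atlas.mask, n_networks=tiny_atlas.n_networks)

    def test_discard_rate_below_half(self, tset):
        assert tset.n_discarded < 0.5 * len(tset.samples)

    def test_subsample_network_rois(self, tiny_atlas):
        rois = rm.subsample_network_rois(tiny_atlas, 0, 2, rng_seed=1)
        assert len(rois) == 2 and all(r.network_index == 0 for r in rois)
        again = rm.subsample_network_rois(tiny_atlas, 0, 2, rng_seed=1)
        assert [r.roi_id for r in rois] == [r.roi_id for r in again]
        with pytest.raises(ValueError):
            rm.subsample_network_rois(tiny_atlas, 0, 5, rng_seed=1)
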