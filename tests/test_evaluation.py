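import numpy as np
import pytest

import rsnmap as rm
from rsnmap.evaluation import NoiseSpec, inject_noise, truncate_scan
from rsnmap.signals import pink_noise_series


class TestPinkNoise:
    def test_zero_mean_and_determinism(self):
        a = pink_noise_series(256, rng_seed=4)
        b = pink_noise_series(256, rng_seed=4)
        c = pink_noise_series(256, rng_seed=5)
        assert abs(a.mean()) < 1e-12
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_log_power_slope_near_minus_one(self):
        """Periodogram + least-squares oracle at T = 4096."""
        series = np.stack([pink_noise_series(4096, rng_seed=s) for s in range(10)])
        from rsnmap.signals import log_spectral_slope

        assert -1.2 < log_spectral_slope(series) < -0.8


class TestInjectNoise:
    def test_ten_percent_interval_rescaling(self, tiny_scan):
        """f = 0.1: signal range exactly [-0.9, 0.9], noise exactly [-0.1, 0.1]."""
        f = 0.1
        clean = inject_noise(tiny_scan, NoiseSpec(fraction=0.0))
        noisy = inject_noise(tiny_scan, NoiseSpec(fraction=f), rng_seed=1)
        sig = clean.data[tiny_scan.mask] * (1 - f)  # rescale [-1,1] -> [-0.9,0.9]
        noise_part = noisy.data[tiny_scan.mask] - sig
        assert sig.min() == pytest.approx(-0.9) and sig.max() == pytest.approx(0.9)
        # every voxel's noise series spans exactly [-0.1, 0.1]
        np.testing.assert_allclose(noise_part.min(axis=1), -0.1, atol=1e-12)
        np.testing.assert_allclose(noise_part.max(axis=1), 0.1, atol=1e-12)

    def test_zero_fraction_is_pure_rescaling(self, tiny_scan):
        out = inject_noise(tiny_scan, NoiseSpec(fraction=0.0))
        inm = out.data[tiny_scan.mask]
        np.testing.assert_allclose(inm.min(axis=1), -1.0, atol=1e-12)
        np.testing.assert_allclose(inm.max(axis=1), 1.0, atol=1e-12)
        # per-voxel affine rescaling preserves correlation structure
        v = np.argwhere(tiny_scan.mask)[:2]
        r_in = np.corrcoef(tiny_scan.series(v))[0, 1]
        r_out = np.corrcoef(out.series(v))[0, 1]
        assert r_out == pytest.approx(r_in, abs=1e-10)

    def test_output_bounded_for_any_fraction(self, tiny_scan):
        for f in (0.25, 0.5, 0.9):
            out = inject_noise(tiny_scan, NoiseSpec(fraction=f), rng_seed=2)
            assert np.abs(out.data).max() <= 1.0 + 1e-12

    def test_noise_independent_across_voxels(self, tiny_scan):
        noisy = inject_noise(tiny_scan, NoiseSpec(fraction=0.9), rng_seed=3)
        vox = np.argwhere(tiny_scan.mask)[:6]
        series = noisy.series(vox)
        corr = np.corrcoef(series)
        off = corr[~np.eye(len(vox), dtype=bool)]
        assert np.abs(off).mean() < 0.25  # dominated by independent noise

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(fraction=1.0)


class TestTruncateScan:
    def test_truncation_keeps_leading_frames(self, tiny_scan):
        out = truncate_scan(tiny_scan, 50)
        assert out.n_frames == 50
        np.testing.assert_array_equal(out.data[..., 0], tiny_scan.data[..., 0])
        np.testing.assert_array_equal(out.data, tiny_scan.data[..., :50])

    def test_full_length_returns_scan_unchanged(self, tiny_scan):
        assert truncate_scan(tiny_scan, tiny_scan.n_frames) is tiny_scan
        assert truncate_scan(tiny_scan, tiny_scan.n_frames + 10) is tiny_scan

    def test_duration_example(self):
        # 150 frames at TR 2.2 s is 330 s = 5 min 30 s of scan time
        assert 150 * 2.2 == pytest.approx(330.0)


class TestConnectivity:
    def test_roi_matrix_matches_brute_force(self, tiny_atlas, tiny_scan):
        """ROI-level matrix equals direct correlation of ROI-mean series (1e-10)."""
        cm = rm.timeseries_connectivity(tiny_scan, tiny_atlas, level="roi")
        cm.validate()
        rois = sorted(tiny_atlas.rois, key=lambda r: (r.network_index, r.roi_id))
        means = np.stack([tiny_scan.series(r.voxels).mean(axis=0) for r in rois])
        brute = np.corrcoef(means)
        np.testing.assert_allclose(cm.matrix, brute, atol=1e-10)

    def test_diagonal_and_symmetry(self, tiny_atlas, tiny_scan):
        for level in ("roi", "voxel"):
            cm = rm.timeseries_connectivity(tiny_scan, tiny_atlas, level=level)
            np.testing.assert_allclose(np.diag(cm.matrix), 1.0, atol=1e-12)
            np.testing.assert_allclose(cm.matrix, cm.matrix.T, atol=1e-12)

    def test_global_regression_yields_negative_between_blocks(self, tiny_atlas):
        spec = rm.SimulationSpec(noise_sd=0.2, global_signal_regression=True)
        scan = rm.simulate_scan(tiny_atlas, spec, n_frames=200, rng_seed=12)
        cm = rm.timeseries_connectivity(scan, tiny_atlas, level="roi")
        nets = cm.node_networks
        between = cm.matrix[nets[:, None] != nets[None, :]]
        assert between.min() < 0

    def test_softmax_connectivity_block_structure(self, tiny_atlas):
        """Probability vectors concentrated per network give within-block
        correlations above between-block correlations."""
        k = tiny_atlas.n_networks
        rng = np.random.default_rng(0)
        probs = np.zeros((k,) + tiny_atlas.grid_shape)
        inm = tiny_atlas.mask
        probs[:, inm] = rng.dirichlet(np.ones(k), size=int(inm.sum())).T
        for roi in tiny_atlas.rois:  # concentrate on the owning network
            vec = np.full(k, 0.1 / (k - 1))
            vec[roi.network_index] = 0.9
            noise = rng.uniform(0.9, 1.1, size=(len(roi.voxels), k))
            p = vec[None, :] * noise
            probs[:, roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]] = (
                p / p.sum(axis=1, keepdims=True)
            ).T
        pm = rm.ProbabilityMaps(probs=probs, subject_id="x", mask=inm,
                                networks=tiny_atlas.networks)
        pm.validate()
        cm = rm.softmax_connectivity(pm, tiny_atlas, level="voxel")
        cm.validate()
        within, between = cm.block_means()
        assert within > between
        cm_roi = rm.softmax_connectivity(pm, tiny_atlas, level="roi")
        w2, b2 = cm_roi.block_means()
        assert w2 > b2
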