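import numpy as np
import pytest

from rsnmap.model import (
    CnnConfig,
    DenseResNet3D,
    check_input_shape,
    load_model,
    save_model,
    should_stop,
)
from rsnmap.model.layers import (
    Parameter,
    Tensor,
    _conv3d_direct,
    _conv3d_fft,
    add,
    softmax,
    weighted_cross_entropy,
)

TINY = CnnConfig(
    n_classes=3, n_dense_blocks=2, units_per_block=(1, 1), growth=3,
    kernel_sizes=(1, 3), head_channels=4, dropout=0.0, dtype="float64",
)


def _loss(model, x, y, w):
    logits = model.forward(x, training=True)
    loss = weighted_cross_entropy(logits[0], y, w)
    for lg in logits[1:]:
        loss = add(loss, weighted_cross_entropy(lg, y, w))
    return loss


class TestLayers:
    def test_fft_conv_matches_direct_path(self):
        """Spectral and per-offset convolutions agree (values and all grads)."""
        rng = np.random.default_rng(0)
        for k, shape, cin, cout in [(7, (2, 9, 8, 10), 4, 5), (3, (2, 8, 8, 8), 6, 4)]:
            x1 = Tensor(rng.standard_normal(shape + (cin,)))
            x1.requires_grad = True
            x2 = Tensor(x1.data.copy())
            x2.requires_grad = True
            w1 = Parameter(rng.standard_normal((k, k, k, cin, cout)))
            b1 = Parameter(rng.standard_normal(cout))
            w2, b2 = Parameter(w1.data.copy()), Parameter(b1.data.copy())
            o1 = _conv3d_direct(x1, w1, b1)
            o2 = _conv3d_fft(x2, w2, b2)
            np.testing.assert_allclose(o1.data, o2.data, atol=1e-10)
            g = rng.standard_normal(o1.data.shape)
            o1.bwd(g)
            o2.bwd(g)
            np.testing.assert_allclose(x1.grad, x2.grad, atol=1e-10)
            np.testing.assert_allclose(w1.grad, w2.grad, atol=1e-10)
            np.testing.assert_allclose(b1.grad, b2.grad, atol=1e-10)

    def test_gradients_match_finite_differences(self):
        """End-to-end gradient check of the whole architecture in float64."""
        model = DenseResNet3D(TINY, rng_seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 6, 6, 6, 2))
        y = np.array([0, 2])
        w = np.array([1.0, 2.0, 0.5])
        loss = _loss(model, x, y, w)
        loss.backward()
        pick = np.random.default_rng(2)
        for p in model.parameters()[::4]:
            idx = tuple(pick.integers(s) for s in p.data.shape)
            eps, old = 1e-6, p.data[idx]
            p.data[idx] = old + eps
            lp = float(_loss(model, x, y, w).data)
            p.data[idx] = old - eps
            lm = float(_loss(model, x, y, w).data)
            p.data[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = p.grad[idx]
            assert ana == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestArchitecture:
    def test_every_head_outputs_simplex_vectors(self):
        cfg = CnnConfig(n_classes=13, n_dense_blocks=2, units_per_block=(1, 1),
                        growth=4, kernel_sizes=(1, 3), head_channels=4)
        model = DenseResNet3D(cfg, rng_seed=0)
        x = np.random.default_rng(0).standard_normal((3, 8, 8, 8, 2))
        for logits in model.forward(x, training=False):
            p = softmax(logits.data)
            assert p.shape == (3, 13)
            assert (p >= 0).all() and (p <= 1).all()
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_head_count_is_blocks_plus_final(self):
        model = DenseResNet3D(CnnConfig(n_classes=4), rng_seed=0)
        x = np.random.default_rng(0).standard_normal((1, 16, 16, 16, 2)).astype(np.float32)
        assert len(model.forward(x)) == 3 + 1

    def test_pooling_shape_arithmetic(self):
        check_input_shape(CnnConfig(n_classes=4), (4, 4, 4))  # 4 -> 2 -> 1
        with pytest.raises(ValueError):
            check_input_shape(CnnConfig(n_classes=4), (2, 2, 2))  # 2 -> 1 -> dead

    def test_inference_deterministic_despite_dropout_config(self):
        cfg = CnnConfig(n_classes=3, n_dense_blocks=2, units_per_block=(1, 1),
                        growth=3, kernel_sizes=(1, 3), head_channels=4, dropout=0.5)
        model = DenseResNet3D(cfg, rng_seed=0)
        x = np.random.default_rng(0).standard_normal((2, 8, 8, 8, 2))
        a = model.forward(x, training=False)[-1].data
        b = model.forward(x, training=False)[-1].data
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = DenseResNet3D(TINY, rng_seed=3)
        x = np.random.default_rng(1).standard_normal((2, 8, 8, 8, 2))
        ref = model.forward(x, training=False)[-1].data
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        assert loaded.config == TINY
        np.testing.assert_array_equal(loaded.forward(x, training=False)[-1].data, ref)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CnnConfig(n_classes=1)
        with pytest.raises(ValueError):
            CnnConfig(n_classes=4, kernel_sizes=(1, 2))
        with pytest.raises(ValueError):
            CnnConfig(n_classes=4, dropout=1.0)


class TestEarlyStopping:
    def test_forced_history_stops_after_three_stale_validations(self):
        """Accuracies [0.5, 0.9, 0.9, 0.9, 0.9]: best at the 2nd validation,
        three non-improving follow, so training stops at the 5th."""
        accs = [0.5, 0.9, 0.9, 0.9, 0.9]
        assert not should_stop(accs[:4], patience=3)
        assert should_stop(accs, patience=3)

    def test_strict_improvement_required(self):
        assert should_stop([0.9, 0.9, 0.9, 0.9], patience=3)
        assert not should_stop([0.5, 0.6, 0.7, 0.8], patience=3)

    def test_never_more_than_patience_after_best(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            accs = list(rng.random(rng.integers(2, 12)))
            if should_stop(accs, patience=3):
                best = int(np.argmax(accs))
                # find first stopping point; no more than 3 stale validations
                # beyond the running best at that point
                for stop in range(1, len(accs) + 1):
                    if should_stop(accs[:stop], patience=3):
                        run_best = int(np.argmax(accs[:stop]))
                        assert stop - 1 - run_best >= 3
                        break
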