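"""The CNN-LSTM-Attention classifier: construction, training behaviour,
prediction contracts and attention-weight properties.

Model tests run on short random segments (small frame counts) so the full
train/predict path is exercised quickly; the architecture is identical to
the full-length configuration.
"""

import numpy as np
import pytest

from gaitfatigue.model import (
    ModelConfig, Network, build_model, train, predict, attention_weights,
    softmax, _SelfAttention,
)
from tests.conftest import make_segment_set


def tiny_cfg(seed=0, **kw):
    base = dict(conv_filters=(4, 8), kernel_sizes=(5, 3), pool_size=2,
                lstm_units=8, dense_units=(8,), dropout=0.1,
                learning_rate=3e-3, batch_size=8, max_epochs=5,
                early_stopping_patience=5, lr_patience=3, seed=seed)
    base.update(kw)
    return ModelConfig(**base)


def separable_segments(n_per_class=20, frames=64, channels=3, gap=3.0, seed=0):
    """Two classes separated by a burst amplitude difference mid-window."""
    rng = np.random.default_rng(seed)
    segs = make_segment_set(n_subjects=1, windows=n_per_class, frames=frames,
                            channels=channels, seed=seed)
    bump = np.exp(-((np.arange(frames) - frames / 2) ** 2) / 18.0)
    for i in range(segs.n_segments):
        if segs.labels[i] == 1:
            segs.data[i] += gap * bump[:, None]
        segs.data[i] += rng.standard_normal((frames, channels)) * 0.1
    return segs


class TestBuild:
    def test_output_shape_is_width_independent(self):
        for channels in (2, 10):
            net = build_model(tiny_cfg(), (444, channels))
            logits = net.forward(np.zeros((3, 444, channels)))
            assert logits.shape == (3, 2)

    def test_seeded_builds_are_identical(self):
        a = build_model(tiny_cfg(seed=9), (100, 4))
        b = build_model(tiny_cfg(seed=9), (100, 4))
        for (i, k, va), (_, _, vb) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(va, vb)

    def test_different_seeds_differ(self):
        a = build_model(tiny_cfg(seed=1), (100, 4))
        b = build_model(tiny_cfg(seed=2), (100, 4))
        assert any(
            not np.array_equal(va, vb)
            for (_, _, va), (_, _, vb) in zip(a.parameters(), b.parameters())
        )

    def test_parameter_count_positive_and_reported(self):
        net = build_model(tiny_cfg(), (64, 3))
        assert net.parameter_count() > 0

    def test_window_shorter_than_receptive_field_rejected(self):
        with pytest.raises(ValueError):
            build_model(tiny_cfg(), (3, 4))
        with pytest.raises(ValueError):
            build_model(tiny_cfg(pool_size=8), (8, 4))  # dies in second pool


class TestGradients:
    def test_numerical_gradient_check(self):
        """Backprop agrees with central finite differences end to end."""
        cfg = tiny_cfg(dropout=0.0)
        net = build_model(cfg, (12, 2))
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 12, 2))
        y = np.array([0, 1, 0, 1])

        def loss_at():
            probs = softmax(net.forward(x, train=False))
            return -np.log(probs[np.arange(4), y]).mean()

        probs = softmax(net.forward(x, train=True))
        d = probs.copy()
        d[np.arange(4), y] -= 1.0
        net.backward(d / 4)

        eps = 1e-6
        checked = 0
        for i, k, p in net.parameters():
            g = net.layers[i].grads[k]
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at()
                flat[idx] = orig - eps
                dn = loss_at()
                flat[idx] = orig
                num = (up - dn) / (2 * eps)
                ana = g.reshape(-1)[idx]
                assert abs(num - ana) < 1e-4 * max(1.0, abs(num)), (i, k)
                checked += 1
        assert checked >= 15


class TestTrain:
    def test_learns_separable_data(self):
        segs = separable_segments()
        cfg = tiny_cfg(max_epochs=30)
        fitted = train(build_model(cfg, segs.data.shape[1:]), segs, cfg)
        assert fitted.history["train_acc"][-1] >= 0.95

    def test_chance_level_on_permuted_labels(self):
        segs = separable_segments(n_per_class=30, seed=1)
        rng = np.random.default_rng(5)
        segs.labels = rng.permutation(segs.labels)
        cfg = tiny_cfg(max_epochs=10, seed=2)
        fitted = train(build_model(cfg, segs.data.shape[1:]), segs, cfg)
        # held-out accuracy at the restored (best) epoch is near chance;
        # the band is wide because the validation split holds 12 segments
        val_acc = fitted.history["val_acc"][fitted.history["best_epoch"]]
        assert 0.2 <= val_acc <= 0.8

    def test_memorization_capacity(self):
        # 20 random segments: the net should overfit its training split
        segs = make_segment_set(n_subjects=1, windows=10, frames=32, channels=2, seed=4)
        cfg = tiny_cfg(conv_filters=(8, 16), lstm_units=16, dense_units=(16,),
                       max_epochs=200, dropout=0.0, learning_rate=5e-3,
                       early_stopping_patience=200, lr_patience=200, batch_size=4)
        fitted = train(build_model(cfg, segs.data.shape[1:]), segs, cfg)
        assert max(fitted.history["train_acc"]) >= 0.99

    def test_history_tracks_aligned(self):
        segs = separable_segments(n_per_class=10)
        cfg = tiny_cfg(max_epochs=4)
        fitted = train(build_model(cfg, segs.data.shape[1:]), segs, cfg)
        h = fitted.history
        assert (len(h["train_loss"]) == len(h["train_acc"])
                == len(h["val_loss"]) == len(h["val_acc"]) == len(h["lr"]))

    def test_single_class_input_rejected(self):
        segs = separable_segments(n_per_class=10)
        segs.labels[:] = 1
        cfg = tiny_cfg()
        with pytest.raises(ValueError, match="both classes"):
            train(build_model(cfg, segs.data.shape[1:]), segs, cfg)

    def test_seeded_determinism(self):
        segs = separable_segments(n_per_class=12, seed=3)
        outs = []
        for _ in range(2):
            cfg = tiny_cfg(seed=11, max_epochs=6)
            fitted = train(build_model(cfg, segs.data.shape[1:]), segs, cfg)
            probs, labels = predict(fitted, segs.data)
            outs.append((fitted.history["val_loss"], probs, labels))
        assert outs[0][0] == outs[1][0]
        np.testing.assert_array_equal(outs[0][1], outs[1][1])
        np.testing.assert_array_equal(outs[0][2], outs[1][2])


@pytest.fixture(scope="module")
def fitted():
    segs = separable_segments(n_per_class=10, seed=6)
    cfg = tiny_cfg(max_epochs=3)
    return train(build_model(cfg, segs.data.shape[1:]), segs, cfg)


class TestPredict:

    def test_probabilities_sum_to_one(self, fitted, rng):
        x = rng.standard_normal((7, 64, 3))
        probs, labels = predict(fitted, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert set(labels) <= {0, 1}

    def test_pointwise_map_on_duplicated_rows(self, fitted, rng):
        x = rng.standard_normal((1, 64, 3))
        dup = np.repeat(x, 4, axis=0)
        probs, _ = predict(fitted, dup)
        assert (probs == probs[0]).all()

    def test_zero_variance_segment_yields_valid_probabilities(self, fitted):
        probs, _ = predict(fitted, np.zeros((1, 64, 3)))
        assert np.isfinite(probs).all()
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-5)

    def test_width_mismatch_rejected(self, fitted, rng):
        with pytest.raises(ValueError, match="match"):
            predict(fitted, rng.standard_normal((2, 64, 5)))


class TestAttention:
    def test_rows_are_probability_vectors(self, rng):
        segs = separable_segments(n_per_class=8, seed=8)
        cfg = tiny_cfg(max_epochs=2)
        fitted = train(build_model(cfg, segs.data.shape[1:]), segs, cfg)
        w = attention_weights(fitted, segs.data[0])
        assert w.ndim == 2 and w.shape[0] == w.shape[1]
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-5)

    def test_layer_equivariance_on_duplicated_frames(self, rng):
        """Identical input frames receive identical attention rows/columns."""
        layer = _SelfAttention()
        h = rng.standard_normal((1, 6, 4))
        h[0, 3] = h[0, 1]  # duplicate frame
        layer.forward(h, train=False)
        a = layer.last_attention[0]
        np.testing.assert_allclose(a[1], a[3], atol=1e-12)
        np.testing.assert_allclose(a[:, 1], a[:, 3], atol=1e-12)

    def test_untrained_model_has_no_attention(self):
        net = build_model(tiny_cfg(), (64, 3))
        with pytest.raises(RuntimeError):
            net.attention_matrix()
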