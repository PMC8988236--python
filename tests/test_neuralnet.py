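"""Network forward pass, gradient correctness, SCG/GD training behavior."""

import math

import numpy as np
import pytest

from adaptgait.neuralnet import (
    GdConfig,
    InitConfig,
    NetworkShape,
    NetworkWeights,
    ScgConfig,
    WeightsFormatError,
    forward_pass,
    init_weights,
    load_weights,
    loss_and_gradient,
    predict_batch,
    save_weights,
    train_gd,
    train_scg,
)


def _finite_difference_max_rel_err(weights, X, y, eps=1e-6):
    _, grad = loss_and_gradient(weights, X, y)
    gf = grad.flatten()
    flat = weights.flatten()

    def loss_at(f):
        w = NetworkWeights.from_flat(f, weights.shape)
        w.input_mean = weights.input_mean
        w.input_scale = weights.input_scale
        return loss_and_gradient(w, X, y)[0]

    errs = []
    for i in range(flat.size):
        up, dn = flat.copy(), flat.copy()
        up[i] += eps
        dn[i] -= eps
        num = (loss_at(up) - loss_at(dn)) / (2 * eps)
        denom = max(abs(num), abs(gf[i]), 1e-8)
        errs.append(abs(num - gf[i]) / denom)
    return max(errs)


class TestInit:
    @pytest.mark.parametrize("n_inputs,bound", [(102, 0.099), (1, 1.0), (4, 0.5)])
    def test_bound_values(self, n_inputs, bound):
        shape = NetworkShape(n_inputs=n_inputs, n_hidden=3, n_outputs=2)
        assert round(InitConfig.bound(shape), 3) == bound

    def test_all_entries_inside_bound(self):
        shape = NetworkShape()
        for seed in range(5):
            w = init_weights(shape, InitConfig(seed=seed))
            bound = 1.0 / math.sqrt(102)
            assert np.abs(w.flatten()).max() < bound
            assert round(bound, 3) == 0.099

    def test_deterministic(self):
        a = init_weights(NetworkShape(), InitConfig(seed=12))
        b = init_weights(NetworkShape(), InitConfig(seed=12))
        assert np.array_equal(a.flatten(), b.flatten())


class TestForwardPass:
    def test_zero_weights_uniform_scores(self):
        shape = NetworkShape()
        zero = NetworkWeights(
            shape=shape,
            w_hidden=np.zeros((102, 20)),
            b_hidden=np.zeros(20),
            w_output=np.zeros((20, 5)),
            b_output=np.zeros(5),
        )
        scores, label = forward_pass(zero, np.random.default_rng(0).normal(size=102))
        np.testing.assert_allclose(scores, 0.2)
        assert label == 0  # lowest-index tie break

    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(1)
        w = init_weights(NetworkShape(), InitConfig(seed=0))
        for _ in range(10):
            scores, _ = forward_pass(w, rng.normal(size=102))
            assert abs(scores.sum() - 1.0) < 1e-12

    def test_hand_computed_toy_network(self):
        """1 input -> 1 tanh unit -> 2 softmax outputs, by hand."""
        shape = NetworkShape(n_inputs=1, n_hidden=1, n_outputs=2)
        w = NetworkWeights(
            shape=shape,
            w_hidden=np.array([[2.0]]),
            b_hidden=np.array([0.1]),
            w_output=np.array([[1.0, -1.0]]),
            b_output=np.array([0.2, -0.2]),
        )
        x = 0.5
        h = math.tanh(2.0 * x + 0.1)
        z0, z1 = h + 0.2, -h - 0.2
        p0 = math.exp(z0) / (math.exp(z0) + math.exp(z1))
        scores, label = forward_pass(w, np.array([x]))
        assert scores[0] == pytest.approx(p0, rel=1e-12)
        assert scores[1] == pytest.approx(1 - p0, rel=1e-12)
        assert label == 0

    def test_shape_mismatch_raises(self):
        w = init_weights(NetworkShape(), InitConfig(seed=0))
        with pytest.raises(WeightsFormatError):
            forward_pass(w, np.zeros(101))


class TestGradient:
    def test_matches_finite_differences_small_shapes(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            n_in, n_hid, n_out = rng.integers(2, 5), rng.integers(2, 4), rng.integers(2, 4)
            shape = NetworkShape(int(n_in), int(n_hid), int(n_out))
            w = init_weights(shape, InitConfig(seed=trial))
            X = rng.normal(size=(4, n_in))
            y = rng.integers(0, n_out, size=4)
            assert _finite_difference_max_rel_err(w, X, y) < 1e-5

    def test_duplicated_batch_same_loss_and_gradient(self):
        rng = np.random.default_rng(3)
        shape = NetworkShape(3, 2, 2)
        w = init_weights(shape, InitConfig(seed=1))
        X = rng.normal(size=(4, 3))
        y = rng.integers(0, 2, size=4)
        l1, g1 = loss_and_gradient(w, X, y)
        l2, g2 = loss_and_gradient(w, np.vstack([X, X]), np.concatenate([y, y]))
        assert l1 == pytest.approx(l2, rel=1e-12)
        np.testing.assert_allclose(g1.flatten(), g2.flatten(), rtol=1e-12)

    def test_near_zero_gradient_at_trained_optimum(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        w, _ = train_scg((X, y), NetworkShape(2, 4, 2), init_cfg=InitConfig(seed=0))
        _, g = loss_and_gradient(w, X, y)
        initial_norm = np.linalg.norm(
            loss_and_gradient(init_weights(NetworkShape(2, 4, 2), InitConfig(seed=0)), X, y)[1].flatten()
        )
        assert np.linalg.norm(g.flatten()) < 0.05 * initial_norm

    def test_empty_batch_raises(self):
        w = init_weights(NetworkShape(3, 2, 2), InitConfig(seed=0))
        with pytest.raises(ValueError):
            loss_and_gradient(w, np.empty((0, 3)), np.empty(0, dtype=int))


class TestScg:
    def test_separable_blobs_converge(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal([-2, -2], 1.0, (200, 2)), rng.normal([2, 2], 1.0, (200, 2))])
        y = np.repeat([0, 1], 200)
        w, hist = train_scg((X, y), NetworkShape(2, 20, 2), init_cfg=InitConfig(seed=5))
        assert len(hist) - 1 <= 1000
        assert (predict_batch(w, X) != y).mean() < 0.05

    def test_plateau_break_stops_early(self):
        # nearly-uninformative data: first improvements are already tiny
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 2)) * 1e-4
        y = rng.integers(0, 2, size=50)
        _, hist = train_scg((X, y), NetworkShape(2, 3, 2), init_cfg=InitConfig(seed=1))
        assert len(hist) - 1 < 100

    def test_history_monotone_nonincreasing(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(-1, 1, (60, 3)), rng.normal(1, 1, (60, 3))])
        y = np.repeat([0, 1], 60)
        _, hist = train_scg((X, y), NetworkShape(3, 5, 2), init_cfg=InitConfig(seed=2))
        diffs = np.diff(hist)
        assert (diffs <= 1e-12).all()  # accepted steps never increase the loss

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        w1, h1 = train_scg((X, y), NetworkShape(3, 4, 2), init_cfg=InitConfig(seed=3))
        w2, h2 = train_scg((X, y), NetworkShape(3, 4, 2), init_cfg=InitConfig(seed=3))
        assert np.array_equal(w1.flatten(), w2.flatten())
        assert h1 == h2


class TestGd:
    def test_empty_buffer_identity(self):
        w = init_weights(NetworkShape(3, 2, 2), InitConfig(seed=0))
        out = train_gd(w, [], GdConfig())
        assert np.array_equal(out.flatten(), w.flatten())
        assert out is not w

    def test_update_scales_with_learning_rate(self):
        rng = np.random.default_rng(9)
        w = init_weights(NetworkShape(3, 2, 2), InitConfig(seed=1))
        X = rng.normal(size=(1, 3))
        y = np.array([1])
        d1 = train_gd(w, (X, y), GdConfig(learning_rate=1e-6)).flatten() - w.flatten()
        d2 = train_gd(w, (X, y), GdConfig(learning_rate=2e-6)).flatten() - w.flatten()
        assert np.linalg.norm(d2) / np.linalg.norm(d1) == pytest.approx(2.0, rel=1e-3)

    def test_descends_on_single_example(self):
        rng = np.random.default_rng(10)
        w = init_weights(NetworkShape(3, 2, 2), InitConfig(seed=2))
        X = rng.normal(size=(1, 3))
        y = np.array([0])
        before, _ = loss_and_gradient(w, X, y)
        out = train_gd(w, (X, y), GdConfig())
        after, _ = loss_and_gradient(out, X, y)
        assert after <= before

    def test_input_weights_not_mutated(self):
        rng = np.random.default_rng(11)
        w = init_weights(NetworkShape(3, 2, 2), InitConfig(seed=3))
        snapshot = w.flatten()
        train_gd(w, (rng.normal(size=(2, 3)), np.array([0, 1])), GdConfig())
        assert np.array_equal(w.flatten(), snapshot)


class TestPersistence:
    def test_save_load_identity(self, tmp_path):
        rng = np.random.default_rng(12)
        X = rng.normal(2.0, 3.0, size=(30, 102))
        y = rng.integers(0, 5, size=30)
        w, _ = train_scg((X, y), NetworkShape(), init_cfg=InitConfig(seed=4),
                         scg_cfg=ScgConfig(max_epochs=5))
        path = tmp_path / "w.json"
        save_weights(w, path)
        back = load_weights(path)
        assert np.array_equal(back.flatten(), w.flatten())
        assert np.array_equal(back.input_mean, w.input_mean)
        assert np.array_equal(back.input_scale, w.input_scale)
        # loaded weights predict identically
        probe = rng.normal(size=(7, 102))
        np.testing.assert_array_equal(predict_batch(back, probe), predict_batch(w, probe))

    def test_version_mismatch_rejected(self, tmp_path):
        w = init_weights(NetworkShape(3, 2, 2), InitConfig(seed=0))
        path = tmp_path / "w.json"
        save_weights(w, path)
        import json

        raw = json.loads(path.read_text())
        raw["version"] = "999"
        path.write_text(json.dumps(raw))
        with pytest.raises(WeightsFormatError, match="version"):
            load_weights(path)

    def test_tampered_dimension_rejected(self, tmp_path):
        w = init_weights(NetworkShape(3, 2, 2), InitConfig(seed=0))
        path = tmp_path / "w.json"
        save_weights(w, path)
        import json

        raw = json.loads(path.read_text())
        raw["shape"]["n_hidden"] = 7
        path.write_text(json.dumps(raw))
        with pytest.raises(WeightsFormatError):
            load_weights(path)
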