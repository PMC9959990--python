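"""CNN-GRU: gate equations vs explicit-loop oracle, structure audit,
forward-pass contracts, and deterministic training bookkeeping."""

import numpy as np
import pytest

from sootylung import classifier as clf
from sootylung import _nn


def explicit_gate_oracle(u, r_prev, kx, wh, bias):
    """Element-by-element evaluation with python loops."""
    n, d_in = u.shape
    hid = kx.shape[1]
    out = np.zeros((n, hid))
    for i in range(n):
        for j in range(hid):
            acc = bias[j]
            for k in range(d_in):
                acc += u[i, k] * kx[k, j]
            for k in range(r_prev.shape[1]):
                acc += r_prev[i, k] * wh[k, j]
            out[i, j] = 1.0 / (1.0 + np.exp(-acc))
    return out


def make_gate_params(rng, d_in=5, hid=4):
    return clf.GruGateParams(
        KXR=rng.normal(size=(d_in, hid)), KXU=rng.normal(size=(d_in, hid)),
        WhR=rng.normal(size=(hid, hid)), WhU=rng.normal(size=(hid, hid)),
        CR=rng.normal(size=hid), CU=rng.normal(size=hid),
    )


class TestGruGates:
    def test_zero_weights_give_half(self):
        w = clf.GruGateParams(*(np.zeros((3, 2)), np.zeros((3, 2)),
                                np.zeros((2, 2)), np.zeros((2, 2)),
                                np.zeros(2), np.zeros(2)))
        out = clf.gru_reset_gate(np.ones((1, 3)), np.ones((1, 2)), w)
        assert np.allclose(out, 0.5)

    def test_large_negative_bias_saturates_to_zero(self):
        w = clf.GruGateParams(*(np.zeros((3, 2)), np.zeros((3, 2)),
                                np.zeros((2, 2)), np.zeros((2, 2)),
                                np.full(2, -1000.0), np.full(2, -1000.0)))
        out = clf.gru_update_gate(np.ones((1, 3)), np.ones((1, 2)), w)
        assert np.all(out < 1e-10)

    def test_scalar_case_hand_arithmetic(self):
        w = clf.GruGateParams(KXR=np.array([[0.5]]), KXU=np.array([[0.5]]),
                              WhR=np.array([[-1.0]]), WhU=np.array([[-1.0]]),
                              CR=np.zeros(1), CU=np.zeros(1))
        out = clf.gru_reset_gate(np.array([[2.0]]), np.array([[1.0]]), w)
        assert abs(out[0, 0] - 0.5) < 1e-12  # sigma(2*0.5 - 1) = sigma(0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = make_gate_params(rng)
        u = rng.normal(size=(3, 5))
        r_prev = rng.normal(size=(3, 4))
        got_r = clf.gru_reset_gate(u, r_prev, w)
        got_u = clf.gru_update_gate(u, r_prev, w)
        assert np.allclose(got_r, explicit_gate_oracle(u, r_prev, w.KXR, w.WhR, w.CR),
                           atol=1e-10)
        assert np.allclose(got_u, explicit_gate_oracle(u, r_prev, w.KXU, w.WhU, w.CU),
                           atol=1e-10)

    def test_outputs_strictly_inside_unit_interval_and_monotone_in_bias(self, rng):
        w = make_gate_params(rng)
        u, r_prev = rng.normal(size=(4, 5)), rng.normal(size=(4, 4))
        out = clf.gru_reset_gate(u, r_prev, w)
        assert np.all(out > 0) and np.all(out < 1)
        w2 = clf.GruGateParams(w.KXR, w.KXU, w.WhR, w.WhU, w.CR + 1.0, w.CU)
        assert np.all(clf.gru_reset_gate(u, r_prev, w2) > out)

    def test_shape_mismatch_rejected(self, rng):
        w = make_gate_params(rng)
        with pytest.raises(ValueError):
            clf.gru_reset_gate(np.ones((2, 7)), np.ones((2, 4)), w)


class TestBuildModel:
    def test_structure_counts(self):
        m = clf.build_model(seed=0)
        s = m.summary()
        assert s["n_conv"] == 4 and s["n_pool"] == 3 and s["n_fc"] == 3
        assert s["n_gru"] == 1 and s["gru_units"] == 512
        assert s["first_conv_maps"] == 128
        assert s["first_conv_output"] == (48, 48)
        assert s["kernel"] == (3, 3) and s["stride"] == 1

    def test_forward_gives_probability_simplex(self, rng):
        m = clf.build_model(seed=0)
        x = rng.random((2, 3, 50, 50)).astype(np.float32)
        probs, labels = clf.predict(m, x)
        assert probs.shape == (2, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)
        assert all(l in ("normal", "benign", "malignant") for l in labels)

    def test_single_image_batch(self, rng):
        m = clf.build_model(seed=0)
        x = rng.random((3, 50, 50)).astype(np.float32)
        probs, labels = clf.predict(m, x)
        assert probs.shape == (1, 3) and len(labels) == 1
        assert labels[0] == ("normal", "benign", "malignant")[probs[0].argmax()]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            clf.CnnGruConfig(conv_channels=(64, 64, 64, 32)).validate()
        with pytest.raises(ValueError):
            clf.CnnGruConfig(gru_units=256).validate()

    def test_checkpoint_round_trip(self, tmp_path, rng):
        m = clf.build_model(seed=1)
        x = rng.random((2, 3, 50, 50)).astype(np.float32)
        p1, _ = clf.predict(m, x)
        path = tmp_path / "model.npz"
        clf.save_checkpoint(m, path)
        m2 = clf.load_checkpoint(path)
        p2, _ = clf.predict(m2, x)
        assert np.allclose(p1, p2)


class TestTrain:
    def _toy_data(self, n=24):
        rng = np.random.default_rng(0)
        X = rng.normal(0.3, 0.02, (n, 3, 50, 50)).astype(np.float32)
        y = np.tile([0, 1, 2], n // 3)
        for i in range(n):
            if y[i] == 1:
                X[i, :, 20:26, 20:26] += 0.5
            elif y[i] == 2:
                X[i, :, 14:34, 14:34] += 0.5
        return X, y

    def test_loss_history_length_matches_epochs(self):
        X, y = self._toy_data()
        m = clf.build_model(seed=0, drop_rate=0.25)
        hist = clf.train(m, (X, y), clf.TrainConfig(epochs=2, seed=0, drop_rate=0.25))
        assert len(hist["loss"]) == len(hist["accuracy"]) == 2

    def test_same_seed_identical_histories(self):
        X, y = self._toy_data()
        h = []
        for _ in range(2):
            m = clf.build_model(seed=4, drop_rate=0.25)
            h.append(clf.train(m, (X, y),
                               clf.TrainConfig(epochs=2, seed=4, drop_rate=0.25)))
        assert h[0]["loss"] == h[1]["loss"]
        assert h[0]["accuracy"] == h[1]["accuracy"]

    def test_single_class_rejected(self):
        X, _ = self._toy_data(6)
        with pytest.raises(ValueError):
            clf.train(clf.build_model(seed=0), (X, np.zeros(6, dtype=int)),
                      clf.TrainConfig(epochs=1))

    def test_gradient_descent_reduces_loss_on_learnable_signal(self):
        X, y = self._toy_data()
        m = clf.build_model(seed=0, drop_rate=0.0)
        hist = clf.train(m, (X, y),
                         clf.TrainConfig(epochs=8, batch_size=8, seed=0, drop_rate=0.0))
        assert hist["loss"][-1] < hist["loss"][0]
        assert hist["accuracy"][-1] >= 0.75
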