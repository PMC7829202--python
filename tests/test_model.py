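"""Reference cell algebra, vectorized equivalence, gradients, training."""

import numpy as np
import pytest

from abrwave.core import WINDOW_LEN
from abrwave.labelgen import LabelVector, WindowedTrace
from abrwave.model import (
    LstmCellParams,
    SequenceModelConfig,
    build_model,
    load_model,
    lstm_cell_step,
    predict_probs,
    run_reference_chain,
    save_model,
    softmax,
    train,
)
from abrwave.model.network import _Direction, sequence_loss_and_grad


def random_cell_params(rng, H, D):
    def w(*shape):
        return rng.standard_normal(shape)

    return LstmCellParams(
        W_f=w(H, H), U_f=w(H, D), b_f=w(H),
        W_i=w(H, H), U_i=w(H, D), b_i=w(H),
        W_a=w(H, H), U_a=w(H, D), b_a=w(H),
        W_o=w(H, H), U_o=w(H, D), b_o=w(H),
    )


class TestReferenceCell:
    def test_all_zero_params_and_state_give_zero(self):
        H, D = 4, 2
        z = np.zeros
        p = LstmCellParams(*[z((H, H)) if i % 3 == 0 else z((H, D)) if i % 3 == 1
                             else z(H) for i in range(12)])
        h, C = lstm_cell_step(p, np.zeros(D), np.zeros(H), np.zeros(H))
        np.testing.assert_array_equal(h, 0)
        np.testing.assert_array_equal(C, 0)

    def test_zero_weights_halve_memory_cell(self, rng):
        # with all weights/biases zero: f = i = o = 1/2, a = 0, so
        # C_t = C_prev / 2 and h_t = tanh(C_t) / 2
        H, D = 5, 3
        z = np.zeros
        p = LstmCellParams(*[z((H, H)) if i % 3 == 0 else z((H, D)) if i % 3 == 1
                             else z(H) for i in range(12)])
        c = rng.standard_normal(H)
        h, C = lstm_cell_step(p, rng.standard_normal(D), np.zeros(H), c)
        np.testing.assert_allclose(C, 0.5 * c)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c))

    def test_shape_mismatch_rejected(self, rng):
        p = random_cell_params(rng, 3, 2)
        with pytest.raises(ValueError):
            lstm_cell_step(p, np.zeros(5), np.zeros(3), np.zeros(3))


class TestVectorizedEquivalence:
    def test_matches_reference_chain_on_random_instances(self):
        """Dual-route check: fused-gate batched recursion vs the per-gate
        scalar reference cell, 100 random (H<=8, D<=4) instances."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            H = int(rng.integers(1, 9))
            D = int(rng.integers(1, 5))
            T = int(rng.integers(1, 20))
            direction = _Direction(D, H, rng, np.float64)
            X = rng.standard_normal((T, 1, D))
            fast = direction.forward(X, reverse=False)[:, 0, :]
            slow = run_reference_chain(direction.as_cell_params(), X[:, 0, :])
            worst = max(worst, float(np.abs(fast - slow).max()))
        assert worst < 1e-5

    def test_gradients_match_finite_differences(self):
        """Backpropagation through time vs central differences at a random
        point, 10 random parameters, 1e-4 relative tolerance."""
        cfg = SequenceModelConfig(
            directionality="bi", num_layers=2, hidden_nodes=5,
            dtype="float64", seed=3,
        )
        model = build_model(cfg)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((12, 3, 1))
        Y = (rng.uniform(size=(12, 3)) < 0.2).astype(np.int64)
        sequence_loss_and_grad(model, X, Y)
        grads = {k: v.copy() for k, v in model.gradients().items()}
        params = model.parameters()
        names = list(params)
        eps = 1e-6
        for _ in range(10):
            name = names[rng.integers(len(names))]
            flat = params[name].reshape(-1)
            idx = int(rng.integers(flat.size))
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = sequence_loss_and_grad(model, X, Y, compute_grad=False)
            flat[idx] = orig - eps
            lm = sequence_loss_and_grad(model, X, Y, compute_grad=False)
            flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            g = grads[name].reshape(-1)[idx]
            assert abs(fd - g) <= 1e-4 * max(abs(fd), abs(g), 1e-6)

    def test_reversal_symmetry_of_bidirectional_model(self):
        """With backward weights tied to forward ones and a head symmetric
        under swapping the two halves, reversing the input reverses the
        output probabilities."""
        cfg = SequenceModelConfig(
            directionality="bi", num_layers=1, hidden_nodes=6,
            dtype="float64", seed=0,
        )
        model = build_model(cfg)
        layer = model.layers[0]
        for k, v in layer.fw.params().items():
            getattr(layer.bw, k)[...] = v
        H = cfg.hidden_nodes
        model.V[H:] = model.V[:H]
        rng = np.random.default_rng(9)
        x = rng.standard_normal(WINDOW_LEN)
        p_fwd = predict_probs(model, x)
        p_rev = predict_probs(model, x[::-1].copy())
        np.testing.assert_allclose(p_rev, p_fwd[::-1], atol=1e-10)


class TestBuildModel:
    def test_selected_architecture_runs_forward(self):
        cfg = SequenceModelConfig(directionality="bi", num_layers=3,
                                  hidden_nodes=16, seed=0)
        model = build_model(cfg)
        probs = predict_probs(model, np.zeros(WINDOW_LEN))
        assert probs.shape == (WINDOW_LEN,)

    def test_output_rows_are_probabilities(self, rng):
        cfg = SequenceModelConfig(directionality="uni", num_layers=1,
                                  hidden_nodes=8, seed=1)
        model = build_model(cfg)
        X = rng.standard_normal((WINDOW_LEN, 2, 1)).astype(np.float32)
        P = softmax(model.logits(X))
        assert P.shape == (WINDOW_LEN, 2, 2)
        np.testing.assert_allclose(P.sum(axis=-1), 1.0, atol=1e-6)
        assert (P >= 0).all()

    def test_same_seed_same_initial_parameters(self):
        cfg = SequenceModelConfig(hidden_nodes=8, num_layers=2, seed=7)
        a, b = build_model(cfg), build_model(cfg)
        for k, v in a.parameters().items():
            np.testing.assert_array_equal(v, b.parameters()[k])

    def test_zero_head_gives_uniform_probabilities(self, rng):
        cfg = SequenceModelConfig(hidden_nodes=8, num_layers=1, seed=2)
        model = build_model(cfg)
        model.V[...] = 0.0
        model.c[...] = 0.0
        probs = predict_probs(model, rng.standard_normal(WINDOW_LEN))
        np.testing.assert_allclose(probs, 0.5, atol=1e-7)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SequenceModelConfig(num_layers=6)
        with pytest.raises(ValueError):
            SequenceModelConfig(directionality="both")


class TestTraining:
    @staticmethod
    def _labels(indices):
        t = np.zeros(WINDOW_LEN, dtype=np.int8)
        t[list(indices)] = 1
        return LabelVector(targets=t, augmented=True)

    def test_overfit_single_sweep(self, rng):
        x = rng.standard_normal(WINDOW_LEN)
        labels = self._labels(range(224, 233))
        cfg = SequenceModelConfig(
            directionality="bi", num_layers=1, hidden_nodes=64,
            learning_rate=0.01, epochs=300, batch_size=1,
            val_fraction=0.0, seed=0,
        )
        model = build_model(cfg)
        model, log = train(model, [(x, labels)], cfg)
        assert log.final_train_loss < 0.05
        probs = predict_probs(model, x)
        on = probs[labels.targets == 1] > 0.5
        off = probs[labels.targets == 0] < 0.5
        assert (~on).sum() <= 2
        assert (~off).sum() <= 2

    def test_all_zero_labels_drive_probs_to_zero(self, rng):
        labels = LabelVector(targets=np.zeros(WINDOW_LEN, dtype=np.int8),
                             augmented=True)
        cfg = SequenceModelConfig(
            directionality="uni", num_layers=1, hidden_nodes=16,
            learning_rate=0.01, epochs=100, batch_size=2,
            val_fraction=0.0, seed=1,
        )
        model = build_model(cfg)
        data = [(rng.standard_normal(WINDOW_LEN), labels) for _ in range(4)]
        model, log = train(model, data, cfg)
        assert log.final_train_loss < 0.01
        probs = predict_probs(model, data[0][0])
        assert probs.mean() < 0.01
        assert probs.max() < 0.5

    def test_empty_dataset_rejected(self):
        cfg = SequenceModelConfig(hidden_nodes=4)
        with pytest.raises(ValueError):
            train(build_model(cfg), [], cfg)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = SequenceModelConfig(directionality="bi", num_layers=2,
                                  hidden_nodes=8, seed=5)
        model = build_model(cfg)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        x = rng.standard_normal(WINDOW_LEN)
        np.testing.assert_allclose(
            predict_probs(model, x), predict_probs(back, x), atol=1e-7
        )
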