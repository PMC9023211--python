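"""Reuploading-circuit classifier: forward pass, loss, gradients, checkpoints."""

import numpy as np
import pytest

from drqc import (
    AnsatzConfig,
    cross_entropy_loss,
    forward,
    forward_batch,
    gradient,
    init_params,
    load_checkpoint,
    predict,
    predict_batch,
    save_checkpoint,
    zero_state,
)
from drqc.model import build_layer, loss_and_gradient
from drqc.quantum import StateVector, apply_1q, apply_cnot, gate_rot

from conftest import kron_apply_1q, kron_cnot_matrix


class TestAnsatzShape:
    def test_default_parameter_counts(self, ansatz):
        assert ansatz.param_shape == (6, 4, 3)
        assert ansatz.n_params == 72
        # one layer carries 3 angles per qubit = 12 trainable parameters
        assert ansatz.param_shape[1] * ansatz.param_shape[2] == 12

    def test_readout_determines_class_count(self):
        assert AnsatzConfig(readout_qubits=(0, 1)).n_classes == 4
        assert AnsatzConfig(readout_qubits=(0,)).n_classes == 2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            AnsatzConfig(n_qubits=1)
        with pytest.raises(ValueError):
            AnsatzConfig(readout_qubits=(0, 0))
        with pytest.raises(ValueError):
            AnsatzConfig(readout_qubits=(4,))

    def test_init_params_range_and_shape(self, ansatz, rng):
        p = init_params(ansatz, rng)
        assert p.shape == (6, 4, 3)
        assert np.all(np.abs(p) <= np.pi)


class TestForward:
    def test_zero_params_zero_input_is_identity_circuit(self, ansatz):
        p = np.zeros(ansatz.param_shape)
        probs = forward(p, np.zeros(4), ansatz)
        np.testing.assert_allclose(probs, [1, 0, 0, 0], atol=1e-12)
        assert predict(p, np.zeros(4), ansatz) == 0

    def test_forward_outputs_distribution(self, ansatz, rng):
        for _ in range(25):
            p = init_params(ansatz, rng)
            x = rng.dirichlet(np.ones(4))
            probs = forward(p, x, ansatz)
            assert np.all(probs >= 0)
            assert abs(probs.sum() - 1) < 1e-10

    def test_forward_matches_layerwise_kronecker_oracle(self, rng):
        cfg = AnsatzConfig(n_qubits=4, n_layers=2)
        p = init_params(cfg, rng)
        x = rng.dirichlet(np.ones(4))
        amps = np.zeros(16, dtype=np.complex128)
        amps[0] = 1.0
        for layer in range(2):
            for q in range(4):
                g = gate_rot(*(p[layer, q] + np.pi * x[q]))
                amps = kron_apply_1q(amps, g, q, 4)
            for q in range(3):
                amps = kron_cnot_matrix(4, q, q + 1) @ amps
        want = np.abs(amps.reshape(4, 4)) ** 2
        want = want.sum(axis=1)  # marginal of qubits (0, 1)
        np.testing.assert_allclose(forward(p, x, cfg), want, atol=1e-12)

    def test_batch_path_matches_scalar_path(self, ansatz, rng):
        p = init_params(ansatz, rng)
        X = rng.dirichlet(np.ones(4), size=7)
        batched = forward_batch(p, X, ansatz)
        for i in range(7):
            np.testing.assert_allclose(batched[i], forward(p, X[i], ansatz), atol=1e-12)

    def test_forward_is_deterministic(self, ansatz, rng):
        p = init_params(ansatz, rng)
        x = rng.dirichlet(np.ones(4))
        a, b = forward(p, x, ansatz), forward(p, x, ansatz)
        assert np.array_equal(a, b)

    def test_two_class_readout_marginalizes_qubit_zero(self, rng):
        cfg = AnsatzConfig(readout_qubits=(0,))
        p = init_params(cfg, rng)
        x = rng.dirichlet(np.ones(4))
        full = forward_batch(p, x[None], AnsatzConfig(readout_qubits=(0, 1)))[0]
        two = forward(p, x, cfg)
        np.testing.assert_allclose(two, [full[0] + full[1], full[2] + full[3]], atol=1e-12)

    def test_short_score_vector_tiles_onto_register(self, rng):
        # two-class scores drive the same four-qubit circuit by tiling
        cfg = AnsatzConfig(readout_qubits=(0,))
        p = init_params(cfg, rng)
        x2 = np.array([0.8, 0.2])
        np.testing.assert_allclose(
            forward(p, x2, cfg), forward(p, np.tile(x2, 2), cfg), atol=1e-14
        )
        with pytest.raises(ValueError):
            forward(p, np.array([0.5, 0.3, 0.2]), cfg)

    def test_param_shape_mismatch_rejected(self, ansatz):
        with pytest.raises(ValueError):
            forward(np.zeros((5, 4, 3)), np.zeros(4), ansatz)

    def test_predict_breaks_ties_toward_lowest_class(self, ansatz):
        assert int(np.argmax(np.array([0.25, 0.25, 0.25, 0.25]))) == 0
        assert predict(np.zeros(ansatz.param_shape), np.zeros(4), ansatz) == 0


class TestBuildLayer:
    def test_identity_layer_fixes_all_zero_state(self):
        s = zero_state(4)
        out = build_layer(s, np.zeros((4, 3)), np.zeros(4))
        np.testing.assert_allclose(out.amplitudes, s.amplitudes, atol=1e-12)

    def test_layer_preserves_norm(self, rng):
        out = build_layer(zero_state(4), rng.uniform(-np.pi, np.pi, (4, 3)),
                          rng.dirichlet(np.ones(4)))
        assert abs(np.linalg.norm(out.amplitudes) - 1) < 1e-10

    def test_layer_equals_explicit_gate_sequence(self, rng):
        angles = rng.uniform(-np.pi, np.pi, (4, 3))
        x = rng.dirichlet(np.ones(4))
        got = build_layer(zero_state(4), angles, x)
        s = zero_state(4)
        for q in range(4):
            s = apply_1q(s, gate_rot(*(angles[q] + np.pi * x[q])), q)
        for q in range(3):
            s = apply_cnot(s, q, q + 1)
        np.testing.assert_allclose(got.amplitudes, s.amplitudes, atol=1e-12)


class TestLossAndGradient:
    def test_uniform_output_loss_is_log4(self, ansatz):
        # a uniform readout on 4 classes costs exactly ln 4
        probs = np.full(4, 0.25)
        assert np.isclose(-np.log(probs[2] + 1e-12), np.log(4), atol=1e-9)
        # and the implemented loss reproduces a direct recomputation
        rng = np.random.default_rng(3)
        p = init_params(ansatz, rng)
        X = rng.dirichlet(np.ones(4), size=9)
        y = rng.integers(0, 4, size=9)
        expected = np.mean(
            [-np.log(forward(p, X[i], ansatz)[y[i]] + 1e-12) for i in range(9)]
        )
        assert np.isclose(cross_entropy_loss(p, (X, y), ansatz), expected, atol=1e-12)

    def test_probability_one_prediction_gives_zero_loss_and_gradient(self, ansatz):
        p = np.zeros(ansatz.param_shape)
        batch = (np.zeros((1, 4)), np.array([0]))
        assert cross_entropy_loss(p, batch, ansatz) < 1e-9
        g = gradient(p, batch, ansatz, method="fd")
        assert np.linalg.norm(g) < 1e-6

    def test_empty_batch_rejected(self, ansatz):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros(ansatz.param_shape), [], ansatz)

    def test_label_out_of_range_rejected(self, ansatz):
        with pytest.raises(ValueError):
            cross_entropy_loss(
                np.zeros(ansatz.param_shape), (np.zeros((1, 4)), np.array([4])), ansatz
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parameter_shift_matches_finite_differences(self, seed):
        cfg = AnsatzConfig(n_layers=1)
        rng = np.random.default_rng(seed)
        p = init_params(cfg, rng)
        X = rng.dirichlet(np.ones(4), size=5)
        y = rng.integers(0, 4, size=5)
        g_fd = gradient(p, (X, y), cfg, method="fd")
        g_ps = gradient(p, (X, y), cfg, method="parameter-shift")
        assert np.max(np.abs(g_fd - g_ps)) < 1e-5

    def test_gradient_matches_slow_per_angle_differences(self, rng):
        # independent oracle: perturb each angle separately via the scalar path
        cfg = AnsatzConfig(n_layers=1)
        p = init_params(cfg, rng)
        X = rng.dirichlet(np.ones(4), size=3)
        y = np.array([0, 1, 2])
        h = 1e-6
        want = np.zeros_like(p)
        for idx in np.ndindex(p.shape):
            pp, pm = p.copy(), p.copy()
            pp[idx] += h
            pm[idx] -= h
            lp = np.mean([-np.log(forward(pp, X[i], cfg)[y[i]] + 1e-12) for i in range(3)])
            lm = np.mean([-np.log(forward(pm, X[i], cfg)[y[i]] + 1e-12) for i in range(3)])
            want[idx] = (lp - lm) / (2 * h)
        _, got = loss_and_gradient(p, (X, y), cfg, method="fd")
        np.testing.assert_allclose(got, want, atol=1e-7)

    def test_unknown_gradient_method_rejected(self, ansatz):
        with pytest.raises(ValueError):
            gradient(np.zeros(ansatz.param_shape), (np.zeros((1, 4)), np.array([0])),
                     ansatz, method="analytic")


class TestCheckpoint:
    def test_round_trip_is_bit_exact(self, ansatz, rng, tmp_path):
        p = init_params(ansatz, rng)
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, p, ansatz, seed=42, metadata={"note": "test"})
        p2, cfg2, doc = load_checkpoint(path)
        assert np.array_equal(p, p2)
        assert cfg2 == ansatz
        assert doc["seed"] == 42
        assert doc["metadata"]["note"] == "test"

    def test_loaded_params_predict_identically(self, ansatz, rng, tmp_path):
        p = init_params(ansatz, rng)
        X = rng.dirichlet(np.ones(4), size=5)
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, p, ansatz)
        p2, cfg2, _ = load_checkpoint(path)
        assert np.array_equal(predict_batch(p, X, ansatz), predict_batch(p2, X, cfg2))
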