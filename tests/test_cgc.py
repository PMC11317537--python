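"""Gating, fusion, towers, masked loss, backprop correctness and training."""

import numpy as np
import pytest

from kinemoe.cgc import (
    CGCConfig,
    CGCModel,
    _assemble_x,
    _aux_backward,
    _backward,
    _forward,
    fuse,
    gate_weights,
    masked_l2_loss,
    select_matrix,
    tower_forward,
    train,
)
from kinemoe.featurize import (
    AuxEncoderSpec,
    FeatureSet,
    build_rbf_centers,
)


def tiny_featureset(n=6, d_e=3, d_s=2, aux_dim=2, seed=0, n_ph=3, labels=None):
    rng = np.random.default_rng(seed)
    spec = AuxEncoderSpec(
        ph_centers=build_rbf_centers([6.0, 6.0 + 0.1 * (n_ph - 1)], 0.1),
        temp_centers=build_rbf_centers([25.0, 25.2], 0.1),
        organism_vocab=("A", "B"),
        aux_dim=aux_dim,
    )
    y = labels if labels is not None else rng.standard_normal((n, 2))
    return FeatureSet(
        enzyme=rng.standard_normal((n, d_e)),
        substrate=rng.standard_normal((n, d_s)),
        rbf_ph=rng.random((n, spec.n_ph)),
        rbf_temp=rng.random((n, spec.n_temp)),
        organism_idx=rng.integers(0, 3, size=n),
        labels=np.asarray(y, dtype=float),
        label_mask=np.ones((n, 2), dtype=bool),
        keys=[(f"C{i}", f"S{i}", 7.0, 30.0, "A") for i in range(n)],
        enzyme_types=["wild_type"] * n,
        spec=spec,
    )


class TestGate:
    def test_zero_matrix_gives_uniform_weights(self):
        w = gate_weights(np.ones(4), np.zeros((5, 4)))
        np.testing.assert_allclose(w, np.full(5, 0.2), atol=1e-12)

    def test_closed_form_two_expert_softmax(self):
        W = np.array([[np.log(2.0)], [0.0]])
        w = gate_weights(np.array([1.0]), W)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_simplex_property_over_random_inputs(self):
        rng = np.random.default_rng(42)
        W = rng.standard_normal((8, 12))
        for _ in range(1000):
            w = gate_weights(rng.standard_normal(12) * 10, W)
            assert np.all(w > 0)
            assert abs(w.sum() - 1.0) < 1e-9

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            gate_weights(np.ones(3), np.zeros((2, 4)))


class TestFuse:
    def test_single_expert_weight_forced_to_one(self):
        S = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(fuse(np.array([1.0]), S), S[0])

    def test_equal_weights_give_mean(self):
        S = np.array([[2.0, 4.0], [6.0, 8.0]])
        np.testing.assert_allclose(fuse(np.array([0.5, 0.5]), S), [4.0, 6.0])

    def test_matches_explicit_weighted_sum_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_exp, h = rng.integers(2, 9), rng.integers(2, 9)
            w = rng.dirichlet(np.ones(n_exp))
            S = rng.standard_normal((n_exp, h))
            explicit = sum(w[i] * S[i] for i in range(n_exp))
            np.testing.assert_allclose(fuse(w, S), explicit, atol=1e-6)


class TestTower:
    def test_zero_weights_output_final_bias(self):
        W = [np.zeros((4, 3)), np.zeros((3, 1))]
        b = [np.zeros(3), np.array([-1.7])]
        assert tower_forward(np.ones(4), W, b) == pytest.approx(-1.7)

    def test_single_affine_layer_hand_computed(self):
        W = [np.array([[2.0], [-1.0]])]
        b = [np.array([0.5])]
        # identity output: 2*1 - 1*3 + 0.5 = -0.5 (negative allowed)
        assert tower_forward(np.array([1.0, 3.0]), W, b) == pytest.approx(-0.5)

    def test_relu_only_between_hidden_layers(self):
        # hidden ReLU clips, output layer does not
        W = [np.array([[1.0]]), np.array([[1.0]])]
        b = [np.array([0.0]), np.array([-5.0])]
        assert tower_forward(np.array([-3.0]), W, b) == pytest.approx(-5.0)


class TestMaskedLoss:
    def test_perfect_single_label_is_zero(self):
        assert masked_l2_loss(
            np.array([[1.0, 9.9]]), np.array([[1.0, 0.0]]),
            np.array([[True, False]])
        ) == 0.0

    def test_mean_over_observed_labels(self):
        loss = masked_l2_loss(
            np.array([[1.0, 2.0]]), np.array([[0.0, 0.0]]),
            np.array([[True, True]])
        )
        assert loss == pytest.approx((1 + 4) / 2)

    def test_invariant_to_masked_placeholder(self):
        preds = np.array([[1.0, 5.0]])
        mask = np.array([[True, False]])
        a = masked_l2_loss(preds, np.array([[0.0, 123.0]]), mask)
        b = masked_l2_loss(preds, np.array([[0.0, -7.0]]), mask)
        assert a == b

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            masked_l2_loss(np.ones((2, 2)), np.ones((2, 2)),
                           np.zeros((2, 2), dtype=bool))


def small_config(fs, **over):
    kw = dict(
        input_dim=fs.input_dim, n_shared_experts=2, n_specific_experts=2,
        expert_dim=5, expert_dropout=0.0, tower_dims=(4, 1),
        batch_size=3, epochs=3, learning_rate=1e-3, seed=0,
    )
    kw.update(over)
    return CGCConfig(**kw)


class TestForward:
    def test_batch_shapes_and_eval_determinism(self):
        fs = tiny_featureset(n=5)
        model = CGCModel.init(small_config(fs), fs.spec)
        p1 = model.forward(fs)
        p2 = model.forward(fs)
        assert p1.shape == (5, 2)
        np.testing.assert_array_equal(p1, p2)

    def test_forward_equals_gate_select_fuse_tower_composition(self):
        """The batched network recomposes from the standalone operations."""
        fs = tiny_featureset(n=4)
        model = CGCModel.init(small_config(fs), fs.spec)
        X, _ = _assemble_x(model.params, fs)
        preds = model.forward(fs)
        for i in range(4):
            x = X[i]
            for ti, task in enumerate(model.config.tasks):
                w = gate_weights(x, model.params[f"L0.gate.{task}"])
                S = select_matrix(model, x, task)
                g = fuse(w, S)
                Ws = [model.params[f"tower.{task}.W{j}"] for j in range(2)]
                bs = [model.params[f"tower.{task}.b{j}"] for j in range(2)]
                y = tower_forward(g, Ws, bs)
                assert y == pytest.approx(preds[i, ti], abs=1e-9)

    def test_select_matrix_rows_match_per_expert_recomputation(self):
        fs = tiny_featureset(n=1)
        model = CGCModel.init(small_config(fs), fs.spec)
        X, _ = _assemble_x(model.params, fs)
        x = X[0]
        S = select_matrix(model, x, "kcat")
        assert S.shape == (4, 5)  # 2 specific + 2 shared
        rows = []
        for g in ("kcat", "shared"):
            for i in range(2):
                W = model.params[f"L0.exp.{g}.{i}.W0"]
                b = model.params[f"L0.exp.{g}.{i}.b0"]
                rows.append(np.maximum(x @ W + b, 0.0))
        np.testing.assert_allclose(S, np.stack(rows), atol=1e-12)

    def test_input_dim_mismatch_raises(self):
        fs = tiny_featureset()
        model = CGCModel.init(small_config(fs, input_dim=fs.input_dim + 1), fs.spec)
        with pytest.raises(ValueError):
            model.forward(fs)


class TestBackprop:
    @pytest.mark.parametrize("n_layers", [1, 2])
    def test_gradients_match_finite_differences(self, n_layers):
        """Analytic backprop vs central differences, including the stacked
        variant and the trainable auxiliary encoder."""
        fs = tiny_featureset(n=4, seed=2)
        cfg = small_config(fs, n_cgc_layers=n_layers, expert_dim=4,
                           tower_dims=(3, 1))
        model = CGCModel.init(cfg, fs.spec)
        p = model.params
        y, mask = fs.labels, fs.label_mask

        def loss_at(params):
            X, _ = _assemble_x(params, fs)
            preds, _ = _forward(params, cfg, X, train=False)
            return masked_l2_loss(preds, y, mask)

        X, x_cache = _assemble_x(p, fs)
        preds, cache = _forward(p, cfg, X, train=False)
        dpreds = 2.0 * (preds - y) * mask / mask.sum()
        grads, dX = _backward(p, cfg, cache, dpreds)
        _aux_backward(grads, x_cache, dX)

        rng = np.random.default_rng(0)
        eps = 1e-6
        for name in sorted(p):
            flat = p[name].reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at(p)
                flat[idx] = orig - eps
                down = loss_at(p)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, abs=2e-5), name

    def test_no_shared_experts_decouples_tasks(self):
        """With m_s=0, one task's loss has exactly zero gradient on the
        other task's specific experts."""
        fs = tiny_featureset(n=5, seed=4)
        cfg = small_config(fs, n_shared_experts=0)
        model = CGCModel.init(cfg, fs.spec)
        X, _ = _assemble_x(model.params, fs)
        preds, cache = _forward(model.params, cfg, X, train=False)
        # gradient of the kcat task only
        dpreds = np.zeros_like(preds)
        dpreds[:, 0] = 1.0
        grads, _ = _backward(model.params, cfg, cache, dpreds)
        for name, g in grads.items():
            if ".exp.km." in name or "gate.km" in name or "tower.km" in name:
                assert np.all(g == 0.0), name
            if ".exp.kcat." in name:
                assert np.any(g != 0.0), name


class TestTraining:
    def test_loss_decreases_on_learnable_signal(self):
        rng = np.random.default_rng(1)
        n = 500
        fs = tiny_featureset(n=n, d_e=6, d_s=4, seed=1)
        # linear signal in the raw feature blocks
        beta = rng.standard_normal(10)
        signal = np.concatenate([fs.enzyme, fs.substrate], axis=1) @ beta
        fs.labels = np.stack([signal, -signal], axis=1)
        cfg = small_config(fs, epochs=5, batch_size=16, learning_rate=3e-3)
        _, hist = train(fs.subset(np.arange(400)), fs.subset(np.arange(400, n)), cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_pure_noise_labels_give_no_skill(self):
        rng = np.random.default_rng(9)
        n = 1000
        fs = tiny_featureset(n=n, d_e=6, d_s=4, seed=5)
        fs.labels = rng.standard_normal((n, 2))
        cfg = small_config(fs, epochs=4, batch_size=32, learning_rate=1e-3)
        model, hist = train(fs.subset(np.arange(800)), fs.subset(np.arange(800, n)), cfg)
        from kinemoe.evalsplit import r2

        val = fs.subset(np.arange(800, n))
        preds = model.forward(val)
        for t in range(2):
            assert abs(r2(val.labels[:, t], preds[:, t])) < 0.1

    def test_identical_seeds_identical_histories(self):
        fs = tiny_featureset(n=40, seed=6)
        cfg = small_config(fs, epochs=3, batch_size=8,
                           expert_dropout=0.2, seed=123)
        tr, va = fs.subset(np.arange(30)), fs.subset(np.arange(30, 40))
        m1, h1 = train(tr, va, cfg)
        m2, h2 = train(tr, va, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_empty_training_set_raises(self):
        fs = tiny_featureset(n=4)
        with pytest.raises(ValueError):
            train(fs.subset(np.array([], dtype=int)), fs, small_config(fs))


class TestPrediction:
    def test_efficiency_and_linear_scale_columns(self):
        from kinemoe.cgc import predict_entries

        fs = tiny_featureset(n=3)
        model = CGCModel.init(small_config(fs), fs.spec)
        table = predict_entries(model, fs)
        assert len(table) == 3
        np.testing.assert_allclose(
            table["pred_log10_efficiency"],
            table["pred_log10_kcat"] - table["pred_log10_km"],
        )
        assert (table["pred_kcat"] > 0).all() and (table["pred_km"] > 0).all()
        # order preserved
        assert list(table["canonical_smiles"]) == ["C0", "C1", "C2"]

    def test_save_load_round_trip(self, tmp_path):
        from kinemoe.cgc import load_model, save_model

        fs = tiny_featureset(n=3)
        model = CGCModel.init(small_config(fs), fs.spec)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(model.forward(fs), back.forward(fs))
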