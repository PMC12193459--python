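"""Architecture components, likelihood and training behaviour."""

import numpy as np
import pytest

from hemexpand import autodiff as ad
from hemexpand import nn
from hemexpand.autodiff import Tensor
from hemexpand.kernels import KernelSpec, stack_kernels
from hemexpand.model import (
    AlignmentError,
    EncoderConfig,
    GPPrediction,
    MSKTModel,
    SequenceBatch,
    TrainingConfig,
    TrainingDivergence,
    _nll_loss,
    embed,
    kernels_to_sequence,
    load_checkpoint,
    negative_log_likelihood,
    predict_expansion_probability,
    save_checkpoint,
    train,
)

TINY_ENCODER = EncoderConfig(
    n_heads=2, key_dim=3, model_dim=8, ffn_dim=10, n_layers=1, dropout=0.0
)


def tiny_model(n_features=3, seq_len=6, seed=0, **kw):
    m = MSKTModel(n_features, seq_len, embed_dim=4, encoder=TINY_ENCODER, seed=seed, **kw)
    m.lengthscales = [None, None, 1.0, 1.0]
    m.kernel_scales = [1.0, 0.1, 1.0, 1.0]
    return m


class TestEmbed:
    def test_identity_configuration(self):
        m = tiny_model(n_features=4)
        m.embedding.W.data = np.eye(4)
        m.embedding.b.data = np.zeros(4)
        X = np.random.default_rng(0).standard_normal((6, 4))
        np.testing.assert_allclose(m.embed(X), X)

    def test_shape_and_determinism(self, rng):
        X = rng.standard_normal((7, 5))
        out1 = embed(X, 12, seed=3)
        out2 = embed(X, 12, seed=3)
        assert out1.shape == (7, 12)
        np.testing.assert_array_equal(out1, out2)
        assert not np.allclose(out1, embed(X, 12, seed=4))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            embed(np.array([[np.nan, 1.0]]), 4, seed=0)


class TestKernelsToSequence:
    def test_identity_truncation_recovers_kernel_rows(self, rng):
        X = rng.standard_normal((4, 3))
        stack = stack_kernels(X, [KernelSpec("linear")])
        out = kernels_to_sequence(stack, model_dim=4, positional=False)
        np.testing.assert_allclose(out, stack.stacked[0])

    def test_output_shape(self, rng):
        X = rng.standard_normal((5, 3))
        stack = stack_kernels(X, [KernelSpec("linear"), KernelSpec("rbf", lengthscale=1.0)])
        assert kernels_to_sequence(stack, model_dim=7).shape == (5, 7)

    def test_positional_encoding_breaks_time_symmetry(self, rng):
        X = rng.standard_normal((5, 3))
        stack_f = stack_kernels(X, [KernelSpec("rbf", lengthscale=1.0)])
        stack_r = stack_kernels(X[::-1], [KernelSpec("rbf", lengthscale=1.0)])
        # identity projection (model_dim = N*T): reversing time permutes the
        # profile rows and columns in lockstep when codes are disabled...
        no_pos_f = kernels_to_sequence(stack_f, 5, positional=False)
        no_pos_r = kernels_to_sequence(stack_r, 5, positional=False)
        np.testing.assert_allclose(no_pos_f[::-1, ::-1], no_pos_r, atol=1e-12)
        # ...while position codes make the reversed sequence genuinely different
        with_pos_f = kernels_to_sequence(stack_f, 5, positional=True)
        with_pos_r = kernels_to_sequence(stack_r, 5, positional=True)
        assert not np.allclose(with_pos_f[::-1, ::-1], with_pos_r)

    def test_invalid_dim(self, rng):
        stack = stack_kernels(rng.standard_normal((4, 2)), [KernelSpec("linear")])
        with pytest.raises(ValueError):
            kernels_to_sequence(stack, model_dim=0)


class TestAttention:
    def test_rows_sum_to_one(self, rng):
        att = nn.MultiHeadAttention(8, 2, 4, rng)
        att(Tensor(rng.standard_normal((3, 5, 8))))
        sums = att.last_attention.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_softmax_saturation(self, rng):
        """When one logit dominates by >= 20, the output row is the dominant value row."""
        att = nn.MultiHeadAttention(2, 1, 2, rng)
        att.wq.W.data = np.eye(2) * 40.0
        att.wq.b.data[:] = 0
        att.wk.W.data = np.eye(2)
        att.wk.b.data[:] = 0
        att.wv.W.data = np.eye(2)
        att.wv.b.data[:] = 0
        att.wo.W.data = np.eye(2)
        att.wo.b.data[:] = 0
        x = np.array([[[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]]])
        out = att(Tensor(x)).data
        np.testing.assert_allclose(out[0, 0], x[0, 0], atol=1e-6)
        np.testing.assert_allclose(out[0, 1], x[0, 1], atol=1e-6)

    def test_hand_computed_two_step_oracle(self):
        """Single head on T=2, d=2 against spelled-out matrix arithmetic."""
        rng = np.random.default_rng(0)
        att = nn.MultiHeadAttention(2, 1, 2, rng)
        Wq = np.array([[0.3, -0.1], [0.2, 0.4]])
        Wk = np.array([[0.1, 0.5], [-0.2, 0.3]])
        Wv = np.array([[0.7, 0.0], [0.1, -0.3]])
        Wo = np.eye(2)
        for layer, W in ((att.wq, Wq), (att.wk, Wk), (att.wv, Wv), (att.wo, Wo)):
            layer.W.data = W
            layer.b.data[:] = 0
        x = np.array([[1.0, 2.0], [-1.0, 0.5]])
        q, k, v = x @ Wq, x @ Wk, x @ Wv
        logits = q @ k.T / np.sqrt(2.0)
        weights = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        expected = weights @ v
        out = att(Tensor(x[None])).data[0]
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestEncoderBlock:
    def test_zero_ffn_reduces_to_layernorm_of_attended(self, rng):
        block = nn.EncoderBlock(8, 2, 4, 10, 0.0, rng)
        block.ffn.fc2.W.data[:] = 0
        block.ffn.fc2.b.data[:] = 0
        x = Tensor(rng.standard_normal((2, 5, 8)))
        attended = x + block.attention(x)
        np.testing.assert_allclose(block(x).data, block.norm(attended).data, atol=1e-12)

    def test_layernorm_rows_standardized(self, rng):
        ln = nn.LayerNorm(16)
        x = Tensor(rng.standard_normal((4, 16)) * 3 + 2)
        z = ln.normalized(x).data
        np.testing.assert_allclose(z.mean(axis=-1), 0.0, atol=1e-5)
        np.testing.assert_allclose(z.var(axis=-1), 1.0, atol=1e-5)

    def test_eval_mode_deterministic(self, rng):
        m = tiny_model()
        X = rng.standard_normal((2, 6, 3))
        m.set_training(False)
        a = m.forward(X)["mean"].data
        b = m.forward(X)["mean"].data
        np.testing.assert_array_equal(a, b)

    def test_dropout_only_in_training(self, rng):
        drop = nn.Dropout(0.5, np.random.default_rng(0))
        x = Tensor(np.ones((10, 10)))
        drop.set_training(False)
        np.testing.assert_array_equal(drop(x).data, x.data)
        drop.set_training(True)
        assert not np.array_equal(drop(x).data, x.data)


class TestHeads:
    def test_point_head_bias_only(self, rng):
        m = tiny_model()
        m.point_head.W.data[:] = 0
        m.point_head.b.data[:] = 2.5
        e = rng.standard_normal((3, 6, 8))
        np.testing.assert_allclose(m.predict_head(e), 2.5)

    def test_point_head_linearity(self, rng):
        m = tiny_model()
        m.point_head.b.data[:] = 0
        e = rng.standard_normal((2, 6, 8))
        np.testing.assert_allclose(m.predict_head(3.0 * e), 3.0 * m.predict_head(e), atol=1e-12)

    def test_variance_softplus_floor(self, rng):
        m = tiny_model()
        pred = m.predict(rng.standard_normal((2, 6, 3)))[0]
        assert pred.variance_path.min() >= 1e-6

    def test_variance_at_zero_preactivation(self, rng):
        m = tiny_model()
        m.var_head.W.data[:] = 0
        m.var_head.b.data[:] = 0
        pred = m.map_to_gp(rng.standard_normal((6, 8)))
        np.testing.assert_allclose(pred.variance_path, np.log(2.0) + 1e-6, atol=1e-12)

    def test_constant_mean_path(self, rng):
        m = tiny_model()
        m.mean_head.W.data[:] = 0
        m.mean_head.b.data[:] = 7.0
        pred = m.map_to_gp(rng.standard_normal((6, 8)))
        np.testing.assert_allclose(pred.mean_path, 7.0)

    def test_gp_prediction_validation(self):
        with pytest.raises(ValueError):
            GPPrediction(np.zeros(3), np.zeros(3))


class TestNegativeLogLikelihood:
    def test_density_at_mode(self):
        pred = GPPrediction(np.array([5.0, 5.0]), np.array([1.0, 1.0]))
        loss = negative_log_likelihood([(0, 5.0)], pred, delta=0.0)
        assert loss == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-9)  # 0.91894

    def test_delta_regularized_value(self):
        pred = GPPrediction(np.array([5.0]), np.array([1.0]))
        loss = negative_log_likelihood([(0, 5.0)], pred, delta=1.0)
        assert loss == pytest.approx(-np.log(1 / np.sqrt(2 * np.pi) + 1), abs=1e-9)

    def test_monotone_in_residual(self):
        pred = GPPrediction(np.zeros(1), np.ones(1))
        losses = [
            negative_log_likelihood([(0, v)], pred, delta=0.0) for v in (0.0, 1.0, 2.0, 5.0)
        ]
        assert np.all(np.diff(losses) > 0)

    def test_alignment_error(self):
        pred = GPPrediction(np.zeros(3), np.ones(3))
        with pytest.raises(AlignmentError):
            negative_log_likelihood([(7.5, 1.0)], pred)

    def test_matches_training_loss(self, rng):
        """The tensor-based training loss agrees with the reference function."""
        m = tiny_model()
        X = rng.standard_normal((3, 6, 3))
        vols = rng.normal(5, 1, (3, 6))
        out = m.forward(X)
        _, nll = _nll_loss(out, vols, delta=1e-6, point_weight=0.0)
        ref = 0.0
        for i in range(3):
            pred = GPPrediction(out["mean"].data[i], out["variance"].data[i])
            ref += negative_log_likelihood(list(enumerate(vols[i])), pred, delta=1e-6)
        assert nll == pytest.approx(ref / vols.size, rel=1e-9)


class TestGradientsAndTraining:
    def test_nll_gradients_match_finite_differences(self, rng):
        m = tiny_model()
        X = rng.standard_normal((2, 6, 3))
        vols = rng.normal(5, 1, (2, 6))
        loss, _ = _nll_loss(m.forward(X), vols, 1e-6, 0.1)
        loss.backward()
        eps = 1e-6
        for name, p in m.named_parameters():
            idx = np.unravel_index(np.argmax(np.abs(p.grad)), p.grad.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp, _ = _nll_loss(m.forward(X), vols, 1e-6, 0.1)
            p.data[idx] = orig - eps
            lm, _ = _nll_loss(m.forward(X), vols, 1e-6, 0.1)
            p.data[idx] = orig
            fd = (lp.data - lm.data) / (2 * eps)
            assert abs(fd - p.grad[idx]) <= 1e-4 * max(1.0, abs(fd)), name

    def test_zero_learning_rate_keeps_parameters(self, rng):
        m = tiny_model()
        before = {k: v.copy() for k, v in m.state_dict().items()}
        X = rng.standard_normal((8, 6, 3))
        vols = rng.normal(5, 1, (8, 6))
        cfg = TrainingConfig(learning_rate=0.0, max_epochs=3, patience=2,
                             batch_size=4, seed=0, lr_decay=1.0)
        train(m, X, vols, cfg, X, vols)
        after = m.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_training_reduces_nll_and_is_seeded(self, rng):
        X = rng.standard_normal((24, 6, 3))
        vols = 5.0 + 2.0 * X[:, :, 0] + rng.normal(0, 0.3, (24, 6))
        hists = []
        finals = []
        for _ in range(2):
            m = tiny_model()
            cfg = TrainingConfig(learning_rate=0.01, optimizer="adam", batch_size=8,
                                 max_epochs=30, patience=29, seed=5)
            h = train(m, X, vols, cfg, X, vols)
            hists.append(h)
            finals.append(m.state_dict())
        assert hists[0]["train_nll"].iloc[-1] < hists[0]["train_nll"].iloc[0]
        # bitwise reproducibility under the same seed
        for k in finals[0]:
            np.testing.assert_array_equal(finals[0][k], finals[1][k])

    def test_early_stopping_on_plateau(self, rng):
        """With a frozen model the validation loss never improves, so training
        stops within patience + 1 epochs of the start."""
        m = tiny_model()
        X = rng.standard_normal((10, 6, 3))
        vols = rng.normal(5, 1, (10, 6))
        cfg = TrainingConfig(learning_rate=0.0, max_epochs=50, patience=3,
                             batch_size=5, seed=0, lr_decay=1.0)
        h = train(m, X, vols, cfg, X, vols)
        assert len(h) <= 5

    def test_divergence_raises(self, rng):
        m = tiny_model()
        X = rng.standard_normal((8, 6, 3))
        vols = rng.normal(5, 1, (8, 6))
        cfg = TrainingConfig(learning_rate=1e9, optimizer="sgd", batch_size=4,
                             max_epochs=10, patience=5, seed=0)
        with pytest.raises(TrainingDivergence), np.errstate(all="ignore"):
            train(m, X, vols, cfg, X, vols)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(patience=10, max_epochs=10)
        with pytest.raises(ValueError):
            TrainingConfig(n_folds=1)
        with pytest.raises(ValueError):
            TrainingConfig(optimizer="lbfgs")
        with pytest.raises(ValueError):
            EncoderConfig(model_dim=10, n_heads=3)


class TestPredictExpansionProbability:
    def make_batch(self, rng, T=6, v0=10.0):
        return SequenceBatch(
            features=rng.standard_normal((T, 3)),
            timestamps=np.arange(T, dtype=float),
            patient_id="p1",
            baseline_volume=v0,
        )

    def test_mean_far_below_threshold(self, rng):
        m = tiny_model()
        m.mean_head.W.data[:] = 0
        m.mean_head.b.data[:] = -100.0
        m.var_head.W.data[:] = 0
        m.var_head.b.data[:] = -20.0  # softplus ~ 2e-9
        _, crossing = predict_expansion_probability(m, self.make_batch(rng))
        assert crossing.probability < 1e-6

    def test_mean_pinned_at_threshold(self, rng):
        from hemexpand.crossing import expansion_threshold

        m = tiny_model()
        c = expansion_threshold(10.0).c
        m.mean_head.W.data[:] = 0
        m.mean_head.b.data[:] = c
        m.var_head.W.data[:] = 0
        m.var_head.b.data[:] = 0
        T = 6
        _, crossing = predict_expansion_probability(m, self.make_batch(rng, T=T))
        assert crossing.probability == pytest.approx(1 - np.exp(-0.5 * T), abs=1e-9)

    def test_invariant_to_dead_feature_column(self, rng):
        m = tiny_model(n_features=3)
        X = rng.standard_normal((6, 3))
        batch = SequenceBatch(X, np.arange(6.0), "p", 10.0)
        _, base = predict_expansion_probability(m, batch)

        m2 = tiny_model(n_features=4)
        m2.load_state_dict(
            {
                k: v if k != "embedding.W" else np.vstack([v, np.zeros((1, v.shape[1]))])
                for k, v in m.state_dict().items()
            }
        )
        m2.lengthscales, m2.kernel_scales = m.lengthscales, m.kernel_scales
        m2.y_loc, m2.y_scale = m.y_loc, m.y_scale
        padded = SequenceBatch(np.hstack([X, np.zeros((6, 1))]), np.arange(6.0), "p", 10.0)
        _, same = predict_expansion_probability(m2, padded)
        assert same.probability == pytest.approx(base.probability, abs=1e-12)

    def test_sequence_batch_validation(self):
        with pytest.raises(ValueError):
            SequenceBatch(np.ones((1, 3)), np.zeros(1), "p", 1.0)
        with pytest.raises(ValueError):
            SequenceBatch(np.full((3, 2), np.nan), np.zeros(3), "p", 1.0)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        m = tiny_model()
        m.y_loc, m.y_scale = 3.0, 2.0
        X = rng.standard_normal((2, 6, 3))
        before = m.predict(X)
        path = tmp_path / "model.mskt"
        save_checkpoint(m, path)
        back = load_checkpoint(path)
        after = back.predict(X)
        np.testing.assert_allclose(before[0].mean_path, after[0].mean_path, atol=1e-12)
        np.testing.assert_allclose(before[1].variance_path, after[1].variance_path, atol=1e-12)


class TestCrossValidate:
    def test_fold_metrics_shape(self, rng):
        from hemexpand.model import cross_validate

        X = rng.standard_normal((18, 6, 3))
        vols = rng.normal(5, 1, (18, 6))
        cfg = TrainingConfig(learning_rate=0.01, optimizer="adam", batch_size=6,
                             max_epochs=3, patience=2, n_folds=3, seed=0)
        folds = cross_validate(lambda: tiny_model(), X, vols, cfg)
        assert len(folds) == 3
        assert set(folds.columns) >= {"fold", "val_nll", "epochs"}
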