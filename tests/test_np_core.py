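"""Model architecture contracts: encoders, latents, decoding, loss, variants."""

import numpy as np
import pytest
from dataclasses import replace

from snpflow import autodiff as ad
from snpflow.np_core import (
    ModelConfig,
    SNPNF,
    VARIANTS,
    build_variant,
    fit,
    load_checkpoint,
    predict_proba,
    save_checkpoint,
)


def tiny_cfg(**kw):
    base = dict(embedding_dim=16, n_encoder_layers=1, n_flow_steps=2, n_heads=2,
                latent_dim=8, window_k=4, learning_rate=1e-3, epochs=2,
                batch_size=8, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def random_batch(rng, B=6, k=4, F=11):
    X = rng.normal(size=(B, k, F))
    Y = rng.integers(0, 3, size=(B, k))
    y = rng.integers(0, 3, size=B)
    Xt = rng.normal(size=(B, F))
    return X, Y, y, Xt


class TestModelConfig:
    def test_defaults_match_reference_configuration(self):
        cfg = ModelConfig()
        assert (cfg.embedding_dim, cfg.n_encoder_layers, cfg.window_k) == (128, 2, 4)
        assert cfg.learning_rate == 1e-5 and cfg.epochs == 10
        assert cfg.n_flow_steps == 5

    def test_heads_must_divide_embedding(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(embedding_dim=30, n_heads=4)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ModelConfig(variant="bogus")


class TestEmbedWindow:
    def test_output_shape_reference_dims(self, rng):
        model = SNPNF(ModelConfig(embedding_dim=128, n_heads=4))
        X, Y, _, _ = random_batch(rng, B=2)
        emb = model.embed_window(X, Y)
        assert emb.shape == (2, 4, 128)

    def test_feature_order_within_visit_matters(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, _, _ = random_batch(rng, B=1)
        Xp = X[:, :, ::-1].copy()
        a = model.embed_window(X, Y).data
        b = model.embed_window(Xp, Y).data
        assert not np.allclose(a, b)

    def test_nonfinite_features_rejected(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, _, _ = random_batch(rng, B=1)
        X[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            model.embed_window(X, Y)


class TestEncoders:
    def test_identical_slots_without_positions_collapse_to_common_vector(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, _, _ = random_batch(rng, B=1)
        X[:] = X[:, :1, :]
        Y[:] = Y[:, :1]
        emb = model.embed_window(X, Y, add_positions=False)
        enc = model.encode_deterministic(emb)
        per = enc.per_point.data[0]
        assert np.allclose(per, per[0], atol=1e-10)
        assert np.allclose(enc.aggregate.data[0], per[0], atol=1e-10)

    def test_aggregate_is_arithmetic_mean(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, _, _ = random_batch(rng)
        enc = model.encode_deterministic(model.embed_window(X, Y))
        manual = enc.per_point.data.sum(axis=1) / X.shape[1]
        assert np.allclose(enc.aggregate.data, manual, atol=1e-7)

    def test_permutation_sensitivity_with_positions_invariance_without(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, _, _ = random_batch(rng, B=1)
        perm = np.array([2, 0, 3, 1])
        with_pos = model.encode_deterministic(model.embed_window(X, Y)).aggregate.data
        with_pos_perm = model.encode_deterministic(
            model.embed_window(X[:, perm], Y[:, perm])).aggregate.data
        assert not np.allclose(with_pos, with_pos_perm)
        no_pos = model.encode_deterministic(
            model.embed_window(X, Y, add_positions=False)).aggregate.data
        no_pos_perm = model.encode_deterministic(
            model.embed_window(X[:, perm], Y[:, perm], add_positions=False)).aggregate.data
        assert np.allclose(no_pos, no_pos_perm, atol=1e-10)


class TestLatentPath:
    def test_zero_depth_chain_passes_z0_through(self, rng):
        model = SNPNF(tiny_cfg(n_flow_steps=0))
        X, Y, _, _ = random_batch(rng)
        q = model.encode_latent(model.embed_window(X, Y), np.random.default_rng(0))
        assert np.array_equal(q.zK.data, q.z0.data)
        assert np.all(q.total_logdet.data == 0)

    def test_same_seed_reproduces_sample(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, _, _ = random_batch(rng)
        emb = model.embed_window(X, Y)
        q1 = model.encode_latent(emb, np.random.default_rng(5))
        q2 = model.encode_latent(emb, np.random.default_rng(5))
        assert np.array_equal(q1.z0.data, q2.z0.data)

    def test_sigma_clamped_from_below(self, rng):
        model = SNPNF(tiny_cfg())
        model.params["logsig_b"].data[:] = -50.0
        model.params["logsig_W"].data[:] = 0.0
        X, Y, _, _ = random_batch(rng)
        q = model.encode_latent(model.embed_window(X, Y), np.random.default_rng(0))
        assert np.allclose(q.sigma.data, 1e-4)


class TestDecode:
    def test_zero_weights_give_uniform_probs(self, rng):
        model = SNPNF(tiny_cfg())
        for nm in ("dec_W1", "dec_b1", "dec_W2", "dec_b2"):
            model.params[nm].data[:] = 0.0
        X, Y, _, _ = random_batch(rng)
        pred, _, _ = model.forward(X, Y, mode="eval")
        assert np.allclose(pred.probs, 1.0 / 3.0)

    def test_probs_are_simplex_rows(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, _, _ = random_batch(rng)
        pred, _, _ = model.forward(X, Y, mode="eval")
        assert np.allclose(pred.probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(pred.probs >= 0)

    def test_softmax_shift_invariance(self, rng):
        from snpflow.np_core import Prediction
        logits = rng.normal(size=(4, 3))
        p1 = Prediction(logits=ad.tensor(logits)).probs
        p2 = Prediction(logits=ad.tensor(logits + 7.3)).probs
        assert np.allclose(p1, p2, atol=1e-12)


class TestForward:
    def test_eval_mode_blind_to_target_label_and_features(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, y, Xt = random_batch(rng)
        rng_a = np.random.default_rng(3)
        rng_b = np.random.default_rng(3)
        p1, _, _ = model.forward(X, Y, mode="eval", Xt=Xt, yt=y, rng=rng_a)
        p2, _, _ = model.forward(X, Y, mode="eval", Xt=Xt * 5, yt=(y + 1) % 3, rng=rng_b)
        assert np.array_equal(p1.logits.data, p2.logits.data)

    def test_train_mode_requires_target_pair(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, _, _ = random_batch(rng)
        with pytest.raises(ValueError, match="target pair"):
            model.forward(X, Y, mode="train")

    def test_gradients_reach_every_parameter(self, rng):
        """One training step sends a nonzero gradient into every registered
        parameter, including all flow-step parameters."""
        model = SNPNF(tiny_cfg(n_flow_steps=2))
        X, Y, y, Xt = random_batch(rng, B=8)
        r = np.random.default_rng(1)
        pred, q_ctx, q_full = model.forward(X, Y, mode="train", Xt=Xt, yt=y, rng=r)
        total, _, _ = model.loss(pred, y, q_full, q_ctx, rng=r)
        total.backward()
        for name, p in model.params.items():
            assert p.grad is not None and np.any(p.grad != 0), name

    def test_forward_backward_is_finite(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, y, Xt = random_batch(rng)
        r = np.random.default_rng(2)
        pred, q_ctx, q_full = model.forward(X, Y, mode="train", Xt=Xt, yt=y, rng=r)
        total, ce, kl = model.loss(pred, y, q_full, q_ctx, rng=r)
        total.backward()
        assert np.isfinite(total.data) and np.isfinite(ce) and np.isfinite(kl)
        norms = [np.linalg.norm(p.grad) for p in model.parameters()]
        assert np.all(np.isfinite(norms))


class TestLoss:
    def test_confident_correct_prediction_has_zero_ce(self, rng):
        from snpflow.np_core import Prediction
        model = SNPNF(tiny_cfg())
        logits = np.array([[50.0, 0.0, 0.0]])
        total, ce, kl = model.loss(Prediction(logits=ad.tensor(logits)),
                                   np.array([0]), None, None)
        assert ce == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_ce_is_log3(self):
        from snpflow.np_core import Prediction
        model = SNPNF(tiny_cfg())
        _, ce, _ = model.loss(Prediction(logits=ad.tensor(np.zeros((5, 3)))),
                              np.arange(5) % 3, None, None)
        assert ce == pytest.approx(np.log(3.0), abs=1e-12)

    def test_identical_posteriors_give_zero_kl(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, y, Xt = random_batch(rng)
        r = np.random.default_rng(0)
        pred, q_ctx, _ = model.forward(X, Y, mode="eval", rng=r)
        total, ce, kl = model.loss(pred, y, q_ctx, q_ctx, rng=r)
        assert kl == 0.0
        assert float(total.data) == pytest.approx(ce)

    def test_out_of_range_label_rejected(self, rng):
        model = SNPNF(tiny_cfg())
        X, Y, _, _ = random_batch(rng)
        pred, _, _ = model.forward(X, Y, mode="eval")
        with pytest.raises(ValueError, match="out of range"):
            model.loss(pred, np.array([3] * X.shape[0]), None, None)


class TestVariants:
    @pytest.mark.parametrize("name", VARIANTS)
    def test_all_variants_construct_and_run_forward(self, name, rng):
        model = build_variant(name, tiny_cfg())
        X, Y, y, Xt = random_batch(rng)
        r = np.random.default_rng(0)
        if model.use_latent:
            pred, q_ctx, q_full = model.forward(X, Y, mode="train", Xt=Xt, yt=y, rng=r)
        else:
            pred, q_ctx, q_full = model.forward(X, Y, mode="eval", rng=r)
        total, ce, kl = model.loss(pred, y, q_full, q_ctx, rng=r)
        assert np.isfinite(float(total.data))

    def test_snp_has_no_flow_steps(self):
        assert build_variant("snp", tiny_cfg(n_flow_steps=4)).n_flow_steps == 0

    def test_deterministic_only_emits_zero_kl(self, rng):
        model = build_variant("tnp_deterministic_only", tiny_cfg())
        X, Y, y, _ = random_batch(rng)
        pred, q_ctx, q_full = model.forward(X, Y, mode="eval")
        _, _, kl = model.loss(pred, y, q_full, q_ctx)
        assert kl == 0.0

    def test_flow_free_models_share_initialization(self):
        """snp and snp_nf-at-depth-0 draw identical parameters under one seed."""
        a = build_variant("snp", tiny_cfg())
        b = build_variant("snp_nf", tiny_cfg(n_flow_steps=0))
        assert set(a.params) == set(b.params)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)


class TestTraining:
    def test_loss_decreases_on_small_cohort(self, small_dataset):
        ds, _ = small_dataset
        cfg = tiny_cfg(epochs=3, seed=1)
        hist = fit(SNPNF(cfg), ds.subset(ds.train_ids))
        assert hist.total[-1] < hist.total[0]

    def test_fit_is_deterministic_given_seed(self, small_dataset):
        ds, _ = small_dataset
        train = ds.subset(ds.train_ids)[:40]
        cfg = tiny_cfg(epochs=2, seed=5)
        h1 = fit(SNPNF(cfg), train)
        h2 = fit(SNPNF(cfg), train)
        assert h1.total == h2.total

    def test_empty_training_set_names_exclusion_rule(self):
        with pytest.raises(ValueError, match="fewer than 5 visits"):
            fit(SNPNF(tiny_cfg()), [])

    def test_predict_proba_shape_and_simplex(self, small_dataset):
        ds, _ = small_dataset
        model = SNPNF(tiny_cfg())
        probs = predict_proba(model, ds.subset(ds.test_ids), n_latent_samples=2)
        assert probs.shape == (len(ds.subset(ds.test_ids)), 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestCheckpoint:
    def test_roundtrip_preserves_parameters_and_config(self, tmp_path, rng):
        model = SNPNF(tiny_cfg(n_flow_steps=3))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, extra={"note": "unit"})
        back, extra = load_checkpoint(path)
        assert extra["note"] == "unit"
        assert back.cfg == model.cfg
        for k in model.params:
            assert np.array_equal(back.params[k].data, model.params[k].data)
        X, Y, _, _ = random_batch(rng)
        r1, r2 = np.random.default_rng(0), np.random.default_rng(0)
        p1, _, _ = model.forward(X, Y, mode="eval", rng=r1)
        p2, _, _ = back.forward(X, Y, mode="eval", rng=r2)
        assert np.array_equal(p1.logits.data, p2.logits.data)
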