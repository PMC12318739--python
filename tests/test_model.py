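"""Network components against brute-force oracles, plus ablation contracts."""

import numpy as np
import pytest

from dcai.autodiff import Tensor, no_grad
from dcai.model import (CrossAttention, DCAIModel, ModelConfig, PoolNorm,
                        StructuredEmbedder, VolumeEmbedder, load_checkpoint,
                        save_checkpoint)
from oracles import (oracle_cross_attention, oracle_fuse_and_classify,
                     oracle_pool_and_normalize, oracle_structured_embedding)

TINY = dict(n_transformer_blocks=2, model_dim=16, n_heads=4, ffn_dim=32,
            dropout=0.0, struct_hidden=8)


def tiny_cfg(**over):
    return ModelConfig(**{**TINY, **over})


class TestStructuredEmbedder:
    def test_zero_input_zero_bias_gives_zeros(self, rng):
        emb = StructuredEmbedder(tiny_cfg(), rng)
        emb.lin1.bias.data[:] = 0
        emb.lin2.bias.data[:] = 0
        out = emb(Tensor(np.zeros((1, 9, 4))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_output_nonnegative(self, rng):
        emb = StructuredEmbedder(tiny_cfg(), rng)
        out = emb(Tensor(rng.standard_normal((3, 9, 4))))
        assert out.data.min() >= 0.0

    def test_matches_explicit_loop_oracle(self, rng):
        emb = StructuredEmbedder(tiny_cfg(), rng)
        s = rng.standard_normal((9, 4))
        out = emb(Tensor(s[None]))
        expected = oracle_structured_embedding(
            s.tolist(), emb.lin1.weight.data.tolist(),
            emb.lin1.bias.data.tolist(), emb.lin2.weight.data.tolist(),
            emb.lin2.bias.data.tolist())
        np.testing.assert_allclose(out.data[0], expected, atol=1e-10)

    def test_wrong_shape_errors(self, rng):
        with pytest.raises(ValueError, match="9, 4"):
            StructuredEmbedder(tiny_cfg(), rng)(Tensor(np.zeros((1, 8, 4))))


class TestVolumeEmbedder:
    def test_zero_cube_zero_bias_gives_zero_tokens(self, rng):
        emb = VolumeEmbedder(tiny_cfg(), rng)
        emb.proj.bias.data[:] = 0
        out = emb(Tensor(np.zeros((1, 32, 32, 32))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_token_is_shared_kernel_dot_slice(self, rng):
        """Each token equals bias + <slice, kernel weights> for each channel."""
        emb = VolumeEmbedder(tiny_cfg(), rng)
        cube = rng.random((32, 32, 32))
        out = emb(Tensor(cube[None])).data[0]
        for z in (0, 17, 31):
            expected = cube[z].reshape(-1) @ emb.proj.weight.data \
                + emb.proj.bias.data
            np.testing.assert_allclose(out[z], expected, atol=1e-10)

    def test_permuting_slices_permutes_tokens(self, rng):
        emb = VolumeEmbedder(tiny_cfg(), rng)
        cube = rng.random((32, 32, 32))
        perm = rng.permutation(32)
        out = emb(Tensor(cube[None])).data[0]
        out_perm = emb(Tensor(cube[perm][None])).data[0]
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-12)

    def test_wrong_shape_errors(self, rng):
        with pytest.raises(ValueError, match="cube"):
            VolumeEmbedder(tiny_cfg(), rng)(Tensor(np.zeros((1, 16, 32, 32))))


class TestCrossAttention:
    def test_single_key_returns_its_value_projection(self, rng):
        ca = CrossAttention(16, rng)
        q = rng.standard_normal((1, 5, 16))
        kv = rng.standard_normal((1, 1, 16))
        out = ca(Tensor(q), Tensor(kv)).data
        expected = kv[0, 0] @ ca.wv.data
        for row in out[0]:
            np.testing.assert_allclose(row, expected, atol=1e-10)

    def test_matches_explicit_loop_oracle(self, rng):
        ca = CrossAttention(16, rng)
        q = rng.standard_normal((3, 16))
        kv = rng.standard_normal((2, 16))
        out = ca(Tensor(q[None]), Tensor(kv[None])).data[0]
        expected = oracle_cross_attention(
            q.tolist(), kv.tolist(), ca.wq.data.tolist(),
            ca.wk.data.tolist(), ca.wv.data.tolist())
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        ca = CrossAttention(16, rng)
        att = ca.attention_weights(Tensor(rng.standard_normal((2, 7, 16))),
                                   Tensor(rng.standard_normal((2, 5, 16))))
        np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)

    def test_mismatched_feature_dim_errors(self, rng):
        ca = CrossAttention(16, rng)
        with pytest.raises(ValueError, match="feature dims"):
            ca(Tensor(np.zeros((1, 3, 16))), Tensor(np.zeros((1, 2, 8))))


class TestPoolNorm:
    def test_single_token_is_its_normalization(self, rng):
        pool = PoolNorm(16)
        x = rng.standard_normal((1, 1, 16))
        single = pool(Tensor(x)).data
        repeated = pool(Tensor(np.repeat(x, 5, axis=1))).data
        np.testing.assert_allclose(single, repeated, atol=1e-12)

    def test_matches_explicit_loop_oracle(self, rng):
        pool = PoolNorm(16)
        pool.norm.gamma.data = rng.standard_normal(16)
        pool.norm.beta.data = rng.standard_normal(16)
        x = rng.standard_normal((4, 16))
        out = pool(Tensor(x[None])).data[0]
        expected = oracle_pool_and_normalize(
            x.tolist(), pool.norm.gamma.data.tolist(),
            pool.norm.beta.data.tolist())
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            PoolNorm(16)(Tensor(np.zeros((1, 0, 16))))


class TestFuseAndClassify:
    def test_symmetric_zero_case(self, rng):
        """Zero fused vector and zero weights give even odds and ln 2 loss."""
        model = DCAIModel(tiny_cfg())
        model.classifier.weight.data[:] = 0
        model.classifier.bias.data[:] = 0
        from dcai.autodiff import cross_entropy_with_logits, softmax
        logits = model.classifier(Tensor(np.zeros((1, 32))))
        np.testing.assert_array_equal(logits.data, [[0.0, 0.0]])
        probs = softmax(logits).data
        np.testing.assert_allclose(probs, [[0.5, 0.5]])
        loss = cross_entropy_with_logits(logits, np.array([1]))
        np.testing.assert_allclose(float(loss.data), np.log(2), atol=1e-12)

    def test_matches_scalar_oracle(self, rng):
        model = DCAIModel(tiny_cfg())
        s_final = rng.standard_normal(16)
        c_final = rng.standard_normal(16)
        from dcai.autodiff import concat, cross_entropy_with_logits, softmax
        v = concat([Tensor(s_final[None]), Tensor(c_final[None])], axis=-1)
        logits = model.classifier(v)
        probs = softmax(logits).data[0]
        loss = float(cross_entropy_with_logits(logits, np.array([1])).data)
        exp_logits, exp_probs, exp_loss = oracle_fuse_and_classify(
            s_final.tolist(), c_final.tolist(),
            model.classifier.weight.data.tolist(),
            model.classifier.bias.data.tolist(), true_label=1)
        np.testing.assert_allclose(logits.data[0], exp_logits, atol=1e-9)
        np.testing.assert_allclose(probs, exp_probs, atol=1e-9)
        assert abs(loss - exp_loss) < 1e-9

    def test_concatenation_order_matters(self, rng):
        from dcai.autodiff import concat
        a, b = rng.standard_normal((1, 16)), rng.standard_normal((1, 16))
        v1 = concat([Tensor(a), Tensor(b)], axis=-1).data
        v2 = concat([Tensor(b), Tensor(a)], axis=-1).data
        assert not np.allclose(v1, v2)


class TestForward:
    def test_full_output_shapes(self, rng):
        model = DCAIModel(tiny_cfg())
        logits = model(rng.random((3, 9, 4)), rng.random((3, 32, 32, 32)))
        assert logits.shape == (3, 2)
        assert np.all(np.isfinite(logits.data))

    @pytest.mark.parametrize("ablation", ["structured_only", "image_only",
                                          "no_transformer",
                                          "no_cross_attention"])
    def test_ablations_produce_valid_predictions(self, ablation, rng):
        model = DCAIModel(tiny_cfg(ablation=ablation))
        probs = model.predict_proba(rng.random((2, 9, 4)),
                                    rng.random((2, 32, 32, 32)))
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_no_transformer_encoder_is_identity(self, rng):
        model = DCAIModel(tiny_cfg(ablation="no_transformer", positional=False))
        s = Tensor(rng.random((2, 9, 4)))
        np.testing.assert_array_equal(model._encode_structured(s).data,
                                      model.struct_embed(s).data)
        c = Tensor(rng.random((2, 32, 32, 32)))
        np.testing.assert_array_equal(model._encode_image(c).data,
                                      model.volume_embed(c).data)

    def test_cross_attention_ablation_changes_output(self, rng):
        s, c = rng.random((2, 9, 4)), rng.random((2, 32, 32, 32))
        full = DCAIModel(tiny_cfg(seed=3)).predict_proba(s, c)
        noca = DCAIModel(tiny_cfg(seed=3,
                                  ablation="no_cross_attention")).predict_proba(s, c)
        assert not np.allclose(full, noca)

    def test_batch_matches_single_sample_calls(self, rng):
        model = DCAIModel(tiny_cfg())
        s, c = rng.random((4, 9, 4)), rng.random((4, 32, 32, 32))
        batch = model.predict_proba(s, c)
        singles = np.vstack([model.predict_proba(s[i:i + 1], c[i:i + 1])
                             for i in range(4)])
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_seeded_construction_is_reproducible(self, rng):
        s, c = rng.random((2, 9, 4)), rng.random((2, 32, 32, 32))
        p1 = DCAIModel(tiny_cfg(seed=9)).predict_proba(s, c)
        p2 = DCAIModel(tiny_cfg(seed=9)).predict_proba(s, c)
        np.testing.assert_array_equal(p1, p2)

    def test_nonfinite_encoder_input_errors(self, rng):
        model = DCAIModel(tiny_cfg())
        s = rng.random((1, 9, 4))
        s[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            model(s, rng.random((1, 32, 32, 32)))


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        model = DCAIModel(tiny_cfg(seed=5))
        s, c = rng.random((2, 9, 4)), rng.random((2, 32, 32, 32))
        before = model.predict_proba(s, c)
        save_checkpoint(model, tmp_path / "model.npz")
        restored = load_checkpoint(tmp_path / "model.npz")
        np.testing.assert_array_equal(restored.predict_proba(s, c), before)

    def test_mismatched_config_errors(self, tmp_path):
        model = DCAIModel(tiny_cfg(seed=5))
        save_checkpoint(model, tmp_path / "model.npz")
        with pytest.raises(ValueError, match="config"):
            load_checkpoint(tmp_path / "model.npz",
                            expected_config=tiny_cfg(seed=6))


def test_finite_difference_gradients_through_full_model(rng):
    """Autodiff loss gradients agree with central differences on a tiny model."""
    cfg = ModelConfig(n_transformer_blocks=1, model_dim=8, n_heads=2,
                      ffn_dim=16, dropout=0.0, struct_hidden=4, seed=2)
    model = DCAIModel(cfg)
    s = rng.random((2, 9, 4))
    c = rng.random((2, 32, 32, 32))
    labels = np.array([0, 1])
    loss = model.loss(s, c, labels)
    loss.backward()
    param_rng = np.random.default_rng(0)
    for name, p in model.named_parameters():
        flat_idx = param_rng.integers(0, p.data.size, size=min(3, p.data.size))
        for fi in flat_idx:
            idx = np.unravel_index(fi, p.data.shape)
            orig = p.data[idx]
            h = 1e-6
            p.data[idx] = orig + h
            with no_grad():
                fp = float(model.loss(s, c, labels).data)
            p.data[idx] = orig - h
            with no_grad():
                fm = float(model.loss(s, c, labels).data)
            p.data[idx] = orig
            num = (fp - fm) / (2 * h)
            ana = p.grad[idx]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), \
                f"{name}[{idx}]: autodiff {ana} vs numeric {num}"
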