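"""Architecture contracts: tokenization, fusion, assembly, encoding,
classification head, forward modes and checkpointing.

All tests run the scaled-down configuration (64-d, 2 layers, 2 heads) —
the identical code path as the full-size model.
"""

import numpy as np
import pytest

from campnet.model import (CaMPNet, CrossAttentionFusion, ModelConfig,
                           load_checkpoint, predict_proba, save_checkpoint)
from campnet.nn.tensor import Tensor, bce_with_logits, no_grad
from campnet.preprocessing import TrainStats


@pytest.fixture(scope="module")
def tiny_model():
    m = CaMPNet(ModelConfig.tiny(), seed=0)
    m.eval()
    return m


def _record(rng, n=1):
    wf = rng.normal(size=(n, 12, 5000)).astype(np.float32)
    f = rng.normal(size=(n, 9)).astype(np.float32)
    msk = np.ones((n, 9), np.float32)
    age = rng.normal(size=n).astype(np.float32)
    sex = rng.integers(0, 2, n)
    return wf, f, msk, age, sex


class TestPatchTokens:
    def test_5000_samples_give_100_tokens(self, tiny_model, rng):
        wf = rng.normal(size=(2, 12, 5000)).astype(np.float32)
        tokens = tiny_model.embed_patches(wf)
        assert tokens.shape == (2, 100, 64)

    def test_identical_windows_give_identical_tokens(self, tiny_model, rng):
        a = rng.normal(size=(1, 12, 5000)).astype(np.float32)
        b = rng.normal(size=(1, 12, 5000)).astype(np.float32)
        b[0, :, 250:300] = a[0, :, 250:300]  # patch 5 shared
        ta = tiny_model.embed_patches(a).data
        tb = tiny_model.embed_patches(b).data
        np.testing.assert_array_equal(ta[0, 5], tb[0, 5])
        assert not np.allclose(ta[0, 6], tb[0, 6])

    def test_circular_shift_by_patch_len_permutes_tokens(self, tiny_model,
                                                         rng):
        wf = rng.normal(size=(1, 12, 5000)).astype(np.float32)
        shifted = np.roll(wf, 50, axis=2)
        t0 = tiny_model.embed_patches(wf).data
        t1 = tiny_model.embed_patches(shifted).data
        np.testing.assert_allclose(t1[0, 1:], t0[0, :-1], atol=1e-6)

    def test_incompatible_length_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="length"):
            tiny_model.embed_patches(np.zeros((1, 12, 4999), np.float32))


class TestFeatureToken:
    def test_all_zero_values_and_mask_is_valid_ablation_input(self,
                                                              tiny_model):
        tok = tiny_model.embed_feature_token(np.zeros((1, 9)),
                                             np.zeros((1, 9)))
        assert tok.shape == (1, 1, 64)
        assert np.all(np.isfinite(tok.data))

    def test_deterministic_at_inference(self, tiny_model, rng):
        f = rng.normal(size=(1, 9))
        m = np.ones((1, 9))
        a = tiny_model.embed_feature_token(f, m).data
        b = tiny_model.embed_feature_token(f, m).data
        np.testing.assert_array_equal(a, b)

    def test_wrong_arity_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.embed_feature_token(np.zeros((1, 8)), np.zeros((1, 8)))


class TestMetadataTokens:
    def test_default_config_yields_two_tokens(self, tiny_model):
        toks = tiny_model.embed_metadata(np.zeros(1), np.zeros(1))
        assert len(toks) == 2
        assert all(t.shape == (1, 1, 64) for t in toks)

    def test_equal_age_sex_give_identical_tokens(self, tiny_model):
        t1 = tiny_model.embed_metadata(np.array([0.3]), np.array([1]))
        t2 = tiny_model.embed_metadata(np.array([0.3]), np.array([1]))
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.data, b.data)

    def test_invalid_sex_code_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="sex"):
            tiny_model.embed_metadata(np.zeros(1), np.array([2]))


class TestCrossAttention:
    def test_identical_patches_give_uniform_attention(self):
        rng = np.random.default_rng(0)
        fusion = CrossAttentionFusion(16, rng)
        xs = Tensor(rng.normal(size=(1, 1, 16)).astype(np.float32))
        one = rng.normal(size=16).astype(np.float32)
        xp = Tensor(np.tile(one, (1, 7, 1)))
        fused, attn = fusion(xs, xp)
        np.testing.assert_allclose(attn.data, 1.0 / 7, atol=1e-6)
        # Z equals the shared value row
        v = xp @ fusion.w_v.weight
        np.testing.assert_allclose((attn @ v).data[0, 0], v.data[0, 0],
                                   atol=1e-5)

    def test_hand_computed_two_patch_softmax(self):
        """Scaled logits [0, ln 3] must give weights [0.25, 0.75]."""
        scores = Tensor(np.array([[[0.0, np.log(3.0)]]], np.float32))
        attn = scores.softmax(axis=-1)
        np.testing.assert_allclose(attn.data[0, 0], [0.25, 0.75], atol=1e-6)

    def test_rows_sum_to_one_on_random_inputs(self):
        rng = np.random.default_rng(1)
        fusion = CrossAttentionFusion(8, rng)
        for _ in range(100):
            xs = Tensor(rng.normal(size=(2, 1, 8)).astype(np.float32))
            xp = Tensor(rng.normal(size=(2, 5, 8)).astype(np.float32))
            _, attn = fusion(xs, xp)
            np.testing.assert_allclose(attn.data.sum(-1), 1.0, atol=1e-6)
            assert np.all(attn.data >= 0) and np.all(attn.data <= 1)


class TestSequenceAndEncoder:
    def test_default_sequence_length_104(self, tiny_model, rng):
        wf, f, msk, age, sex = _record(rng)
        patches = tiny_model.embed_patches(wf)
        feat = tiny_model.embed_feature_token(f, msk)
        fused, _ = tiny_model.fusion(feat, patches)
        meta = tiny_model.embed_metadata(age, sex)
        seq = tiny_model.assemble_sequence(fused, patches, meta)
        assert seq.shape == (1, 104, 64)

    def test_ablation_sequence_length_102(self, tiny_model, rng):
        wf, f, msk, age, sex = _record(rng)
        patches = tiny_model.embed_patches(wf)
        feat = tiny_model.embed_feature_token(f, msk)
        fused, _ = tiny_model.fusion(feat, patches)
        seq = tiny_model.assemble_sequence(fused, patches, [])
        assert seq.shape == (1, 102, 64)

    def test_cls_occupies_position_zero(self, tiny_model, rng):
        wf, f, msk, age, sex = _record(rng)
        patches = tiny_model.embed_patches(wf)
        feat = tiny_model.embed_feature_token(f, msk)
        fused, _ = tiny_model.fusion(feat, patches)
        seq = tiny_model.assemble_sequence(fused, patches, [])
        expected = tiny_model.cls_token.data[0, 0] \
            + tiny_model.pos_embed.data[0, 0]
        np.testing.assert_allclose(seq.data[0, 0], expected, atol=1e-6)

    def test_encoder_preserves_shape(self, tiny_model, rng):
        x = Tensor(rng.normal(size=(2, 10, 64)).astype(np.float32))
        out = tiny_model.encode(x)
        assert out.shape == (2, 10, 64)

    def test_zero_depth_encoder_is_identity(self, rng):
        m = CaMPNet(ModelConfig.tiny(n_layers=0), seed=0)
        m.eval()
        x = Tensor(rng.normal(size=(1, 5, 64)).astype(np.float32))
        np.testing.assert_array_equal(m.encode(x).data, x.data)

    def test_joint_patch_and_position_permutation_fixes_cls_output(self, rng):
        """Permuting patches together with their positional embeddings is a
        relabeling the encoder cannot distinguish: the CLS state is
        unchanged."""
        m = CaMPNet(ModelConfig.tiny(), seed=3)
        m.eval()
        wf, f, msk, age, sex = _record(rng)
        with no_grad():
            patches = m.embed_patches(wf)
            feat = m.embed_feature_token(f, msk)
            fused, _ = m.fusion(feat, patches)
            meta = m.embed_metadata(age, sex)
            seq = m.assemble_sequence(fused, patches, meta).data.copy()
            base_cls = m.classify(m.encode(Tensor(seq))).data
            # swap the already-position-encoded patch tokens 10 and 40
            swapped = seq.copy()
            swapped[:, [12, 42]] = swapped[:, [42, 12]]
            swapped_cls = m.classify(m.encode(Tensor(swapped))).data
        np.testing.assert_allclose(swapped_cls, base_cls, atol=1e-4)


class TestForward:
    def test_modes_and_shapes(self, tiny_model, rng):
        wf, f, msk, age, sex = _record(rng, 2)
        with no_grad():
            logits, attn = tiny_model.forward(wf, f, msk, age, sex)
        assert logits.shape == (2, 13) and attn.shape == (2, 100)
        np.testing.assert_allclose(attn.sum(-1), 1.0, atol=1e-6)

    def test_feature_masked_touches_only_the_feature_path(self, tiny_model,
                                                          rng):
        wf, f, msk, age, sex = _record(rng)
        # patch tokens are computed from the waveform alone, so they are
        # bit-identical between modes; logits differ through fusion only
        t_full = tiny_model.embed_patches(wf).data
        t_masked = tiny_model.embed_patches(wf).data
        np.testing.assert_array_equal(t_full, t_masked)
        with no_grad():
            l_full, _ = tiny_model.forward(wf, f, msk, age, sex, "full")
            l_masked, _ = tiny_model.forward(wf, f, msk, age, sex,
                                             "feature_masked")
            l_zero, _ = tiny_model.forward(wf, np.zeros_like(f),
                                           np.zeros_like(msk), age, sex,
                                           "full")
        # masked mode equals explicitly zeroed features
        np.testing.assert_array_equal(l_masked.data, l_zero.data)
        assert not np.allclose(l_masked.data, l_full.data)

    def test_without_age_sex_shortens_the_sequence(self, tiny_model, rng):
        wf, f, msk, age, sex = _record(rng)
        with no_grad():
            logits, attn = tiny_model.forward(wf, f, msk, age, sex,
                                              "without_age_sex")
        assert logits.shape == (1, 13)

    def test_inference_is_deterministic(self, tiny_model, rng):
        wf, f, msk, age, sex = _record(rng)
        with no_grad():
            a, _ = tiny_model.forward(wf, f, msk, age, sex)
            b, _ = tiny_model.forward(wf, f, msk, age, sex)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unknown_mode_rejected(self, tiny_model, rng):
        wf, f, msk, age, sex = _record(rng)
        with pytest.raises(ValueError, match="mode"):
            tiny_model.forward(wf, f, msk, age, sex, "bogus")

    def test_gradients_reach_every_branch(self, rng):
        m = CaMPNet(ModelConfig.tiny(), seed=1)
        m.train()
        wf, f, msk, age, sex = _record(rng, 2)
        logits, _ = m.forward(wf, f, msk, age, sex)
        loss = bce_with_logits(logits, np.ones((2, 13), np.float32))
        loss.backward()
        reached = {name for name, p in m.named_parameters()
                   if p.grad is not None and np.any(p.grad != 0)}
        for branch in ("fusion.w_q.weight", "fusion.w_k.weight",
                       "fusion.w_v.weight", "patch_proj.weight",
                       "feature_embed.fc1.weight", "age_embed.fc1.weight",
                       "sex_embed.fc1.weight", "pos_embed", "cls_token",
                       "head.weight"):
            assert branch in reached, f"no gradient reached {branch}"


class TestHeadAndProbabilities:
    def test_zero_cls_state_gives_bias_logits(self, rng):
        m = CaMPNet(ModelConfig.tiny(), seed=0)
        m.head.bias.data = np.arange(13, dtype=np.float32)
        out = m.classify(Tensor(np.zeros((1, 3, 64), np.float32)))
        np.testing.assert_allclose(out.data[0], np.arange(13), atol=1e-6)

    def test_known_cls_state_matrix_product(self, rng):
        m = CaMPNet(ModelConfig.tiny(), seed=0)
        state = rng.normal(size=(1, 1, 64)).astype(np.float32)
        expected = state[0, 0] @ m.head.weight.data + m.head.bias.data
        np.testing.assert_allclose(m.classify(Tensor(state)).data[0],
                                   expected, rtol=1e-5)

    def test_sigmoid_fixed_points_and_monotonicity(self):
        assert predict_proba(np.array([0.0]))[0] == pytest.approx(0.5)
        assert predict_proba(np.array([np.log(3.0)]))[0] == \
            pytest.approx(0.75, abs=1e-6)
        z = np.linspace(-5, 5, 50)
        p = predict_proba(z)
        assert np.all(np.diff(p) > 0) and np.all((p > 0) & (p < 1))


class TestCheckpoint:
    def test_round_trip_restores_weights_config_and_stats(self, tmp_path,
                                                          rng):
        m = CaMPNet(ModelConfig.tiny(), seed=5)
        m.eval()
        stats = TrainStats(np.arange(9.0), np.ones(9), 64.8, 17.0)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, m, stats, extra={"note": "test"})
        m2, stats2, meta = load_checkpoint(path)
        assert meta["version"] == 1
        assert meta["extra"]["note"] == "test"
        np.testing.assert_array_equal(stats2.feature_mean, stats.feature_mean)
        wf, f, msk, age, sex = _record(rng)
        with no_grad():
            a, _ = m.forward(wf, f, msk, age, sex)
            b, _ = m2.forward(wf, f, msk, age, sex)
        np.testing.assert_array_equal(a.data, b.data)
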