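"""The attention trunk: head projections, cross-channel attention, pooling."""

import numpy as np
import pytest

from sensornet._autodiff import Tensor
from sensornet.adaptive_convolution import (AttentionIteration,
                                            HeadExpansionFirst, HeadMix,
                                            HeadTensor, IterationConfig,
                                            QKVProjection, StandardHeadMix,
                                            _attention_block, adaptive_pool,
                                            attend, attention_weights,
                                            expand_heads_first, mix_heads,
                                            project_qkv, run_iteration,
                                            standard_multihead)
from sensornet.patching import extract_patches


from tests_oracles import naive_attention


# ---------------------------------------------------------------------------
# dense layer (head generation)
# ---------------------------------------------------------------------------

class TestHeadExpansion:
    def test_identity_initialization_reproduces_input(self, rng):
        mod = HeadExpansionFirst(1, rng)
        mod.w1.data = np.ones(1)
        mod.b1.data = np.zeros(1)
        mod.w2.data = np.eye(1)
        mod.b2.data = np.zeros(1)
        x = HeadTensor(rng.random((3, 1, 6, 6)))
        out = expand_heads_first(x, 1, module=mod)
        np.testing.assert_allclose(out.values, x.values, rtol=1e-12)

    def test_expands_single_head_to_64(self, rng):
        x = HeadTensor(rng.random((4, 1, 48, 48)).astype(np.float32))
        out = expand_heads_first(x, 64, rng=rng)
        assert out.values.shape == (4, 64, 48, 48)

    def test_parameter_count_by_weight_enumeration(self, rng):
        mod = HeadExpansionFirst(64, rng)
        # layer 1: 64 scalar filters + biases; layer 2: 64 groups of 1x1x64
        assert mod.n_parameters() == (1 * 64 + 64) + (64 * 64 + 64)

    def test_rejects_multi_head_input(self, rng):
        x = HeadTensor(rng.random((2, 3, 4, 4)))
        with pytest.raises(ValueError, match="M=1"):
            expand_heads_first(x, 8, rng=rng)


class TestHeadMix:
    def test_uniform_weights_average_heads(self, rng):
        m = 5
        mod = HeadMix(m, 1, rng)
        mod.weight.data = np.full((1, m), 1.0 / m)
        mod.bias.data = np.zeros(1)
        x = HeadTensor(rng.random((2, m, 4, 4)))
        out = mix_heads(x, 1, module=mod)
        np.testing.assert_allclose(out.values[:, 0], x.values.mean(axis=1),
                                   rtol=1e-12)

    def test_matches_explicit_loop(self, rng):
        mod = HeadMix(3, 4, rng)
        x = HeadTensor(rng.random((2, 3, 5, 5)))
        out = mix_heads(x, 4, module=mod)
        for o in range(4):
            expected = sum(mod.weight.data[o, m] * x.values[:, m]
                           for m in range(3)) + mod.bias.data[o]
            np.testing.assert_allclose(out.values[:, o], expected, rtol=1e-5)

    def test_table_schedule_64_to_128_shape(self, rng):
        x = HeadTensor(rng.random((4, 64, 24, 24)).astype(np.float32))
        out = mix_heads(x, 128, rng=rng)
        assert out.values.shape == (4, 128, 24, 24)

    def test_rejects_nonpositive_heads(self, rng):
        with pytest.raises(ValueError):
            HeadMix(4, 0, rng)


class TestQKVProjection:
    def test_shapes_equal_across_projections(self, rng):
        x = HeadTensor(rng.random((3, 1, 8, 8)))
        q, k, v = project_qkv(x, 8, True, rng=rng)
        assert q.values.shape == k.values.shape == v.values.shape == (3, 8, 8, 8)
        assert (q.role, k.role, v.role) == ("query", "key", "value")

    def test_identical_weights_give_identical_projections(self, rng):
        mod = QKVProjection(1, 4, True, rng)
        for layer in (mod.key, mod.value):
            for (_, src), (_, dst) in zip(mod.query.named_parameters(),
                                          layer.named_parameters()):
                dst.data = src.data.copy()
        x = HeadTensor(rng.random((2, 1, 6, 6)))
        q, k, v = project_qkv(x, 4, True, module=mod)
        np.testing.assert_array_equal(q.values, k.values)
        np.testing.assert_array_equal(q.values, v.values)

    def test_parameter_count_over_default_schedule(self, rng):
        total = sum(
            QKVProjection(m_in, m_out, first, rng).n_parameters()
            for m_in, m_out, first in [(1, 64, True), (64, 128, False),
                                       (128, 256, False)]
        )
        # 3 * (4288 + 8320 + 33024), by weight enumeration
        assert total == 3 * ((64 + 64 + 64 * 64 + 64)
                             + (64 * 128 + 128)
                             + (128 * 256 + 256)) == 136896


# ---------------------------------------------------------------------------
# attention core
# ---------------------------------------------------------------------------

class TestAttentionWeights:
    def test_all_zero_patches_give_uniform_weights(self):
        z = extract_patches(np.zeros((3, 4, 4)), (2, 2), 2)
        w = attention_weights(z, z)
        np.testing.assert_allclose(w.values, 1.0 / 3.0, rtol=1e-12)

    def test_rows_normalized(self, rng):
        for _ in range(20):
            q = extract_patches(rng.standard_normal((4, 6, 6)), (2, 2), 2)
            k = extract_patches(rng.standard_normal((4, 6, 6)), (2, 2), 2)
            w = attention_weights(q, k).values
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(w > 0) and np.all(w < 1)

    def test_matches_scalar_oracle_on_small_integers(self):
        q_maps = np.array([[[1., 2.], [0., 1.]], [[2., 0.], [1., 3.]]])
        k_maps = np.array([[[0., 1.], [2., 1.]], [[1., 1.], [0., 2.]]])
        q = extract_patches(q_maps, (2, 2), 2)
        k = extract_patches(k_maps, (2, 2), 2)
        expected, _ = naive_attention(q.values, k.values, q.values)
        np.testing.assert_allclose(attention_weights(q, k).values, expected,
                                   rtol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        q = extract_patches(rng.random((2, 4, 4)), (2, 2), 2)
        k = extract_patches(rng.random((3, 4, 4)), (2, 2), 2)
        with pytest.raises(ValueError, match="differ"):
            attention_weights(q, k)


class TestAttend:
    def test_uniform_weights_give_channel_mean(self, rng):
        from sensornet.adaptive_convolution import AttentionWeights
        v = extract_patches(rng.random((3, 4, 4)), (2, 2), 2)
        w = AttentionWeights(np.full((3, 3, 4), 1.0 / 3.0))
        out = attend(w, v)
        np.testing.assert_allclose(out.values,
                                   np.broadcast_to(v.values.mean(0), v.values.shape),
                                   rtol=1e-12)

    def test_identity_weights_return_values(self, rng):
        from sensornet.adaptive_convolution import AttentionWeights
        v = extract_patches(rng.random((3, 4, 4)), (2, 2), 2)
        eye = np.repeat(np.eye(3)[:, :, None], 4, axis=2)
        out = attend(AttentionWeights(eye), v)
        np.testing.assert_allclose(out.values, v.values, rtol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        q = extract_patches(rng.standard_normal((3, 6, 6)), (2, 2), 2)
        k = extract_patches(rng.standard_normal((3, 6, 6)), (2, 2), 2)
        v = extract_patches(rng.standard_normal((3, 6, 6)), (2, 2), 2)
        w = attention_weights(q, k)
        _, expected = naive_attention(q.values, k.values, v.values)
        np.testing.assert_allclose(attend(w, v).values, expected, atol=1e-10)


class TestAdaptivePool:
    def test_divisible_case_is_block_averaging(self, rng):
        x = HeadTensor(rng.random((2, 4, 48, 48)))
        out = adaptive_pool(x, (4, 24, 24))
        expected = x.values.reshape(2, 4, 24, 2, 24, 2).mean(axis=(3, 5))
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_squeeze_is_global_mean_per_head(self, rng):
        x = HeadTensor(rng.random((3, 5, 4, 4)))
        out = adaptive_pool(x, (1, 1, 1), squeeze_channels=True)
        assert out.values.shape == (5, 1, 1, 1)
        np.testing.assert_allclose(out.values[:, 0, 0, 0],
                                   x.values.mean(axis=(0, 2, 3)), rtol=1e-12)

    def test_target_exceeding_input_rejected(self, rng):
        x = HeadTensor(rng.random((2, 4, 8, 8)))
        with pytest.raises(ValueError, match="exceeds"):
            adaptive_pool(x, (4, 16, 8))


class TestRunIteration:
    def test_default_schedule_shape_chain(self, rng):
        x = HeadTensor(rng.random((4, 1, 48, 48)).astype(np.float32))
        t = run_iteration(x, IterationConfig(64, (64, 24, 24)), first=True, rng=rng)
        assert t.values.shape == (4, 64, 24, 24)
        t = run_iteration(t, IterationConfig(128, (128, 12, 12)), rng=rng)
        assert t.values.shape == (4, 128, 12, 12)
        t = run_iteration(t, IterationConfig(256, None, squeeze_channels=True),
                          rng=rng)
        assert t.values.shape == (256, 1, 1, 1)

    def test_same_module_accepts_different_channel_counts(self, rng):
        cfg = IterationConfig(4, (4, 4, 4))
        mod = AttentionIteration(1, cfg, first=True, rng=rng)
        for c in (3, 8):
            x = HeadTensor(rng.random((c, 1, 8, 8)))
            assert run_iteration(x, cfg, first=True, module=mod).values.shape \
                == (c, 4, 4, 4)

    def test_iteration_equals_composition_of_suboperations(self, rng):
        """One iteration == project -> extract -> attend -> fold -> pool."""
        from sensornet.patching import PatchTensor, fold_patches

        cfg = IterationConfig(3, (3, 4, 4), kernel=(2, 2), stride=2)
        mod = AttentionIteration(1, cfg, first=True, rng=rng)
        x = HeadTensor(rng.random((2, 1, 8, 8)))
        got = run_iteration(x, cfg, first=True, module=mod).values

        q, k, v = project_qkv(x, 3, True, module=mod.projection)
        per_head = []
        for m in range(3):
            qp = extract_patches(q.values[:, m], cfg.kernel, cfg.stride)
            kp = extract_patches(k.values[:, m], cfg.kernel, cfg.stride)
            vp = extract_patches(v.values[:, m], cfg.kernel, cfg.stride)
            folded = fold_patches(attend(attention_weights(qp, kp), vp))
            per_head.append(folded)
        stacked = HeadTensor(np.stack(per_head, axis=1))
        expected = adaptive_pool(stacked, cfg.pool_target).values
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestStandardMultihead:
    def test_single_head_identity_weights(self, rng):
        mod = StandardHeadMix((4, 4), 1, 1, rng)
        mod.weight.data = np.ones((4, 4, 1, 1))
        mod.bias.data = np.zeros((4, 4, 1))
        x = HeadTensor(rng.random((2, 1, 4, 4)))
        out = standard_multihead(x, module=mod)
        np.testing.assert_allclose(out.values, x.values, rtol=1e-12)

    @pytest.mark.parametrize("map_size,m_in,m_out", [
        ((48, 48), 1, 64), ((24, 24), 64, 128), ((12, 12), 128, 256)])
    def test_conv_mixing_is_smaller_at_every_stage(self, rng, map_size, m_in, m_out):
        conv = (HeadExpansionFirst(m_out, rng) if m_in == 1
                else HeadMix(m_in, m_out, rng))
        std = StandardHeadMix(map_size, m_in, m_out, rng)
        assert conv.n_parameters() < std.n_parameters()

    def test_head_order_matters(self, rng):
        mod = StandardHeadMix((4, 4), 3, 2, rng)
        x = rng.random((2, 3, 4, 4))
        swapped = x[:, [1, 0, 2]]
        a = standard_multihead(HeadTensor(x), module=mod).values
        b = standard_multihead(HeadTensor(swapped), module=mod).values
        assert not np.allclose(a, b)


# ---------------------------------------------------------------------------
# vectorized path vs naive oracle, batched
# ---------------------------------------------------------------------------

def test_vectorized_attention_block_matches_naive_loop(rng):
    """Full (N, C, M, H, W) attention equals the per-head scalar oracle."""
    from sensornet.patching import PatchTensor, fold_patches

    n, c, m, h, w = 2, 4, 3, 8, 8
    q = rng.standard_normal((n, c, m, h, w))
    k = rng.standard_normal((n, c, m, h, w))
    v = rng.standard_normal((n, c, m, h, w))
    out = _attention_block(Tensor(q), Tensor(k), Tensor(v), (2, 2), 2).data

    for ni in range(n):
        for mi in range(m):
            qp = extract_patches(q[ni, :, mi], (2, 2), 2)
            kp = extract_patches(k[ni, :, mi], (2, 2), 2)
            vp = extract_patches(v[ni, :, mi], (2, 2), 2)
            _, attended = naive_attention(qp.values, kp.values, vp.values)
            folded = fold_patches(PatchTensor(attended, (2, 2), 2, (h, w)))
            np.testing.assert_allclose(out[ni, :, mi], folded, atol=1e-5)
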