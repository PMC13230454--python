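"""Encoder components: tokenisation, windows, attention, merging."""

import numpy as np
import pytest

from oracles import shifted_window_allowed_pairs

from echostrain.nn import Tensor, softmax
from echostrain.profiling import count_parameters
from echostrain.swin import (ModelConfig, PatchEmbed, PatchMerging,
                             RelativePositionBias, SwinBlock,
                             VideoSwinEncoder, WindowConfig, attention,
                             effective_window, window_partition,
                             window_reverse)
from echostrain.swin import _attention_mask


def rng():
    return np.random.default_rng(0)


class TestTokenize:
    def test_full_clip_token_grid_is_32x56x56(self):
        cfg = ModelConfig(embed_dim=4, heads=(1, 1, 1))
        pe = PatchEmbed(cfg, rng())
        out = pe(Tensor(np.zeros((3, 64, 224, 224), dtype=np.float32)))
        assert out.shape == (32, 56, 56, 4)

    def test_toy_clip_token_grid(self):
        cfg = ModelConfig(embed_dim=4, heads=(1, 1, 1))
        out = PatchEmbed(cfg, rng())(Tensor(np.zeros((3, 8, 8, 8))))
        assert out.shape == (4, 2, 2, 4)

    def test_zero_clip_with_zero_bias_gives_zero_tokens(self):
        cfg = ModelConfig(embed_dim=4, heads=(1, 1, 1))
        pe = PatchEmbed(cfg, rng())  # projection and norm biases are zero
        out = pe(Tensor(np.zeros((3, 8, 8, 8))))
        assert np.allclose(out.data, 0.0)

    def test_indivisible_clip_rejected(self):
        cfg = ModelConfig(embed_dim=4, heads=(1, 1, 1))
        with pytest.raises(ValueError):
            PatchEmbed(cfg, rng())(Tensor(np.zeros((3, 7, 8, 8))))


class TestWindows:
    @pytest.mark.parametrize("grid,n_windows", [
        ((32, 28, 28), 64), ((32, 14, 14), 16), ((8, 7, 7), 1)])
    def test_partition_counts(self, grid, n_windows):
        x = Tensor(np.random.default_rng(1).random((*grid, 3)))
        wins = window_partition(x, (8, 7, 7))
        assert wins.shape == (n_windows, 8 * 7 * 7, 3)

    def test_partition_reverse_is_exact_inverse(self):
        x = np.random.default_rng(2).random((16, 14, 7, 5))
        wins = window_partition(Tensor(x), (8, 7, 7))
        back = window_reverse(wins, (8, 7, 7), (16, 14, 7))
        assert np.array_equal(back.data, Tensor(x).data)

    def test_effective_window_clips_to_grid_and_zeroes_shift(self):
        win, shift = effective_window((4, 2, 2), WindowConfig())
        assert win == (4, 2, 2) and shift == (0, 0, 0)
        win, shift = effective_window((32, 7, 7), WindowConfig())
        assert win == (8, 7, 7) and shift == (4, 0, 0)


class TestAttention:
    def test_single_token_returns_v_exactly(self):
        v = np.array([[3.0, -1.0]])
        out = attention(np.array([[2.0]]), np.array([[5.0]]), v)
        assert np.allclose(out.data, v)

    def test_orthogonal_query_gives_mean_of_value_rows(self):
        q = np.array([[1.0, 0.0], [1.0, 0.0]])
        k = np.array([[0.0, 1.0], [0.0, -1.0]])  # q.k = 0 for both keys
        v = np.array([[2.0, 0.0], [0.0, 4.0]])
        out = attention(q, k, v)
        assert np.allclose(out.data, [[1.0, 2.0], [1.0, 2.0]])

    def test_two_token_hand_case(self):
        q = np.array([[1.0], [0.0]])
        k = np.array([[1.0], [0.0]])
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = attention(q, k, v)
        w = np.exp([1.0, 0.0]) / np.exp([1.0, 0.0]).sum()
        assert np.allclose(out.data[0], w @ v, atol=1e-6)
        assert np.allclose(out.data[1], [0.5, 0.5], atol=1e-6)

    def test_rows_sum_to_one_and_output_in_convex_hull(self):
        r = np.random.default_rng(3)
        q, k, v = (r.normal(size=(6, 4)) for _ in range(3))
        probs = softmax(Tensor(q) @ Tensor(k).transpose(1, 0)
                        * (1 / 2.0), axis=-1)
        assert np.allclose(probs.data.sum(axis=-1), 1.0, atol=1e-6)
        out = attention(q, k, v).data
        assert np.all(out.max(axis=0) <= v.max(axis=0) + 1e-6)
        assert np.all(out.min(axis=0) >= v.min(axis=0) - 1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 4)))


class TestRelativePositionBias:
    def test_table_size_for_standard_window(self):
        b = RelativePositionBias((8, 7, 7), heads=2, rng=rng())
        assert b.table.shape == (15 * 13 * 13, 2)
        assert b.forward().shape == (2, 8 * 7 * 7, 8 * 7 * 7)

    def test_degenerate_window_bias_is_constant_and_neutral(self):
        b = RelativePositionBias((1, 1, 1), heads=1, rng=rng())
        assert b.table.shape == (1, 1)
        q = k = np.array([[1.0, 0.0], [0.0, 1.0]])
        v = np.array([[1.0, 2.0], [3.0, 4.0]])
        plain = attention(q, k, v).data
        biased = attention(q, k, v, bias=Tensor(np.full((2, 2), 5.0))).data
        assert np.allclose(plain, biased, atol=1e-6)  # constant bias cancels

    def test_index_antisymmetric_through_zero_offset(self):
        idx = RelativePositionBias._relative_index((3, 2, 2))
        centre = idx[0, 0]  # zero offset
        assert np.array_equal(idx + idx.T, np.full_like(idx, 2 * centre))


class TestShiftedBlock:
    def _block(self, dim=6, shifted=True, window=(2, 2, 2)):
        wc = WindowConfig(window=window, shift=tuple(w // 2 for w in window))
        return SwinBlock(dim, 2, wc, shifted=shifted, mlp_ratio=2.0,
                         rng=rng())

    def test_zero_shift_equals_standard_block(self):
        wc = WindowConfig(window=(2, 2, 2), shift=(1, 1, 1))
        r1, r2 = np.random.default_rng(5), np.random.default_rng(5)
        std = SwinBlock(6, 2, wc, shifted=False, mlp_ratio=2.0, rng=r1)
        shf = SwinBlock(6, 2, wc, shifted=True, mlp_ratio=2.0, rng=r2)
        shf.wc = WindowConfig(window=(2, 2, 2), shift=(1, 1, 1))
        # force the shifted block's shift to zero via effective_window on a
        # grid the window covers entirely
        x = np.random.default_rng(6).random((2, 2, 2, 6))
        assert np.allclose(std(Tensor(x)).data, shf(Tensor(x)).data,
                           atol=1e-6)

    def test_cyclic_shift_roundtrip_is_identity(self):
        x = Tensor(np.random.default_rng(7).random((4, 4, 4, 3)))
        rolled = x.roll((-2, -1, -1), axes=(0, 1, 2))
        back = rolled.roll((2, 1, 1), axes=(0, 1, 2))
        assert np.array_equal(back.data, x.data)

    def test_mask_forbids_exactly_the_wrapped_pairs(self):
        grid, window, shift = (4, 4, 4), (2, 2, 2), (1, 1, 1)
        mask = _attention_mask(grid, grid, window, shift)
        allowed_oracle = shifted_window_allowed_pairs(grid, window, shift)
        # map post-roll coordinates to (window, slot) positions
        wt, wh, ww = window
        for ti in range(4):
            for hi in range(4):
                for wi in range(4):
                    for tj in range(4):
                        for hj in range(4):
                            for wj in range(4):
                                i, j = (ti, hi, wi), (tj, hj, wj)
                                win_i = (ti // wt, hi // wh, wi // ww)
                                win_j = (tj // wt, hj // wh, wj // ww)
                                if win_i != win_j:
                                    continue
                                widx = (win_i[0] * 2 + win_i[1]) * 2 + win_i[2]
                                slot_i = ((ti % wt) * wh + hi % wh) * ww + wi % ww
                                slot_j = ((tj % wt) * wh + hj % wh) * ww + wj % ww
                                masked = mask[widx, slot_i, slot_j] < -1e8
                                assert masked == (not allowed_oracle[i, j])

    def test_block_preserves_grid_shape_with_padding(self):
        blk = self._block(window=(8, 7, 7))
        blk.wc = WindowConfig()
        x = np.random.default_rng(8).random((8, 8, 8, 6))
        out = blk(Tensor(x))
        assert out.shape == x.shape


class TestPatchMerging:
    @pytest.mark.parametrize("grid,expect", [
        ((32, 28, 28), (32, 14, 14)), ((32, 56, 56), (32, 28, 28))])
    def test_halves_space_doubles_channels(self, grid, expect):
        pm = PatchMerging(3, rng())
        out = pm(Tensor(np.random.default_rng(9).random((*grid, 3))))
        assert out.shape == (*expect, 6)

    def test_zero_tokens_stay_zero(self):
        pm = PatchMerging(3, rng())
        out = pm(Tensor(np.zeros((2, 4, 4, 3))))
        assert np.allclose(out.data, 0.0)

    def test_odd_spatial_dims_rejected(self):
        with pytest.raises(ValueError):
            PatchMerging(3, rng())(Tensor(np.zeros((2, 3, 4, 3))))


class TestEncoder:
    def test_stage_outputs_keep_temporal_length_and_halve_space(self):
        cfg = ModelConfig(embed_dim=4, depths=(2, 2, 2), heads=(1, 2, 4),
                          fusion_dim=8)
        enc = VideoSwinEncoder(cfg)
        f1, f2, f3 = enc.encode(np.random.default_rng(10)
                                .random((3, 16, 64, 64)).astype(np.float32))
        assert f1.shape == (8, 8, 8, 8)
        assert f2.shape == (8, 4, 4, 16)
        assert f3.shape == (8, 2, 2, 32)

    def test_doubling_width_roughly_quadruples_parameters(self):
        small = ModelConfig(embed_dim=8, depths=(2, 2, 2), heads=(1, 2, 4),
                            fusion_dim=16)
        large = ModelConfig(embed_dim=16, depths=(2, 2, 2), heads=(2, 4, 8),
                            fusion_dim=32)

        def linear_params(cfg):
            bias_entries = 15 * 13 * 13
            return count_parameters(cfg) - sum(
                d * bias_entries * h for d, h in zip(cfg.depths, cfg.heads))

        ratio = linear_params(large) / linear_params(small)
        assert abs(ratio - 4.0) < 0.4  # within 10%
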