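"""FP-block operations against independent scalar/loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpnets.fp_block import (FPBlockConfig, depthwise_filter, feature_product,
                             fp_block_forward, init_fp_block, instance_stats,
                             load_fp_block, num_parameters, pointwise_combine,
                             project_and_residual, save_fp_block)


class TestPointwiseCombine:
    def test_identity_single_map(self, rng):
        t0 = rng.random((5, 5, 1))
        out = pointwise_combine(t0, np.array([[1.0]]))
        np.testing.assert_allclose(out, t0)

    def test_rectifies_negative_combinations(self):
        t0 = np.zeros((1, 1, 2))
        t0[0, 0] = [2.0, -3.0]
        out = pointwise_combine(t0, np.array([[1.0, 1.0]]))
        assert out[0, 0, 0] == 0.0

    def test_matches_nested_loop_oracle(self, rng):
        t0 = rng.standard_normal((4, 4, 3))
        w = rng.standard_normal((8, 3))
        out = pointwise_combine(t0, w)
        expected = np.empty((4, 4, 8))
        for i in range(4):
            for j in range(4):
                for m in range(8):
                    acc = sum(w[m, n] * t0[i, j, n] for n in range(3))
                    expected[i, j, m] = max(acc, 0.0)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_depth_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pointwise_combine(rng.random((4, 4, 3)), rng.random((8, 2)))


class TestDepthwiseFilter:
    def test_delta_kernel_is_identity(self, rng):
        fmap = rng.standard_normal((6, 7))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        np.testing.assert_allclose(depthwise_filter(fmap, delta), fmap)

    def test_zero_kernel(self, rng):
        assert not depthwise_filter(rng.random((5, 5)), np.zeros((3, 3))).any()

    @pytest.mark.parametrize("stride", [1, 2])
    def test_matches_sliding_window_oracle(self, rng, stride):
        fmap = rng.standard_normal((8, 8))
        filt = rng.standard_normal((3, 3))
        out = depthwise_filter(fmap, filt, stride=stride)
        padded = np.pad(fmap, 1)
        expected = np.array(
            [[np.sum(padded[i:i + 3, j:j + 3] * filt)
              for j in range(0, 8, stride)] for i in range(0, 8, stride)])
        assert out.shape == expected.shape
        np.testing.assert_allclose(out, expected, rtol=1e-12)


class TestInstanceStats:
    def test_constant_map(self):
        s = instance_stats(np.full((4, 4), 3.7))
        assert s.mu == pytest.approx(3.7) and s.sigma == 0.0

    def test_direct_formula(self):
        s = instance_stats(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert s.mu == pytest.approx(2.5)
        assert s.sigma == pytest.approx(np.sqrt(1.25))

    def test_permutation_invariant(self, rng):
        fmap = rng.standard_normal((5, 5))
        shuffled = rng.permutation(fmap.ravel()).reshape(5, 5)
        a, b = instance_stats(fmap), instance_stats(shuffled)
        assert a.mu == pytest.approx(b.mu) and a.sigma == pytest.approx(b.sigma)


class TestFeatureProduct:
    def test_fully_rectified_factor_gives_zero(self, rng):
        rv = np.zeros((4, 4))  # rv - mu_v = 0 everywhere -> ReLU = 0
        rg = rng.random((4, 4))
        out = feature_product(rv, rg, instance_stats(rv), instance_stats(rg))
        assert not out.any()

    def test_equal_pair_is_nonnegative_square(self, rng):
        rv = rng.standard_normal((6, 6))
        s = instance_stats(rv)
        out = feature_product(rv, rv, s, s)
        expected = (np.maximum(rv - s.mu, 0.0) / (s.sigma + 1e-5)) ** 2
        np.testing.assert_allclose(out, expected, rtol=1e-12)
        assert (out >= 0).all()

    def test_matches_elementwise_scalar_oracle(self, rng):
        rv, rg = rng.standard_normal((6, 6)), rng.standard_normal((6, 6))
        sv, sg = instance_stats(rv), instance_stats(rg)
        out = feature_product(rv, rg, sv, sg)
        for i in range(6):
            for j in range(6):
                expected = (max(rv[i, j] - sv.mu, 0.0) * max(rg[i, j] - sg.mu, 0.0)
                            / ((sv.sigma + 1e-5) * (sg.sigma + 1e-5)))
                assert out[i, j] == pytest.approx(expected, rel=1e-12)

    def test_centering_then_scaling_commutes_with_relu(self, rng):
        # ReLU(a - mu)/sigma == ReLU((a - mu)/sigma) for sigma > 0
        a = rng.standard_normal((5, 5))
        s = instance_stats(a)
        lhs = np.maximum(a - s.mu, 0.0) / s.sigma
        rhs = np.maximum((a - s.mu) / s.sigma, 0.0)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestProjectAndResidual:
    def test_zero_projection_reduces_to_shortcut(self, rng):
        t0 = rng.random((4, 4, 3))
        t2 = rng.random((4, 4, 5))
        out = project_and_residual(t2, np.zeros((3, 5)), t0)
        np.testing.assert_allclose(out, t0)

    def test_identity_residual_adds_elementwise(self, rng):
        t0, t2 = rng.random((4, 4, 2)), rng.random((4, 4, 6))
        p = rng.standard_normal((2, 6))
        out = project_and_residual(t2, p, t0)
        np.testing.assert_allclose(out, t0 + t2 @ p.T, rtol=1e-12)

    def test_shape_mismatch_without_shortcut_raises(self, rng):
        with pytest.raises(ValueError, match="shortcut"):
            project_and_residual(rng.random((2, 2, 4)), rng.random((3, 4)),
                                 rng.random((4, 4, 3)))

    def test_strided_block_shape_contract(self):
        config = FPBlockConfig(d_in=16, d_out=32, q=1.0, stride=2)
        params = init_fp_block(config, seed=0)
        out = fp_block_forward(np.random.default_rng(0).random((32, 32, 16)),
                               params, config)
        assert out.shape == (16, 16, 32)


class TestFPBlockForward:
    def test_equals_hand_composed_pipeline(self, rng):
        config = FPBlockConfig(d_in=3, d_out=3, q=1.0, stride=1)
        params = init_fp_block(config, seed=7)
        t0 = rng.random((8, 8, 3))
        out = fp_block_forward(t0, params, config)
        t1 = pointwise_combine(t0, params.expansion)
        maps = []
        for m in range(config.n_pairs):
            rv = depthwise_filter(t1[:, :, m], params.filters_v[m])
            rg = depthwise_filter(t1[:, :, m], params.filters_g[m])
            maps.append(feature_product(rv, rg, instance_stats(rv), instance_stats(rg)))
        expected = t0 + np.stack(maps, axis=2) @ params.projection.T
        np.testing.assert_allclose(out, expected, rtol=1e-10)

    def test_zero_projection_gives_shortcut_path(self, rng):
        config = FPBlockConfig(d_in=4, d_out=4, q=1.0, stride=1)
        params = init_fp_block(config, seed=3)
        params.projection[...] = 0.0
        t0 = rng.random((6, 6, 4))
        np.testing.assert_allclose(fp_block_forward(t0, params, config), t0)

    def test_shift_equivariance_on_interior(self, rng):
        config = FPBlockConfig(d_in=2, d_out=3, q=1.0, stride=1)
        params = init_fp_block(config, seed=5)
        base = rng.random((14, 14, 2))
        # embed the same content at two offsets of a larger canvas
        big = np.zeros((20, 20, 2))
        big[3:17, 3:17] = base
        shifted = np.roll(big, 1, axis=0)
        out_a = fp_block_forward(big, params, config)
        out_b = fp_block_forward(shifted, params, config)
        # instance stats differ negligibly (content identical up to the roll),
        # so the interior responses must translate with the input
        np.testing.assert_allclose(out_a[6:14, 6:14], out_b[7:15, 6:14],
                                   rtol=1e-6, atol=1e-8)

    def test_deterministic(self, rng):
        config = FPBlockConfig(d_in=3, d_out=5, q=0.8, stride=2)
        params = init_fp_block(config, seed=0)
        t0 = rng.random((10, 10, 3))
        a = fp_block_forward(t0, params, config)
        b = fp_block_forward(t0, params, config)
        np.testing.assert_array_equal(a, b)


class TestInitAndCheckpoint:
    def test_same_seed_bit_identical(self):
        config = FPBlockConfig(4, 6, 1.0, 1)
        a, b = init_fp_block(config, 42), init_fp_block(config, 42)
        for x, y in [(a.expansion, b.expansion), (a.filters_v, b.filters_v),
                     (a.filters_g, b.filters_g), (a.projection, b.projection)]:
            np.testing.assert_array_equal(x, y)

    def test_different_seeds_differ(self):
        config = FPBlockConfig(4, 6, 1.0, 1)
        assert not np.array_equal(init_fp_block(config, 1).expansion,
                                  init_fp_block(config, 2).expansion)

    @pytest.mark.parametrize("d_in,d_out,q", [(4, 6, 1.0), (16, 32, 0.8), (8, 8, 3.0)])
    def test_shape_census(self, d_in, d_out, q):
        config = FPBlockConfig(d_in, d_out, q)
        params = init_fp_block(config, 0)
        e = int(round(q * d_out))
        assert params.expansion.shape == (e, d_in)
        assert params.filters_v.shape == params.filters_g.shape == (e, 3, 3)
        assert params.projection.shape == (d_out, e)
        counted = (params.expansion.size + params.filters_v.size
                   + params.filters_g.size + params.projection.size)
        assert counted == num_parameters(config)

    def test_checkpoint_roundtrip_exact(self, tmp_path):
        config = FPBlockConfig(3, 5, 0.8, 2)
        params = init_fp_block(config, 11)
        path = tmp_path / "block.npz"
        save_fp_block(path, params)
        loaded = load_fp_block(path)
        assert loaded.config == config
        np.testing.assert_array_equal(loaded.filters_v, params.filters_v)
        np.testing.assert_array_equal(loaded.projection, params.projection)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), d_in=st.integers(1, 4), d_out=st.integers(1, 5),
       stride=st.sampled_from([1, 2]))
def test_t2_nonnegative_and_shape_law(seed, d_in, d_out, stride):
    """T2 >= 0 everywhere and (h, w, d_in) -> (floor(h/s), floor(w/s), d_out)."""
    rng = np.random.default_rng(seed)
    config = FPBlockConfig(d_in, d_out, 1.0, stride)
    params = init_fp_block(config, seed)
    t0 = rng.standard_normal((8, 8, d_in))
    t1 = pointwise_combine(t0, params.expansion)
    rv = depthwise_filter(t1[:, :, 0], params.filters_v[0], stride)
    rg = depthwise_filter(t1[:, :, 0], params.filters_g[0], stride)
    t2 = feature_product(rv, rg, instance_stats(rv), instance_stats(rg))
    assert (t2 >= 0).all()
    out = fp_block_forward(t0, params, config)
    assert out.shape == (8 // stride, 8 // stride, d_out)
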