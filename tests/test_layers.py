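"""Encoded layers: chain construction, receptive-field extraction, batched
developmental-conv weights vs per-field loops, the weight-sharing limit
against a classical convolution, dual pooling, and the random-basis baseline."""

import numpy as np
import pytest
from scipy.signal import correlate

from neurogem.autodiff import Tensor
from neurogem.layers import (
    DevConvLayer,
    avg_pool_dual,
    dev_conv_forward,
    dev_conv_weights,
    extract_receptive_field_identities,
    im2col_indices,
    lenet5_parameter_budget,
    mlp_weights_from_rules,
    random_basis_weights,
)
from neurogem.spatial import GeneField3D


def _arr(t):
    return t.data if isinstance(t, Tensor) else np.asarray(t)


class TestMLPChain:
    def test_single_layer_reduces_to_layer_weights(self, rng):
        xi, o, xo = rng.normal(size=(6, 3)), rng.normal(size=(3, 3)), rng.normal(size=(4, 3))
        [w] = mlp_weights_from_rules([xi, xo], o)
        np.testing.assert_allclose(_arr(w), xi @ o @ xo.T, atol=1e-12)

    def test_chain_matches_per_layer_contraction(self, rng):
        xs = [rng.normal(size=(n, 3)) for n in (6, 4, 3)]
        o = rng.normal(size=(3, 3))
        ws = mlp_weights_from_rules(xs, o)
        assert len(ws) == 2
        for layer_i, w in enumerate(ws):
            expected = np.einsum("ia,ab,jb->ij", xs[layer_i], o, xs[layer_i + 1])
            np.testing.assert_allclose(_arr(w), expected, atol=1e-10)

    def test_hidden_identity_couples_exactly_two_matrices(self, rng):
        xs = [rng.normal(size=(n, 2)) for n in (5, 4, 3)]
        o = rng.normal(size=(2, 2))
        base = [_arr(w) for w in mlp_weights_from_rules(xs, o)]
        xs[1] = xs[1].copy()
        xs[1][2] += 1.0  # perturb one hidden neuron's identity
        new = [_arr(w) for w in mlp_weights_from_rules(xs, o)]
        d0 = new[0] - base[0]
        d1 = new[1] - base[1]
        assert np.all(d0[:, [0, 1, 3]] == 0) and np.any(d0[:, 2] != 0)
        assert np.all(d1[[0, 1], :] == 0) and np.any(d1[2, :] != 0)

    def test_too_short_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            mlp_weights_from_rules([rng.normal(size=(3, 2))], rng.normal(size=(2, 2)))


class TestReceptiveFields:
    def test_full_window_is_flattened_map(self, rng):
        m = rng.normal(size=(3, 3, 1, 2))
        xr = _arr(extract_receptive_field_identities(m, k=3))
        assert xr.shape == (1, 2, 9)
        np.testing.assert_allclose(xr[0], m.reshape(9, 2).T)

    def test_stride_two_tiles_match_manual_extraction(self, rng):
        m = rng.normal(size=(4, 4, 1, 3))
        xr = _arr(extract_receptive_field_identities(m, k=2, stride=2))
        assert xr.shape == (4, 3, 4)
        r = 0
        for i in (0, 2):
            for j in (0, 2):
                window = m[i : i + 2, j : j + 2, :, :].reshape(4, 3).T
                np.testing.assert_allclose(xr[r], window)
                r += 1

    def test_constant_map_gives_identical_slices(self):
        m = np.full((5, 5, 2, 3), 0.7)
        xr = _arr(extract_receptive_field_identities(m, k=3))
        assert np.allclose(xr, xr[0])

    def test_padding_adds_zero_identities(self, rng):
        m = rng.normal(size=(2, 2, 1, 1))
        xr = _arr(extract_receptive_field_identities(m, k=3, padding=1))
        assert xr.shape == (4, 1, 9)
        # top-left window: padded row+column are zero, center block is the map
        w0 = xr[0, 0].reshape(3, 3)
        assert np.all(w0[0, :] == 0) and np.all(w0[:, 0] == 0)
        np.testing.assert_allclose(w0[1:, 1:], m[:, :, 0, 0])

    def test_kernel_larger_than_input_rejected(self, rng):
        with pytest.raises(ValueError, match="kernel"):
            extract_receptive_field_identities(rng.normal(size=(2, 2, 1, 1)), k=5)


class TestDevConvWeights:
    def test_zero_interaction_zero_weights(self, rng):
        y = rng.normal(size=(3, 2, 4))
        x = rng.normal(size=(3, 4, 5))
        w = _arr(dev_conv_weights(y, np.zeros((4, 4)), x))
        np.testing.assert_array_equal(w, np.zeros((3, 2, 5)))

    def test_single_gene_rank_one_kernels(self, rng):
        y = rng.normal(size=(4, 3, 1))
        x = rng.normal(size=(4, 1, 6))
        w = _arr(dev_conv_weights(y, rng.normal(size=(1, 1)), x))
        for r in range(4):
            assert np.linalg.matrix_rank(w[r]) <= 1

    def test_batched_equals_per_receptive_field_loop(self, rng):
        for _ in range(20):
            r_count, c_out, k2c, g = (int(rng.integers(1, 6)) for _ in range(4))
            y = rng.normal(size=(r_count, c_out, g))
            o = rng.normal(size=(g, g))
            x = rng.normal(size=(r_count, g, k2c))
            w = _arr(dev_conv_weights(y, o, x))
            for r in range(r_count):
                np.testing.assert_allclose(w[r], y[r] @ o @ x[r], atol=1e-10)

    def test_gene_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="gene dimension"):
            dev_conv_weights(
                rng.normal(size=(2, 2, 3)), rng.normal(size=(4, 4)), rng.normal(size=(2, 4, 5))
            )


def _constant_field(g, rng, depth_only=True):
    """3-D field whose expression is constant over height and width."""
    fld = GeneField3D.create(g, rng)
    sig = fld.sigma.data.copy()
    sig[:, 0] = 0.0  # no height/width dependence → translation invariance
    sig[:, 1] = 0.0
    fld.sigma = Tensor(sig, requires_grad=True)
    return fld


class TestDevConvForward:
    def test_zero_input_zero_output(self, rng):
        fld = GeneField3D.create(2, rng)
        layer = DevConvLayer(k=2, c_in=1, c_out=3, output_field=fld,
                             interaction=Tensor(rng.normal(size=(2, 2))))
        out, out_map = dev_conv_forward(
            np.zeros((2, 4, 4, 1)), rng.normal(size=(4, 4, 1, 2)), layer
        )
        np.testing.assert_array_equal(_arr(out), np.zeros((2, 3, 3, 3)))
        assert out_map.shape == (3, 3, 3, 2)

    def test_weight_sharing_limit_matches_classical_convolution(self, rng):
        # spatially constant identities → every W_r identical → the layer is an
        # ordinary shared-kernel convolution with that kernel
        g = 3
        in_fld = _constant_field(g, rng)
        out_fld = _constant_field(g, rng)
        from neurogem.spatial import layer_identity_map

        in_map = layer_identity_map((5, 5, 1), in_fld)
        o = Tensor(rng.normal(size=(g, g)))
        layer = DevConvLayer(k=3, c_in=1, c_out=1, output_field=out_fld, interaction=o)
        act = rng.normal(size=(1, 5, 5, 1))
        out, _ = dev_conv_forward(act, in_map, layer)

        xr = _arr(extract_receptive_field_identities(in_map, k=3))
        assert np.allclose(xr, xr[0])  # identities are translation invariant
        from neurogem.spatial import layer_identity_map as lim

        y = _arr(lim((3, 3, 1), out_fld)).reshape(9, 1, g)
        kernel = (y[0] @ o.data @ xr[0]).reshape(3, 3)
        expected = correlate(act[0, :, :, 0], kernel, mode="valid")
        np.testing.assert_allclose(_arr(out)[0, :, :, 0], expected, atol=1e-6)

    def test_impulse_support_confined_to_covering_fields(self, rng):
        fld = GeneField3D.create(2, rng)
        layer = DevConvLayer(k=2, c_in=1, c_out=1, output_field=fld,
                             interaction=Tensor(rng.normal(size=(2, 2))))
        act = np.zeros((1, 4, 4, 1))
        act[0, 0, 0, 0] = 1.0  # corner impulse: only receptive field (0,0) sees it
        out, _ = dev_conv_forward(act, rng.normal(size=(4, 4, 1, 2)), layer)
        o = _arr(out)[0, :, :, 0]
        assert np.all(o[1:, :] == 0) and np.all(o[:, 1:] == 0)

    def test_misaligned_identity_map_rejected(self, rng):
        fld = GeneField3D.create(2, rng)
        layer = DevConvLayer(k=2, c_in=1, c_out=1, output_field=fld,
                             interaction=Tensor(rng.normal(size=(2, 2))))
        with pytest.raises(ValueError, match="align"):
            dev_conv_forward(np.zeros((1, 4, 4, 1)), rng.normal(size=(3, 3, 1, 2)), layer)


class TestAvgPoolDual:
    def test_constant_maps_unchanged(self):
        act = np.full((1, 4, 4, 2), 0.3)
        m = np.full((4, 4, 2, 3), 1.7)
        pa, pm = avg_pool_dual(act, m, window=2)
        np.testing.assert_allclose(_arr(pa), np.full((1, 2, 2, 2), 0.3))
        np.testing.assert_allclose(_arr(pm), np.full((2, 2, 2, 3), 1.7))

    def test_two_by_two_mean(self):
        act = np.array([[1.0, 3.0], [5.0, 7.0]]).reshape(1, 2, 2, 1)
        pa, _ = avg_pool_dual(act, np.zeros((2, 2, 1, 1)), window=2)
        assert _arr(pa).item() == pytest.approx(4.0)

    def test_identity_pooling_is_per_gene(self, rng):
        m = rng.normal(size=(4, 4, 1, 2))
        _, pm = avg_pool_dual(np.zeros((1, 4, 4, 1)), m, window=2)
        for gi in range(2):
            for i in range(2):
                for j in range(2):
                    manual = m[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 0, gi].mean()
                    assert _arr(pm)[i, j, 0, gi] == pytest.approx(manual)

    def test_pooling_commutes_with_gene_permutation(self, rng):
        m = rng.normal(size=(4, 4, 1, 3))
        perm = [2, 0, 1]
        _, pm = avg_pool_dual(np.zeros((1, 4, 4, 1)), m, window=2)
        _, pm_perm = avg_pool_dual(np.zeros((1, 4, 4, 1)), m[..., perm], window=2)
        np.testing.assert_allclose(_arr(pm_perm), _arr(pm)[..., perm])

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            avg_pool_dual(np.zeros((1, 5, 5, 1)), np.zeros((5, 5, 1, 1)), window=2)


class TestRandomBasis:
    def test_identity_basis_returns_coefficients(self, rng):
        p = rng.normal(size=(4, 3))
        np.testing.assert_allclose(_arr(random_basis_weights(np.eye(4), p)), p)

    def test_rank_bound_and_product_oracle(self, rng):
        r = rng.normal(size=(6, 2))
        p = rng.normal(size=(2, 4))
        w = _arr(random_basis_weights(r, p))
        np.testing.assert_allclose(w, r @ p, atol=1e-12)
        assert np.linalg.matrix_rank(w) <= 2

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="basis"):
            random_basis_weights(rng.normal(size=(6, 2)), rng.normal(size=(3, 4)))


class TestLeNetBudget:
    def test_shared_and_local_totals(self):
        shared = lenet5_parameter_budget(locally_connected=False)
        local = lenet5_parameter_budget(locally_connected=True)
        assert shared.total == 61_706
        assert local.total == 423_038
        assert round(local.total / shared.total) == 7

    def test_local_counts_enumerate_per_neuron_kernels(self):
        local = lenet5_parameter_budget(locally_connected=True)
        # conv1: 28×28 positions × 6 maps × (5·5·1 weights) + per-neuron biases
        assert local.counts["conv1.weights"] == 28 * 28 * 6 * 25
        assert local.counts["conv1.bias"] == 28 * 28 * 6
        assert local.counts["conv2.weights"] == 10 * 10 * 16 * 25 * 6
        assert local.counts["conv2.bias"] == 10 * 10 * 16


def test_im2col_order_is_row_major_height_width_channel():
    idx, (h, w), n = im2col_indices((2, 2, 2), k=2)
    assert (h, w) == (1, 1) and n == 8
    np.testing.assert_array_equal(idx[0], np.arange(8))
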