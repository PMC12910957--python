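"""Convolution primitives: dilated, gated and depthwise-separable."""

import numpy as np
import pytest
from scipy.special import expit

from hdgsnet.nn import (BatchNorm, Conv1d, Depthwise1d, Dropout, GatedConv,
                        MaxPool1d, SeparableConv1d, dilated_conv1d,
                        separable_params)


def brute_force_conv(f, kernel, dilation=1):
    """Direct summation oracle for (F *_l k)(x) = sum_y F(x+l*y) k(y)."""
    f = np.asarray(f, dtype=float)
    k = np.asarray(kernel, dtype=float)
    n = f.size - (k.size - 1) * dilation
    return np.array([sum(f[x + dilation * y] * k[y] for y in range(k.size))
                     for x in range(n)])


class TestDilatedConv:
    def test_spaced_taps_example(self):
        out = dilated_conv1d([1, 2, 3, 4], [1, 1], dilation=2)
        assert np.allclose(out, [4, 6])  # F(x) + F(x+2)

    @pytest.mark.parametrize("seed", range(10))
    def test_l1_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=rng.integers(5, 40))
        k = rng.normal(size=rng.integers(1, min(5, f.size) + 1))
        assert np.allclose(dilated_conv1d(f, k, 1), brute_force_conv(f, k, 1),
                           atol=1e-6)

    @pytest.mark.parametrize("dilation", [1, 2, 3, 5])
    def test_any_dilation_matches_brute_force(self, dilation):
        rng = np.random.default_rng(dilation)
        f = rng.normal(size=50)
        k = rng.normal(size=5)
        assert np.allclose(dilated_conv1d(f, k, dilation),
                           brute_force_conv(f, k, dilation), atol=1e-6)

    def test_centered_delta_kernel_is_identity(self):
        f = np.arange(10.0)
        for dilation in (1, 2, 4):
            out = dilated_conv1d(f, [0, 1, 0], dilation, padding="same")
            assert np.allclose(out, f)

    def test_footprint(self):
        conv = Conv1d(1, 1, kernel=7, dilation=3)
        assert conv.footprint == 19  # (7-1)*3 + 1

    def test_nonpositive_dilation_rejected(self):
        with pytest.raises(ValueError):
            dilated_conv1d([1, 2, 3], [1], dilation=0)
        with pytest.raises(ValueError):
            Conv1d(1, 1, 3, dilation=0)

    def test_layer_l1_matches_oracle(self):
        rng = np.random.default_rng(0)
        conv = Conv1d(1, 1, 5, dilation=1, bias=False, rng=rng)
        x = rng.normal(size=(1, 30, 1)).astype(np.float32)
        got = conv.forward(x)[0, 2:-2, 0]
        expected = brute_force_conv(x[0, :, 0], conv.w.v[:, 0, 0])
        assert np.allclose(got, expected, atol=1e-5)


class TestGatedConv:
    def _scalar_gate(self, w, b, v, c, x):
        """Direct substitution into Y = (X*W+b) . sigmoid(X*V+c)."""
        gate = GatedConv(1, 1, kernel=1)
        gate.w_feature[...] = w
        gate.b_feature[...] = b
        gate.w_gate[...] = v
        gate.b_gate[...] = c
        return gate.forward(np.full((1, 1, 1), x, dtype=np.float32)).item()

    def test_scalar_substitution(self):
        assert self._scalar_gate(2, 0, 0, 0, 1) == pytest.approx(2 * expit(0))
        assert self._scalar_gate(2, 0, 0, 0, 1) == pytest.approx(1.0)

    def test_all_zero_parameters_give_zero(self):
        assert self._scalar_gate(0, 0, 0, 0, 5) == 0.0

    def test_saturated_gate_passes_feature_path(self):
        # c -> +inf: sigmoid -> 1 and Y -> X*W + b
        assert self._scalar_gate(3, 1, 0, 30, 2) == pytest.approx(7.0, abs=1e-9)

    def test_gate_bounds_output_by_feature_path(self):
        rng = np.random.default_rng(1)
        gate = GatedConv(2, 4, kernel=3, rng=rng)
        x = rng.normal(size=(2, 20, 2)).astype(np.float32)
        y = gate.forward(x)
        feature = gate.fused.forward(x)[..., :4]
        assert np.all(np.abs(y) <= np.abs(feature) + 1e-7)

    def test_channel_mismatch_is_error(self):
        gate = GatedConv(2, 4, kernel=3)
        with pytest.raises(ValueError, match="channels"):
            gate.forward(np.zeros((1, 10, 3), dtype=np.float32))


class TestSeparableParams:
    def test_2d_form(self):
        p = separable_params(3, 2, 4, spatial_dims=2)
        assert (p["depthwise"], p["pointwise"]) == (18, 8)  # K^2*Cin, Cin*Cout

    def test_1d_form_beats_full(self):
        p = separable_params(3, 2, 4, spatial_dims=1)
        assert p["separable_total"] == 14 and p["full"] == 24

    def test_k1_has_no_saving(self):
        p = separable_params(1, 8, 8)
        assert p["separable_total"] == p["pointwise"] + p["depthwise"]
        assert p["full"] == p["pointwise"]

    def test_identities_on_grid(self):
        for k in range(1, 9):
            for cin in (1, 3, 16, 64):
                for cout in (1, 5, 64):
                    p1 = separable_params(k, cin, cout, 1)
                    p2 = separable_params(k, cin, cout, 2)
                    assert p1["depthwise"] == k * cin
                    assert p2["depthwise"] == k * k * cin
                    assert p1["pointwise"] == p2["pointwise"] == cin * cout
                    assert p2["full"] == k * k * cin * cout
                    if k > 1 and cout > 1:
                        assert p1["separable_total"] < p1["full"]

    def test_layer_weight_count_matches_formula(self):
        sep = SeparableConv1d(6, 10, kernel=5, bias=False)
        expected = separable_params(5, 6, 10, 1)["separable_total"]
        assert sum(p.v.size for p in sep.params()) == expected

    def test_separable_equals_composed_convs(self):
        rng = np.random.default_rng(2)
        sep = SeparableConv1d(3, 5, kernel=3, rng=rng)
        x = rng.normal(size=(2, 12, 3)).astype(np.float32)
        depthwise, pointwise = sep.layers
        manual = pointwise.forward(depthwise.forward(x))
        assert np.allclose(sep.forward(x), manual)


class TestTrainEvalModes:
    def test_eval_forward_is_deterministic(self):
        rng = np.random.default_rng(0)
        bn = BatchNorm(3)
        drop = Dropout(0.4, np.random.default_rng(1))
        x = rng.normal(size=(4, 10, 3)).astype(np.float32)
        bn.forward(x, train=True)  # populate running stats
        a = drop.forward(bn.forward(x, train=False), train=False)
        b = drop.forward(bn.forward(x, train=False), train=False)
        assert np.array_equal(a, b)

    def test_dropout_scales_in_train_mode(self):
        drop = Dropout(0.4, np.random.default_rng(0))
        x = np.ones((200, 10, 3), dtype=np.float32)
        y = drop.forward(x, train=True)
        uniq = np.unique(y)
        assert all(min(abs(u - 0.0), abs(u - 1 / 0.6)) < 1e-5 for u in uniq)
        assert abs(y.mean() - 1.0) < 0.05  # inverted scaling keeps the mean

    def test_batchnorm_train_normalizes(self):
        rng = np.random.default_rng(3)
        bn = BatchNorm(2)
        x = (rng.normal(size=(50, 20, 2)) * 3 + 7).astype(np.float32)
        y = bn.forward(x, train=True)
        assert np.allclose(y.mean(axis=(0, 1)), 0.0, atol=1e-3)
        assert np.allclose(y.std(axis=(0, 1)), 1.0, atol=1e-2)


class TestPooling:
    def test_width_trace_arithmetic(self):
        w = 146
        trace = []
        for _ in range(4):
            w = MaxPool1d.out_width(w)
            trace.append(w)
        assert trace == [48, 16, 5, 1]

    def test_max_and_gradient_routing(self):
        pool = MaxPool1d()
        x = np.array([[[1.0], [5.0], [2.0], [0.0], [7.0], [3.0]]],
                     dtype=np.float32)
        y = pool.forward(x)
        assert y.tolist() == [[[5.0], [7.0]]]
        gx = pool.backward(np.ones_like(y))
        assert gx[0, :, 0].tolist() == [0, 1, 0, 0, 1, 0]

    def test_remainder_columns_dropped(self):
        x = np.arange(8, dtype=np.float32).reshape(1, 8, 1)
        y = MaxPool1d().forward(x)
        assert y[0, :, 0].tolist() == [2.0, 5.0]  # positions 6,7 dropped
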