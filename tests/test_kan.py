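"""Spline-basis and KAN-layer correctness checks.

The independent oracle for basis values is scipy.interpolate.BSpline
(design_matrix / interpolation), never the module under test.
"""

import numpy as np
import pytest
from scipy.interpolate import BSpline, make_interp_spline

from trispectrakan._nn import Nadam, silu
from trispectrakan.kan import (KANLayer, KANNetwork, SplineSpec,
                               bspline_basis, bspline_basis_and_deriv,
                               extend_grid, kan_param_count)

RNG = np.random.default_rng(21)


class TestExtendGrid:
    def test_cubic_default_grid(self):
        knots = extend_grid(SplineSpec(3, 5, (-1.0, 1.0)))
        assert np.allclose(knots, np.arange(-2.2, 2.21, 0.4), atol=1e-12)
        assert len(knots) == 12

    def test_linear_minimal_grid(self):
        assert np.allclose(extend_grid(SplineSpec(1, 1, (0.0, 1.0))),
                           [-1.0, 0.0, 1.0, 2.0])

    @pytest.mark.parametrize("k,g", [(1, 1), (2, 3), (3, 5), (5, 8)])
    def test_knots_strictly_increasing(self, k, g):
        knots = extend_grid(SplineSpec(k, g, (-2.0, 3.0)))
        assert len(knots) == g + 2 * k + 1
        assert np.all(np.diff(knots) > 0)


class TestBasis:
    @pytest.mark.parametrize("g", range(1, 9))
    @pytest.mark.parametrize("k", range(1, 6))
    def test_partition_of_unity(self, g, k):
        spec = SplineSpec(k, g, (-1.0, 1.0))
        x = np.linspace(-1.0, 1.0, 101)
        total = bspline_basis(x, spec).sum(axis=-1)
        assert np.abs(total - 1.0).max() < 1e-12

    def test_matches_scipy_design_matrix(self):
        spec = SplineSpec(3, 5, (-1.0, 1.0))
        x = np.linspace(-0.999, 0.999, 37)
        ref = BSpline.design_matrix(x, extend_grid(spec), 3).toarray()
        assert np.allclose(bspline_basis(x, spec), ref, atol=1e-12)

    def test_cardinal_cubic_central_value(self):
        # cubic B-spline on unit-spaced knots takes value 2/3 at its center
        spec = SplineSpec(3, 4, (-2.0, 2.0))  # knots at integers
        vals = bspline_basis(np.array([0.0]), spec)[0]
        assert vals.max() == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_compact_support(self):
        spec = SplineSpec(3, 5, (-1.0, 1.0))
        assert np.allclose(bspline_basis(np.array([100.0]), spec), 0.0)
        # each basis function is nonzero on at most k+1 intervals
        x = np.linspace(-2.2, 2.2, 441)
        b = bspline_basis(x, spec)
        h = 0.4
        for m in range(b.shape[1]):
            support = x[b[:, m] > 1e-14]
            if support.size:
                assert support.max() - support.min() <= (3 + 1) * h + 1e-9

    def test_derivative_matches_scipy(self):
        spec = SplineSpec(3, 5, (-1.0, 1.0))
        knots = extend_grid(spec)
        x = np.linspace(-0.99, 0.99, 25)
        _, db = bspline_basis_and_deriv(x, spec)
        for m in range(spec.n_basis):
            c = np.zeros(spec.n_basis)
            c[m] = 1.0
            ref = BSpline(knots, c, 3).derivative()(x)
            assert np.allclose(db[:, m], ref, atol=1e-10)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            bspline_basis(np.array([np.nan]), SplineSpec())


class TestParamCount:
    def test_printed_output_layer_count(self):
        assert kan_param_count(769, 6, SplineSpec(3, 5)) == 46140

    @pytest.mark.parametrize("n_in,n_out,expected", [
        (1, 1, 10), (2, 3, 60), (768, 769, 5905920)])
    def test_closed_form(self, n_in, n_out, expected):
        assert kan_param_count(n_in, n_out, SplineSpec(3, 5)) == expected

    @pytest.mark.parametrize("n_in,n_out,k,g", [
        (1, 1, 3, 5), (4, 7, 2, 4), (3, 2, 1, 1)])
    def test_count_equals_enumerated_parameters(self, n_in, n_out, k, g):
        spec = SplineSpec(k, g)
        layer = KANLayer(n_in, n_out, spec, np.random.default_rng(0))
        assert sum(p.size for p in layer.params()) == \
            kan_param_count(n_in, n_out, spec)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            kan_param_count(0, 5, SplineSpec())


class TestKANLayer:
    def test_reduces_to_silu_map_when_splines_zeroed(self):
        spec = SplineSpec()
        layer = KANLayer(3, 3, spec, np.random.default_rng(0), dtype=np.float64)
        layer.spline_coeff.value[...] = 0.0
        layer.spline_scale.value[...] = 0.0
        layer.base_weight.value[...] = np.eye(3)
        x = RNG.uniform(-1, 1, (8, 3))
        assert np.allclose(layer.forward(x), silu(x), atol=1e-12)

    def test_spline_path_interpolates_identity(self):
        # coefficients fitted (by scipy) so the spline term equals g(x) = x
        spec = SplineSpec(3, 5, (-1.0, 1.0))
        knots = extend_grid(spec)
        xs = np.linspace(-1, 1, spec.n_basis)
        interp = make_interp_spline(xs, xs, k=3,
                                    t=knots)
        layer = KANLayer(1, 1, spec, np.random.default_rng(0), dtype=np.float64)
        layer.base_weight.value[...] = 0.0
        layer.spline_scale.value[...] = 1.0
        layer.spline_coeff.value[0, 0, :] = interp.c
        grid = np.linspace(-1, 1, 101)[:, None]
        y = layer.forward(grid)
        assert np.abs(y - grid).max() < 0.05

    def test_gradients_match_finite_differences(self):
        spec = SplineSpec(3, 5)
        layer = KANLayer(4, 3, spec, np.random.default_rng(0), dtype=np.float64)
        x = RNG.uniform(-1.3, 1.3, (6, 4))
        y = layer.forward(x, train=True)
        g = RNG.standard_normal(y.shape)
        for p in layer.params():
            p.grad.fill(0.0)
        gx = layer.backward(g)
        h = 1e-5
        scale = max(1.0, np.abs(gx).max())
        num = np.zeros_like(x)
        for idx in np.ndindex(x.shape):
            xp = x.copy(); xp[idx] += h
            xm = x.copy(); xm[idx] -= h
            num[idx] = ((layer.forward(xp) * g).sum()
                        - (layer.forward(xm) * g).sum()) / (2 * h)
        assert np.abs(num - gx).max() / scale < 1e-4
        for p in [layer.base_weight, layer.spline_coeff, layer.spline_scale]:
            numg = np.zeros_like(p.value)
            for idx in np.ndindex(p.value.shape):
                v0 = p.value[idx]
                p.value[idx] = v0 + h
                lp = (layer.forward(x) * g).sum()
                p.value[idx] = v0 - h
                lm = (layer.forward(x) * g).sum()
                p.value[idx] = v0
                numg[idx] = (lp - lm) / (2 * h)
            pscale = max(1.0, np.abs(p.grad).max())
            assert np.abs(numg - p.grad).max() / pscale < 1e-4

    def test_width_mismatch_rejected(self):
        layer = KANLayer(4, 3, SplineSpec(), np.random.default_rng(0))
        with pytest.raises(ValueError):
            layer.forward(np.zeros((2, 5)))


class TestKANNetwork:
    def test_single_layer_equals_layer_forward(self):
        net = KANNetwork([4, 3], SplineSpec(), np.random.default_rng(3),
                         dtype=np.float64)
        x = RNG.uniform(-1, 1, (5, 4))
        layer = net.layers[0]
        assert np.array_equal(net.forward(x), layer.forward(x))

    def test_superposition_theorem_shape(self):
        # the two-layer representation for n inputs uses 2n + 1 middle terms
        n = 3
        net = KANNetwork([n, 2 * n + 1, 1], SplineSpec(),
                         np.random.default_rng(0))
        assert net.shape[1] == 7
        assert net.forward(np.zeros((2, 3), dtype=np.float32)).shape == (2, 1)

    def test_bad_shape_chain_rejected(self):
        with pytest.raises(ValueError):
            KANNetwork([4], SplineSpec(), np.random.default_rng(0))

    def test_fits_sine_and_linear_model_cannot(self):
        x = np.linspace(-1, 1, 256)[:, None]
        y_tgt = np.sin(np.pi * x)
        net = KANNetwork([1, 5, 1], SplineSpec(), np.random.default_rng(0),
                         dtype=np.float64)
        opt = Nadam(net.params(), lr=0.01)
        for _ in range(2000):
            opt.zero_grad()
            r = net.forward(x, train=True) - y_tgt
            net.backward(2 * r / len(x))
            opt.step()
        rmse = np.sqrt(np.mean((net.forward(x) - y_tgt) ** 2))
        assert rmse < 0.05
        # width-matched linear least squares cannot represent the sine
        coef, *_ = np.linalg.lstsq(np.hstack([x, np.ones_like(x)]), y_tgt,
                                   rcond=None)
        lin_rmse = np.sqrt(np.mean(
            (np.hstack([x, np.ones_like(x)]) @ coef - y_tgt) ** 2))
        assert lin_rmse > 0.3

    def test_checkpoint_round_trip(self, tmp_path):
        from trispectrakan.kan import load_kan, save_kan
        net = KANNetwork([2, 4, 3], SplineSpec(2, 4), np.random.default_rng(9))
        x = RNG.uniform(-1, 1, (5, 2)).astype(np.float32)
        save_kan(net, tmp_path / "net.npz")
        net2 = load_kan(tmp_path / "net.npz")
        assert np.allclose(net.forward(x), net2.forward(x), atol=1e-7)
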