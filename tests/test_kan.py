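"""Kolmogorov-Arnold layer: B-spline basis, base/spline paths, gradients."""

import numpy as np
import pytest

from emokan.errors import ConfigError
from emokan.nn import KANLayer, bspline_basis, bspline_basis_and_deriv, kan_param_count
from emokan.nn.kan import make_grid, silu


def de_boor_basis(x: float, knots: np.ndarray, i: int, k: int) -> float:
    """Independent recursive Cox-de Boor oracle for one basis function."""
    if k == 0:
        return 1.0 if knots[i] <= x < knots[i + 1] else 0.0
    left = 0.0
    if knots[i + k] != knots[i]:
        left = (x - knots[i]) / (knots[i + k] - knots[i]) * de_boor_basis(x, knots, i, k - 1)
    right = 0.0
    if knots[i + k + 1] != knots[i + 1]:
        right = ((knots[i + k + 1] - x) / (knots[i + k + 1] - knots[i + 1])
                 * de_boor_basis(x, knots, i + 1, k - 1))
    return left + right


class TestBSplineBasis:
    def test_order_zero_is_indicator(self):
        grid = make_grid(5, 0)
        x = np.array([-0.9, -0.1, 0.55])
        basis = bspline_basis(x, grid, 0)
        assert basis.shape == (3, 5)
        assert np.all(basis.sum(axis=-1) == 1.0)
        assert np.all((basis == 0.0) | (basis == 1.0))

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_partition_of_unity(self, rng, k):
        grid = make_grid(5, k)
        x = rng.uniform(-1.0, 1.0, size=200)
        basis = bspline_basis(x, grid, k)
        assert np.max(np.abs(basis.sum(axis=-1) - 1.0)) < 1e-9

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_recursive_oracle(self, rng, k):
        grid = make_grid(4, k, (-2.0, 1.5))
        xs = rng.uniform(-2.0, 1.5, size=9)
        basis = bspline_basis(xs, grid, k)
        n_basis = len(grid) - 1 - k
        for xi, x in enumerate(xs):
            for i in range(n_basis):
                assert basis[xi, i] == pytest.approx(de_boor_basis(float(x), grid, i, k),
                                                     abs=1e-9)

    def test_derivative_matches_finite_difference(self, rng):
        grid = make_grid(5, 3)
        x = rng.uniform(-0.95, 0.95, size=20)
        _, deriv = bspline_basis_and_deriv(x, grid, 3)
        eps = 1e-6
        fd = (bspline_basis(x + eps, grid, 3) - bspline_basis(x - eps, grid, 3)) / (2 * eps)
        assert np.max(np.abs(deriv - fd)) < 1e-6

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigError):
            bspline_basis(np.zeros(2), np.array([0.0, 1.0, 0.5]), 1)
        with pytest.raises(ConfigError):
            make_grid(0, 3)


class TestKANPaths:
    def test_base_path(self, rng):
        layer = KANLayer(4, 3, rng)
        layer.W_spline.value[...] = 0.0
        x = np.zeros((2, 4), dtype=np.float32)
        assert np.allclose(layer.forward(x), 0.0)  # SiLU(0)=0
        x = np.full((2, 4), 30.0, dtype=np.float32)
        expected = x @ layer.W_base.value  # SiLU(x) ~ x for large x
        assert np.allclose(layer.forward(x), expected, rtol=1e-4)
        x = rng.standard_normal((5, 4)).astype(np.float32)
        assert np.allclose(layer.forward(x), silu(x) @ layer.W_base.value, atol=1e-6)

    def test_spline_path_zeroing(self, rng):
        x = rng.standard_normal((5, 4)).astype(np.float32)
        layer = KANLayer(4, 3, rng)
        layer.W_base.value[...] = 0.0
        layer.W_spline.value[...] = 0.0
        assert np.allclose(layer.forward(x), 0.0)
        layer = KANLayer(4, 3, rng)
        layer.W_base.value[...] = 0.0
        layer.scaler.value[...] = 0.0
        assert np.allclose(layer.forward(x), 0.0)

    def test_scalar_spline_matches_brute_force(self, rng):
        layer = KANLayer(1, 1, rng, grid_size=5, spline_order=3)
        layer.W_base.value[...] = 0.0
        x = rng.uniform(-1, 1, size=(7, 1))
        out = layer.forward(x)
        for n in range(7):
            expected = 0.0
            for k_idx in range(layer.n_coef):
                b = de_boor_basis(float(x[n, 0]), layer.grid, k_idx, 3)
                expected += b * float(layer.W_spline.value[0, 0, k_idx])
            expected *= float(layer.scaler.value[0, 0])
            assert out[n, 0] == pytest.approx(expected, abs=1e-6)

    def test_forward_is_sum_of_paths(self, rng):
        x = rng.standard_normal((6, 5)).astype(np.float32)
        layer = KANLayer(5, 4, rng)
        full = layer.forward(x)
        w_base = layer.W_base.value.copy()
        layer.W_base.value[...] = 0.0
        spline_only = layer.forward(x)
        layer.W_base.value[...] = w_base
        w_spl = layer.W_spline.value.copy()
        layer.W_spline.value[...] = 0.0
        base_only = layer.forward(x)
        layer.W_spline.value[...] = w_spl
        assert np.allclose(full, base_only + spline_only, atol=1e-5)

    def test_linear_in_spline_coefficients(self, rng):
        x = rng.uniform(-1, 1, size=(4, 3)).astype(np.float32)
        layer = KANLayer(3, 2, rng)
        layer.W_base.value[...] = 0.0
        once = layer.forward(x)
        layer.W_spline.value *= 2.0
        assert np.allclose(layer.forward(x), 2.0 * once, atol=1e-6)


class TestParamCount:
    @pytest.mark.parametrize("args,expected", [
        ((1, 1, 5, 3), 10),
        ((256, 128, 5, 3), 327_680),
        ((2, 3, 4, 3), 54),
    ])
    def test_formula(self, args, expected):
        assert kan_param_count(*args) == expected

    def test_layer_matches_formula(self, rng):
        layer = KANLayer(6, 4, rng, grid_size=7, spline_order=2)
        assert sum(p.size for p in layer.params()) == kan_param_count(6, 4, 7, 2)


class TestGradients:
    def test_finite_difference_matches_backward(self, rng):
        """Autodiff-style gradient of the layer vs finite differences (float64)."""
        layer = KANLayer(4, 3, rng, grid_size=4, spline_order=3)
        for p in layer.params():
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        x = rng.uniform(-0.9, 0.9, size=(6, 4))
        w_out = rng.standard_normal(3)

        def loss():
            return float(np.sum(layer.forward(x) @ w_out))

        layer.forward(x)
        layer.backward(np.tile(w_out, (6, 1)))
        eps = 1e-6
        for p in layer.params():
            flat, g = p.value.ravel(), p.grad.ravel()
            for j in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp = loss()
                flat[j] = orig - eps
                lm = loss()
                flat[j] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(g[j], abs=1e-4)

        # input gradient
        dx = np.zeros_like(x)
        grad_out = np.tile(w_out, (6, 1))
        for p in layer.params():
            p.zero_grad()
        layer.forward(x)
        dx = layer.backward(grad_out)
        for (n, i) in [(0, 0), (2, 3), (5, 1)]:
            xp = x.copy()
            xp[n, i] += eps
            lp = float(np.sum(layer.forward(xp) @ w_out))
            xp[n, i] -= 2 * eps
            lm = float(np.sum(layer.forward(xp) @ w_out))
            assert (lp - lm) / (2 * eps) == pytest.approx(dx[n, i], abs=1e-4)
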