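"""Kolmogorov-Arnold layer: a SiLU linear path plus a learnable B-spline path.

Each input-output edge carries its own spline, expressed in a shared uniform
B-spline basis over [-1, 1] (the correction stage bounds the features).  The
layer output is ``SiLU(X) @ W_base + sum_i scaler[i,o] * sum_k B_k(x_i) *
W_spline[i,o,k]``.  With ``grid_size`` intervals and polynomial order ``k``
there are ``grid_size + k`` basis functions, hence
``d_in * d_out * (2 + grid_size + k)`` parameters per layer.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError
from .core import DTYPE, Layer, Parameter


def make_grid(grid_size: int, spline_order: int, grid_range=(-1.0, 1.0)) -> np.ndarray:
    """Uniform knot vector over the range, extended by ``spline_order`` knots each side."""
    lo, hi = grid_range
    if not (grid_size >= 1 and spline_order >= 0 and hi > lo):
        raise ConfigError("need grid_size >= 1, spline_order >= 0 and hi > lo")
    h = (hi - lo) / grid_size
    return lo + h * np.arange(-spline_order, grid_size + spline_order + 1)


def bspline_basis(x, grid: np.ndarray, k: int) -> np.ndarray:
    """Cox-de Boor basis values at ``x`` (any shape); appends an axis of length
    ``len(grid) - 1 - k`` (= grid_size + k for an extended uniform grid)."""
    grid = np.asarray(grid, dtype=float)
    if k < 0 or len(grid) < k + 2 or np.any(np.diff(grid) <= 0):
        raise ConfigError("invalid spline grid or order")
    x = np.asarray(x, dtype=float)[..., None]
    basis = ((x >= grid[:-1]) & (x < grid[1:])).astype(float)
    for d in range(1, k + 1):
        left = (x - grid[: -(d + 1)]) / (grid[d:-1] - grid[: -(d + 1)]) * basis[..., :-1]
        right = (grid[d + 1:] - x) / (grid[d + 1:] - grid[1:-d]) * basis[..., 1:]
        basis = left + right
    return basis


def bspline_basis_and_deriv(x, grid: np.ndarray, k: int):
    """Basis values and their x-derivatives (via the order-(k-1) basis)."""
    basis = bspline_basis(x, grid, k)
    if k == 0:
        return basis, np.zeros_like(basis)
    lower = bspline_basis(x, grid, k - 1)
    denom_l = grid[k:-1] - grid[:-(k + 1)]
    denom_r = grid[k + 1:] - grid[1:-k]
    deriv = k * (lower[..., :-1] / denom_l - lower[..., 1:] / denom_r)
    return basis, deriv


def kan_param_count(d_in: int, d_out: int, grid_size: int, spline_order: int) -> int:
    """Base weights + spline coefficients + per-edge scaler."""
    if min(d_in, d_out, grid_size) < 1 or spline_order < 0:
        raise ConfigError("dimensions and grid_size must be positive")
    return d_in * d_out * (2 + grid_size + spline_order)


def silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


class KANLayer(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 grid_size: int = 5, spline_order: int = 3,
                 grid_range=(-1.0, 1.0), spline_init_scale: float = 0.1,
                 name: str = "kan"):
        self.d_in, self.d_out = d_in, d_out
        self.grid_size, self.spline_order = grid_size, spline_order
        self.grid = make_grid(grid_size, spline_order, grid_range)
        self.lo, self.hi = float(grid_range[0]), float(grid_range[1])
        n_coef = grid_size + spline_order
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W_base = Parameter(rng.uniform(-limit, limit, (d_in, d_out)),
                                name=f"{name}.W_base", decay=True)
        self.W_spline = Parameter(
            rng.normal(0.0, spline_init_scale / np.sqrt(d_in), (d_in, d_out, n_coef)),
            name=f"{name}.W_spline", decay=True)
        self.scaler = Parameter(np.ones((d_in, d_out)), name=f"{name}.scaler")
        self.n_coef = n_coef

    def params(self):
        return [self.W_base, self.W_spline, self.scaler]

    def _scaled_spline_flat(self) -> np.ndarray:
        # (d_in * n_coef, d_out) view of scaler-weighted spline coefficients
        wsc = self.W_spline.value * self.scaler.value[:, :, None]
        return wsc.transpose(0, 2, 1).reshape(self.d_in * self.n_coef, self.d_out)

    def forward(self, x, training=False):
        self._x = x
        xc = np.clip(x, self.lo, self.hi)
        dtype = np.asarray(x).dtype if np.asarray(x).dtype.kind == "f" else DTYPE
        self._in_range = ((x >= self.lo) & (x <= self.hi)).astype(dtype)
        basis, deriv = bspline_basis_and_deriv(xc, self.grid, self.spline_order)
        self._basis = basis.astype(dtype)
        self._deriv = deriv.astype(dtype)
        sig = 1.0 / (1.0 + np.exp(-x))
        self._sig = sig
        self._silu = x * sig
        bflat = self._basis.reshape(x.shape[0], -1)
        self._bflat = bflat
        return self._silu @ self.W_base.value + bflat @ self._scaled_spline_flat()

    def backward(self, grad):
        n = grad.shape[0]
        # base path
        self.W_base.grad += self._silu.T @ grad
        dsilu = grad @ self.W_base.value.T
        dx = dsilu * (self._sig * (1.0 + self._x * (1.0 - self._sig)))
        # spline coefficient gradients share T[i,o,k] = sum_n grad[n,o]*B[n,i,k]
        T = (self._bflat.T @ grad).reshape(self.d_in, self.n_coef, self.d_out)
        T = T.transpose(0, 2, 1)  # (d_in, d_out, n_coef)
        self.W_spline.grad += T * self.scaler.value[:, :, None]
        self.scaler.grad += (T * self.W_spline.value).sum(axis=-1)
        # input gradient through the spline path (zero where input was clamped)
        m = (grad @ self._scaled_spline_flat().T).reshape(n, self.d_in, self.n_coef)
        dx += (m * self._deriv).sum(axis=-1) * self._in_range
        return dx
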