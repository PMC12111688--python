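"""Frequency-channel attention (F2CA).

A squeeze-excitation style gate whose channel descriptor is the real part of
the full-length discrete Fourier transform of the globally averaged channel
vector: pool -> Re(DFT) -> bottleneck (ReLU) -> expand (sigmoid) -> rescale.
The DFT is unnormalised and length-preserving (C in, C out), so the
bottleneck weight is C x C/r; with biases in both layers the block adds
(C*C/r + C/r) + (C/r*C + C) parameters — 1,096 for C=64, r=8.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError
from .core import DTYPE, Layer, Parameter, glorot_uniform


def dft_real_matrix(c: int) -> np.ndarray:
    """Matrix R with R[k, n] = cos(2*pi*k*n / C): freg = R @ v1 = Re(DFT(v1))."""
    k = np.arange(c)
    return np.cos(2.0 * np.pi * np.outer(k, k) / c)


def global_average_pool(activation_map: np.ndarray) -> np.ndarray:
    """Mean over the spatial axes of an (H, W, C) or (N, H, W, C) map."""
    activation_map = np.asarray(activation_map, dtype=float)
    axes = (0, 1) if activation_map.ndim == 3 else (1, 2)
    return activation_map.mean(axis=axes)


def fourier_descriptor(v1: np.ndarray) -> np.ndarray:
    """Real part of the full-length unnormalised DFT of the channel vector."""
    v1 = np.asarray(v1, dtype=float)
    return np.fft.fft(v1, axis=-1).real


def excite(freg: np.ndarray, W1: np.ndarray, b1: np.ndarray,
           W2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Bottleneck gate: sigmoid(W2 . relu(W1 . freg + b1) + b2), values in (0, 1)."""
    hidden = np.maximum(freg @ W1 + b1, 0.0)
    return 1.0 / (1.0 + np.exp(-(hidden @ W2 + b2)))


def reweight(activation_map: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Scale each channel plane of the map by its attention weight."""
    activation_map = np.asarray(activation_map, dtype=float)
    s = np.asarray(s, dtype=float)
    if activation_map.shape[-1] != s.shape[-1]:
        raise ValueError("attention vector length must equal the channel count")
    return activation_map * s if activation_map.ndim == 3 else activation_map * s[:, None, None, :]


class F2CA(Layer):
    """The attention block as a trainable layer on (N, H, W, C) maps."""

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator,
                 name: str = "f2ca"):
        if channels % ratio:
            raise ConfigError(f"channels {channels} not divisible by ratio {ratio}")
        hidden = channels // ratio
        self.W1 = Parameter(glorot_uniform(rng, (channels, hidden), channels, hidden),
                            name=f"{name}.W1", decay=True)
        self.b1 = Parameter(np.zeros(hidden), name=f"{name}.b1")
        self.W2 = Parameter(glorot_uniform(rng, (hidden, channels), hidden, channels),
                            name=f"{name}.W2", decay=True)
        self.b2 = Parameter(np.zeros(channels), name=f"{name}.b2")
        self.R = dft_real_matrix(channels)  # kept in float64 for descriptor accuracy

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x, training=False):
        self._x = x
        self._hw = x.shape[1] * x.shape[2]
        v1 = x.mean(axis=(1, 2))
        freg = v1 @ self.R.T
        z1 = freg @ self.W1.value + self.b1.value
        a = np.maximum(z1, 0.0)
        z2 = a @ self.W2.value + self.b2.value
        s = (1.0 / (1.0 + np.exp(-z2))).astype(x.dtype)
        self._freg, self._z1, self._a, self._s = freg, z1, a, s
        return x * s[:, None, None, :]

    def backward(self, grad):
        x, s = self._x, self._s
        dx = grad * s[:, None, None, :]
        ds = (grad * x).sum(axis=(1, 2))
        dz2 = ds * s * (1.0 - s)
        self.W2.grad += self._a.T @ dz2
        self.b2.grad += dz2.sum(axis=0)
        dz1 = (dz2 @ self.W2.value.T) * (self._z1 > 0)
        self.W1.grad += self._freg.T @ dz1
        self.b1.grad += dz1.sum(axis=0)
        dv1 = ((dz1 @ self.W1.value.T) @ self.R).astype(dx.dtype)
        dx += dv1[:, None, None, :] / dx.dtype.type(self._hw)
        return dx
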