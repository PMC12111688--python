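"""The four ablation architectures and group fusion.

All variants share the backbone: three 3x3 same-padding convolutions with
32, 64 and 64 filters, each followed by batch-norm, ReLU and dropout
(0.5 / 0.4 / 0.3), then flatten (4*4*64 = 1024) -> dense 256 (ReLU) ->
dropout 0.5.  Heads:

* ``cnn``          — dense ``num_classes``
* ``cnn_fcn``      — dense 128 (ReLU) -> dense ``num_classes``
* ``cnn_kan``      — KAN(256 -> 128) -> dense ``num_classes``
* ``cnn_kan_f2ca`` — as ``cnn_kan`` with the F2CA attention block inserted
  after the third convolution, on the 4x4x64 map.

With ``num_classes=4`` the ``cnn`` variant totals 320,388 parameters and
``cnn_fcn`` 352,772 (batch-norm moving statistics counted); F2CA adds
exactly 1,096 at C=64, r=8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .nn import (
    F2CA,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    KANLayer,
    MeanFusion,
    Network,
    ReLU,
)

VARIANTS = ("cnn", "cnn_fcn", "cnn_kan", "cnn_kan_f2ca")


@dataclass
class KANConfig:
    d_hidden: int = 128
    grid_size: int = 5
    spline_order: int = 3
    grid_range: tuple = (-1.0, 1.0)


@dataclass
class ModelConfig:
    variant: str = "cnn_kan_f2ca"
    num_classes: int = 4
    conv_filters: tuple = (32, 64, 64)
    conv_kernel: int = 3
    dropout_conv: tuple = (0.5, 0.4, 0.3)
    dropout_fc: float = 0.5
    l2: float = 0.001
    f2ca_ratio: int = 8
    group_size: int = 1  # 12 fuses per-window embeddings in KAN variants
    fusion: str = "mean"
    kan: KANConfig = field(default_factory=KANConfig)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.num_classes < 2 or self.group_size < 1:
            raise ConfigError("num_classes >= 2 and group_size >= 1 required")
        if self.fusion not in ("mean", "concat"):
            raise ConfigError(f"fusion must be 'mean' or 'concat', got {self.fusion!r}")


def build_model(config: ModelConfig, seed: int = 0, input_shape=(4, 4, 3)) -> Network:
    """Assemble one ablation variant as a trainable network."""
    rng = np.random.default_rng(seed)
    h, w, c_in = input_shape
    layers: list = []
    c_prev = c_in
    for i, (filters, rate) in enumerate(zip(config.conv_filters, config.dropout_conv)):
        layers += [
            Conv2D(c_prev, filters, rng, kernel=config.conv_kernel, name=f"conv{i + 1}"),
            BatchNorm(filters, name=f"bn{i + 1}"),
            ReLU(),
            Dropout(rate),
        ]
        c_prev = filters
    if config.variant == "cnn_kan_f2ca":
        layers.append(F2CA(c_prev, config.f2ca_ratio, rng))
    flat = h * w * c_prev
    layers += [Flatten(), Dense(flat, 256, rng, activation="relu", name="dense1"),
               Dropout(config.dropout_fc)]

    fused_dim = 256
    if config.group_size > 1 and config.variant in ("cnn_kan", "cnn_kan_f2ca"):
        if config.fusion == "mean":
            layers.append(MeanFusion(config.group_size))
        else:
            layers += [GroupConcat(config.group_size)]
            fused_dim = 256 * config.group_size

    if config.variant == "cnn":
        layers.append(Dense(fused_dim, config.num_classes, rng, name="head"))
    elif config.variant == "cnn_fcn":
        layers += [Dense(fused_dim, 128, rng, activation="relu", name="fc2"),
                   Dense(128, config.num_classes, rng, name="head")]
    else:
        layers += [KANLayer(fused_dim, config.kan.d_hidden, rng,
                            grid_size=config.kan.grid_size,
                            spline_order=config.kan.spline_order,
                            grid_range=config.kan.grid_range),
                   Dense(config.kan.d_hidden, config.num_classes, rng, name="head")]
    net = Network(layers, seed=seed)
    net.config = config
    return net


class GroupConcat(MeanFusion):
    """Concatenate (rather than average) the embeddings of one sample group."""

    def forward(self, x, training=False):
        g = self.group_size
        if g == 1:
            return x
        if x.shape[0] % g:
            raise ValueError(f"batch of {x.shape[0]} not divisible by group size {g}")
        self._d = x.shape[1]
        return x.reshape(-1, g * x.shape[1])

    def backward(self, grad):
        if self.group_size == 1:
            return grad
        return grad.reshape(-1, self._d)


def count_params(model: Network) -> int:
    """Total parameter count, batch-norm moving statistics included."""
    return model.count_params()


def fuse_group(per_window_features, mode: str = "mean") -> np.ndarray:
    """Fuse the per-window feature vectors of one sample group into one vector."""
    group = np.stack([np.asarray(v, dtype=float) for v in per_window_features])
    if group.ndim != 2:
        raise ValueError("expected equally sized 1-D vectors")
    if mode == "mean":
        return group.mean(axis=0)
    if mode == "concat":
        return group.reshape(-1)
    raise ConfigError(f"unknown fusion mode {mode!r}")


def predict(model: Network, batch: np.ndarray) -> np.ndarray:
    """Class probabilities (softmax rows) for a pseudo-RGB batch, dropout off."""
    return model.predict_proba(np.asarray(batch))
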