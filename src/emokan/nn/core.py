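"""Layers, the sequential network container, losses and the Adam optimizer.

Conventions
-----------
* Activations flow as float32; images are NHWC.
* ``Layer.forward(x, training)`` caches what ``backward`` needs; ``backward``
  accumulates parameter gradients and returns the gradient w.r.t. its input.
* ``Parameter.decay`` marks weights subject to the L2 penalty (kernels only;
  biases, batch-norm and spline scalers are exempt).
* Parameter counting includes batch-norm moving statistics, the convention
  under which the reference architecture totals decompose exactly.
"""

from __future__ import annotations

import json

import numpy as np

from ..errors import ConfigError

DTYPE = np.float32


class Parameter:
    def __init__(self, value: np.ndarray, name: str = "", trainable: bool = True,
                 decay: bool = False):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = trainable
        self.decay = decay

    @property
    def size(self) -> int:
        return int(self.value.size)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str | None = None, name: str = "dense"):
        self.W = Parameter(glorot_uniform(rng, (d_in, d_out), d_in, d_out),
                           name=f"{name}.W", decay=True)
        self.b = Parameter(np.zeros(d_out), name=f"{name}.b")
        if activation not in (None, "relu"):
            raise ConfigError(f"unsupported activation {activation!r}")
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "relu":
            self._mask = z > 0
            z = z * self._mask
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv2D(Layer):
    """3x3 convolution, stride 1, same padding, NHWC, via im2col."""

    def __init__(self, c_in: int, filters: int, rng: np.random.Generator,
                 kernel: int = 3, name: str = "conv"):
        k = kernel
        fan_in, fan_out = k * k * c_in, k * k * filters
        self.W = Parameter(glorot_uniform(rng, (k * k * c_in, filters), fan_in, fan_out),
                           name=f"{name}.W", decay=True)
        self.b = Parameter(np.zeros(filters), name=f"{name}.b")
        self.k = k
        self.c_in = c_in
        self.filters = filters

    def params(self):
        return [self.W, self.b]

    def _im2col(self, xpad, H, W):
        k = self.k
        cols = np.empty((xpad.shape[0], H, W, k, k, xpad.shape[-1]), dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                cols[:, :, :, di, dj, :] = xpad[:, di:di + H, dj:dj + W, :]
        return cols

    def forward(self, x, training=False):
        n, H, W, c = x.shape
        p = self.k // 2
        xpad = np.zeros((n, H + 2 * p, W + 2 * p, c), dtype=DTYPE)
        xpad[:, p:p + H, p:p + W, :] = x
        cols = self._im2col(xpad, H, W).reshape(n * H * W, -1)
        self._cols, self._shape = cols, (n, H, W, c)
        out = cols @ self.W.value + self.b.value
        return out.reshape(n, H, W, self.filters)

    def backward(self, grad):
        n, H, W, c = self._shape
        k, p = self.k, self.k // 2
        g = grad.reshape(n * H * W, self.filters)
        self.W.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value.T).reshape(n, H, W, k, k, c)
        dxpad = np.zeros((n, H + 2 * p, W + 2 * p, c), dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                dxpad[:, di:di + H, dj:dj + W, :] += dcols[:, :, :, di, dj, :]
        return dxpad[:, p:p + H, p:p + W, :]


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, H, W) with moving statistics."""

    # momentum 0.9 so the moving statistics converge within the short
    # (tens of epochs) schedules this package trains on desk-scale data
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "bn"):
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.moving_mean = Parameter(np.zeros(channels), name=f"{name}.moving_mean",
                                     trainable=False)
        self.moving_var = Parameter(np.ones(channels), name=f"{name}.moving_var",
                                    trainable=False)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta, self.moving_mean, self.moving_var]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean.value = (m * self.moving_mean.value + (1 - m) * mean).astype(DTYPE)
            self.moving_var.value = (m * self.moving_var.value + (1 - m) * var).astype(DTYPE)
        else:
            mean, var = self.moving_mean.value, self.moving_var.value
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = (x - mean) * self._inv
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        axes = self._axes
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.value
        if not self._training:
            return gxhat * self._inv
        m = self._m
        return (self._inv / m) * (
            m * gxhat - gxhat.sum(axis=axes) - self._xhat * (gxhat * self._xhat).sum(axis=axes)
        )


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ConfigError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(0)  # reseeded by the owning Network

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MeanFusion(Layer):
    """Average embeddings over consecutive groups of ``group_size`` rows.

    Fuses the per-window embeddings of one sample group into a single vector
    before the classifier head; the batch shrinks by the group factor.
    """

    def __init__(self, group_size: int):
        if group_size < 1:
            raise ConfigError("group_size must be >= 1")
        self.group_size = group_size

    def forward(self, x, training=False):
        g = self.group_size
        if g == 1:
            return x
        if x.shape[0] % g:
            raise ValueError(f"batch of {x.shape[0]} not divisible by group size {g}")
        self._n = x.shape[0]
        return x.reshape(-1, g, x.shape[1]).mean(axis=1)

    def backward(self, grad):
        g = self.group_size
        if g == 1:
            return grad
        return np.repeat(grad / g, g, axis=0)


class Network:
    """A plain sequential container with a shared RNG for dropout masks."""

    def __init__(self, layers: list[Layer], seed: int = 0):
        self.layers = layers
        self.reseed(seed)

    def reseed(self, seed: int) -> None:
        ss = np.random.SeedSequence(seed)
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(ss.spawn(1)[0])

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def trainable_params(self) -> list[Parameter]:
        return [p for p in self.params() if p.trainable]

    def count_params(self) -> int:
        """Total parameters, batch-norm moving statistics included."""
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        chunks = [softmax(self.forward(x[i:i + batch_size], training=False))
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0)

    def summary(self) -> list[dict]:
        """Per-layer name / parameter-count records (JSON-serialisable)."""
        rows = []
        for layer in self.layers:
            rows.append({
                "layer": type(layer).__name__,
                "params": sum(p.size for p in layer.params()),
            })
        rows.append({"layer": "TOTAL", "params": self.count_params()})
        return rows

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state, seen = {}, set()
        for i, p in enumerate(self.params()):
            key = p.name or f"param_{i}"
            if key in seen:
                key = f"{key}__{i}"
            seen.add(key)
            state[key] = p.value
        return state

    def save(self, path, meta: dict | None = None) -> None:
        arrays = self.state_dict()
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta or {}).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    def load(self, path) -> dict:
        with np.load(path) as data:
            keys = [k for k in data.files if k != "__meta__"]
            params = self.params()
            if len(keys) != len(params):
                raise ConfigError("checkpoint does not match the architecture")
            for p, key in zip(params, keys):
                value = data[key]
                if value.shape != p.value.shape:
                    raise ConfigError(f"shape mismatch for {key}")
                p.value = value.astype(DTYPE)
            meta = json.loads(bytes(data["__meta__"]).decode()) if "__meta__" in data.files else {}
        return meta


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy of integer labels; returns ``(loss, dlogits)``."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -float(logp[np.arange(n), y].mean())
    grad = np.exp(logp)
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(DTYPE)


class Adam:
    """Adam with optional decoupled-from-loss L2 gradient term (lambda * 2w)."""

    def __init__(self, params: list[Parameter], lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7, l2: float = 0.0):
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def penalty(self) -> float:
        """The L2 term added to the loss: l2 * sum of squared decaying weights."""
        if self.l2 == 0.0:
            return 0.0
        return self.l2 * float(sum(np.sum(p.value.astype(np.float64) ** 2)
                                   for p in self.params if p.decay))

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2 and p.decay:
                g = g + (2.0 * self.l2) * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * (g * g)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
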