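"""Feed-forward layers operating on single samples.

Sequence tensors are ``(timesteps, channels)`` arrays; flat tensors are 1-D.
Each layer implements ``forward(x, training, rng)`` and ``backward(grad)``,
accumulating parameter gradients in ``self.grads`` (same keys as
``self.params``).  L2 penalties follow the ``l2 * sum(w**2)`` convention, so
their gradient contribution is ``2 * l2 * w``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1D", "MaxPool1D", "Flatten", "Dropout", "Sequential"]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def relu_grad(a: np.ndarray) -> np.ndarray:
    return (a > 0.0).astype(a.dtype)


_ACTIVATIONS = {
    "relu": (relu, relu_grad),
    "tanh": (np.tanh, lambda a: 1.0 - np.tanh(a) ** 2),
    "linear": (lambda a: a, lambda a: np.ones_like(a)),
}


class Layer:
    """Base class: parameterless identity."""

    stage: str = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def l2_loss(self) -> float:
        return 0.0

    def add_l2_grads(self) -> None:
        pass

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))


class Dense(Layer):
    """Fully connected layer on a flat input: ``y = act(x W + b)``."""

    def __init__(self, in_dim: int, out_dim: int, activation: str = "linear",
                 l2: float = 0.0, stage: str = "dense") -> None:
        super().__init__()
        self.in_dim, self.out_dim = int(in_dim), int(out_dim)
        self.act, self.act_grad = _ACTIVATIONS[activation]
        self.activation = activation
        self.l2 = float(l2)
        self.stage = stage

    def init(self, rng: np.random.Generator) -> None:
        self.params = {
            "W": glorot_uniform(rng, (self.in_dim, self.out_dim),
                                self.in_dim, self.out_dim),
            "b": np.zeros(self.out_dim),
        }
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        self._x = x
        self._a = x @ self.params["W"] + self.params["b"]
        return self.act(self._a)

    def backward(self, grad):
        da = grad * self.act_grad(self._a)
        self.grads["W"] += np.outer(self._x, da)
        self.grads["b"] += da
        return da @ self.params["W"].T

    def l2_loss(self) -> float:
        return self.l2 * float(np.sum(self.params["W"] ** 2))

    def add_l2_grads(self) -> None:
        if self.l2:
            self.grads["W"] += 2.0 * self.l2 * self.params["W"]


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution over ``(T, C)`` input.

    Output is ``(T - kernel + 1, filters)``; each filter spans all input
    channels.  ReLU is the conventional activation here.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 activation: str = "relu", l2: float = 0.0) -> None:
        super().__init__()
        self.in_channels = int(in_channels)
        self.filters = int(filters)
        self.kernel = int(kernel)
        self.act, self.act_grad = _ACTIVATIONS[activation]
        self.l2 = float(l2)
        self.stage = "conv1d"

    def init(self, rng):
        fan_in = self.kernel * self.in_channels
        self.params = {
            "W": glorot_uniform(rng, (self.kernel, self.in_channels, self.filters),
                                fan_in, self.filters),
            "b": np.zeros(self.filters),
        }
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        T = x.shape[0]
        if T < self.kernel:
            raise ValueError(
                f"input length {T} shorter than kernel {self.kernel}"
            )
        # windows: (T-K+1, C, K)
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=0)
        self._win = win
        self._a = np.einsum("tck,kcf->tf", win, self.params["W"]) + self.params["b"]
        return self.act(self._a)

    def backward(self, grad):
        da = grad * self.act_grad(self._a)  # (T-K+1, F)
        self.grads["W"] += np.einsum("tck,tf->kcf", self._win, da)
        self.grads["b"] += da.sum(axis=0)
        T = self._win.shape[0] + self.kernel - 1
        dx = np.zeros((T, self.in_channels))
        for k in range(self.kernel):
            dx[k : k + da.shape[0]] += da @ self.params["W"][k].T
        return dx

    def l2_loss(self) -> float:
        return self.l2 * float(np.sum(self.params["W"] ** 2))

    def add_l2_grads(self) -> None:
        if self.l2:
            self.grads["W"] += 2.0 * self.l2 * self.params["W"]


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; output length floor(T/pool).

    A map shorter than the pool width is pooled whole (output length 1) so
    that short windows — lag as low as 3 with kernel 3 — survive the stack.
    """

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = int(pool)
        self.stage = "maxpool"

    def forward(self, x, training=False, rng=None):
        T, C = x.shape
        pool = min(self.pool, T)
        n_out = T // pool
        trimmed = x[: n_out * pool].reshape(n_out, pool, C)
        self._argmax = trimmed.argmax(axis=1)  # (n_out, C)
        self._in_shape = (T, C)
        self._pool_used = pool
        return trimmed.max(axis=1)

    def backward(self, grad):
        T, C = self._in_shape
        pool = self._pool_used
        dx = np.zeros((T, C))
        n_out = grad.shape[0]
        rows = (np.arange(n_out)[:, None] * pool + self._argmax)  # (n_out, C)
        np.add.at(dx, (rows, np.arange(C)[None, :]), grad)
        return dx


class Flatten(Layer):
    """Reshape to 1-D (identity on already-flat input)."""

    def __init__(self) -> None:
        super().__init__()
        self.stage = "flatten"

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(-1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active only when ``training`` is true."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = float(rate)
        self.stage = "dropout"

    def forward(self, x, training=False, rng=None):
        if training and self.rate > 0.0:
            if rng is None:
                raise ValueError("dropout in training mode needs an rng")
            keep = 1.0 - self.rate
            self._mask = (rng.random(x.shape) < keep) / keep
            return x * self._mask
        self._mask = None
        return x

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential:
    """Ordered layer stack for single-sample forward/backward passes."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def init(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init(rng)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def l2_loss(self) -> float:
        return float(sum(layer.l2_loss() for layer in self.layers))

    def add_l2_grads(self) -> None:
        for layer in self.layers:
            layer.add_l2_grads()

    @property
    def stages(self) -> list[str]:
        return [layer.stage for layer in self.layers]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"{i}:{layer.stage}:{k}"] = v
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = np.asarray(weights[f"{i}:{layer.stage}:{k}"])
            layer.zero_grads()
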