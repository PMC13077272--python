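"""Minimal neural-network primitives with explicit caches.

Every layer keeps the forward activations and the backward gradient signal of
the last pass. That bookkeeping is what the rest of the package is built on:

* layer-wise relevance propagation re-reads the cached activations,
* differentially private training reconstructs *per-sample* gradients from the
  cached ``(input, output-gradient)`` pair of each affine layer without ever
  materialising a per-sample gradient tensor (for a dense layer the per-sample
  weight gradient is the outer product ``x_i g_i``, whose L1 norm factorises as
  ``|x_i|_1 |g_i|_1``).

All randomness is injected through :class:`numpy.random.Generator` instances;
no layer owns global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Dense",
    "ReLU",
    "Dropout",
    "BatchNorm",
    "Embedding",
    "MLP",
    "Adam",
    "SGD",
]


@dataclass
class Param:
    """A trainable tensor with its accumulated gradient."""

    data: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Dense:
    """Affine layer ``y = x W + b`` with He-style initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self.n_in = n_in
        self.n_out = n_out
        self._x: np.ndarray | None = None
        self._g: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        self._g = g
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.data.T

    # ---- per-sample gradient access (used by the privacy module) ----
    def per_sample_l1(self) -> np.ndarray:
        """L1 norm of each sample's (W, b) gradient contribution."""
        xs = np.abs(self._x).sum(axis=1)
        gs = np.abs(self._g).sum(axis=1)
        return xs * gs + gs

    def weighted_grads(self, w: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the *weighted sum* over samples, weights ``w``."""
        xw = self._x * w[:, None]
        return {"W": xw.T @ self._g, "b": w @ self._g}

    def params(self) -> dict[str, Param]:
        return {"W": self.W, "b": self.b}


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask

    def params(self) -> dict[str, Param]:
        return {}


class Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = 1.0
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask

    def params(self) -> dict[str, Param]:
        return {}


class BatchNorm:
    """Per-feature normalisation with learnable scale/shift.

    Modes:
      * ``training=True`` and not frozen: batch statistics, running stats
        updated with ``momentum``.
      * ``training=False``: running statistics (inference mode).
      * ``frozen=True``: running statistics even while training, which keeps
        the layer's gradients per-sample separable — required during
        differentially private steps, where batch statistics would couple
        samples and break the sensitivity analysis.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.frozen = False
        self._xhat: np.ndarray | None = None
        self._g: np.ndarray | None = None
        self._istd: np.ndarray | None = None
        self._batch_mode = False

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if training and not self.frozen:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._batch_mode = True
        else:
            mean = self.running_mean
            var = self.running_var
            self._batch_mode = False
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return self.gamma.data * self._xhat + self.beta.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        self._g = g
        xhat, istd = self._xhat, self._istd
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        gx = g * self.gamma.data
        if not self._batch_mode:
            return gx * istd
        n = g.shape[0]
        return (istd / n) * (n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))

    def per_sample_l1(self) -> np.ndarray:
        gs = np.abs(self._g)
        return (gs * np.abs(self._xhat)).sum(axis=1) + gs.sum(axis=1)

    def weighted_grads(self, w: np.ndarray) -> dict[str, np.ndarray]:
        gw = self._g * w[:, None]
        return {"gamma": (gw * self._xhat).sum(axis=0), "beta": gw.sum(axis=0)}

    # Affine view with the statistics used on the last forward pass; consumed
    # by LRP, which treats the layer as a diagonal linear map.
    def affine_view(self) -> tuple[np.ndarray, np.ndarray]:
        if self._batch_mode:
            raise RuntimeError("LRP requires an eval/frozen-mode forward pass")
        scale = self.gamma.data * self._istd
        shift = self.beta.data - self.gamma.data * self.running_mean * self._istd
        return scale, shift

    def params(self) -> dict[str, Param]:
        return {"gamma": self.gamma, "beta": self.beta}


class Embedding:
    """Lookup table for one categorical field."""

    def __init__(self, n_levels: int, dim: int, rng: np.random.Generator):
        self.table = Param(rng.normal(0.0, 0.1, size=(n_levels, dim)))
        self.n_levels = n_levels
        self.dim = dim
        self._idx: np.ndarray | None = None

    def forward(self, idx: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        idx = np.asarray(idx)
        if idx.min() < 0 or idx.max() >= self.n_levels:
            raise IndexError(
                f"category index out of range [0, {self.n_levels}): "
                f"[{idx.min()}, {idx.max()}]")
        self._idx = idx
        return self.table.data[idx]

    def backward(self, g: np.ndarray) -> None:
        np.add.at(self.table.grad, self._idx, g)

    def params(self) -> dict[str, Param]:
        return {"table": self.table}


class MLP:
    """A stack of layers applied in order, with flat parameter naming."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> dict[str, Param]:
        out: dict[str, Param] = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"layer{i}.{name}"] = p
        return out

    def set_frozen_batchnorm(self, frozen: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.frozen = frozen


def collect_params(modules: dict[str, object]) -> dict[str, Param]:
    out: dict[str, Param] = {}
    for prefix, mod in modules.items():
        for name, p in mod.params().items():
            out[f"{prefix}.{name}"] = p
    return out


class SGD:
    def __init__(self, params: dict[str, Param], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def step(self) -> None:
        for p in self.params.values():
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            p.data -= self.lr * g

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


class Adam:
    def __init__(self, params: dict[str, Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
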