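"""Minimal module/parameter registry with torch-like semantics."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor


class Module:
    """Base class: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self):
        self.training = True

    # registry walks __dict__ (assignment order, hence deterministic) and
    # recurses through arbitrarily nested lists/tuples of sub-modules
    def _named_items(self, prefix: str = "") -> Iterator[tuple[str, object]]:
        def walk(name: str, value):
            if isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)
            else:
                yield name, value

        for name, value in vars(self).items():
            yield from walk(f"{prefix}{name}", value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for full, value in self._named_items(prefix):
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, value in self._named_items():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- checkpointing ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for full, (owner, attr) in self._buffer_owners(prefix):
            yield full, getattr(owner, attr)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._buffer_owners())
        for name, array in state.items():
            if name in params:
                if params[name].data.shape != array.shape:
                    raise ValueError(f"shape mismatch for parameter {name}")
                params[name].data = np.array(array, dtype=np.float64)
            elif name in buffers:
                owner, attr = buffers[name]
                setattr(owner, attr, np.array(array, dtype=np.float64))
            else:
                raise KeyError(f"unexpected entry in state dict: {name}")

    def _buffer_owners(self, prefix: str = "") -> Iterator[tuple[str, tuple["Module", str]]]:
        own = getattr(self, "_buffers", set())
        for name in vars(self):
            if name in own:
                yield f"{prefix}{name}", (self, name)
        for full, value in self._named_items(prefix):
            if isinstance(value, Module):
                yield from value._buffer_owners(prefix=full + ".")

    def register_buffer(self, name: str, array: np.ndarray) -> None:
        if not hasattr(self, "_buffers"):
            self._buffers: set[str] = set()
        self._buffers.add(name)
        setattr(self, name, np.asarray(array, dtype=np.float64))


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    """Affine map ``x @ W + b`` with Xavier-uniform weights and zero bias."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.W = Tensor(xavier_uniform(rng, in_features, out_features), requires_grad=True)
        self.b = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    """Lookup table initialised N(0, std)."""

    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator, std: float = 0.02):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, std, size=(num_embeddings, dim)), requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        from .autodiff import gather

        return gather(self.weight, indices)


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Needs an rng at call time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics for eval."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.register_buffer("running_mean", np.zeros(dim))
        self.register_buffer("running_var", np.ones(dim))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            if x.shape[0] < 2:
                raise ValueError(
                    "batch normalization is undefined for training batches of size 1; "
                    "use a larger batch size"
                )
            mean = x.mean(axis=0, keepdims=True)
            centered = x - mean
            var = (centered**2.0).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean.data[0]
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data[0]
            xhat = centered * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * Tensor((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class SetNorm(Module):
    """Set normalization: standardize jointly over set elements and features.

    Statistics are taken per set (all elements x all feature channels), then a
    per-feature learnable affine is applied.  A boolean element mask excludes
    padded positions from both the statistics and the output.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        from .autodiff import set_norm

        # x: (..., L, h); statistics over the last two axes jointly
        return set_norm(x, self.gamma, self.beta, mask=mask, eps=self.eps)
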