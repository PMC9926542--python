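"""Layer containers built on the autodiff tensor: Module, Linear, LayerNorm, PReLU."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, layer_norm, prelu


class Parameter(Tensor):
    def __init__(self, data, no_decay: bool = False):
        super().__init__(data, requires_grad=True)
        self.no_decay = no_decay


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal init (clipped at ±2σ), the Swin-family default."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Module:
    """Minimal recursive container with named parameters and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if prefix else name
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # ---- (de)serialisation -------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._modules: list[Module] = list(modules)

    def append(self, m: Module) -> None:
        self._modules.append(m)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[i]

    def _children(self):
        for i, m in enumerate(self._modules):
            yield str(i), m

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._modules):
            yield from m.named_parameters(prefix=f"{prefix}{i}.")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules:
            m.train(mode)
        return self


class Linear(Module):
    """Token-wise affine map; weight stored [in, out] so x @ W + b."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32), no_decay=True) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32), no_decay=True)
        self.beta = Parameter(np.zeros(channels, dtype=np.float32), no_decay=True)
        self.eps = eps

    def forward(self, x):
        return layer_norm(x, self.gamma, self.beta, eps=self.eps)


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.slope = Parameter(np.full(channels, init, dtype=np.float32), no_decay=True)

    def forward(self, x):
        return prelu(x, self.slope)
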