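"""Neural-network building blocks over the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "Conv2d", "Sequential"]


class Module:
    """Base class: child modules and parameters discovered via attributes."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(full))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}"))
                    elif isinstance(item, Tensor):
                        out.append((f"{full}.{i}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, v in state.items():
            if own[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            own[k].data = np.asarray(v, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None, bias: bool = True):
        scale = scale if scale is not None else 1.0 / np.sqrt(n_in)
        self.weight = _param(rng, (n_in, n_out), scale)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, scale: float | None = None):
        scale = scale if scale is not None else 1.0 / np.sqrt(c_in * kernel * kernel)
        self.weight = _param(rng, (c_out, c_in, kernel, kernel), scale)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.items = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x
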