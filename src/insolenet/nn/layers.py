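"""Network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d


class Module:
    """Base class: tracks parameters and sub-modules, supports train/eval mode."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name: str, mod: "Module") -> "Module":
        self._modules[name] = mod
        return mod

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running moments)."""
        out = dict(getattr(self, "_buffers", {}))
        out = {prefix + k: v for k, v in out.items()}
        for name, m in self._modules.items():
            out.update(m.buffers(prefix + name + "."))
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for m in self._modules.values():
            m.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        state.update({"buffer:" + k: v.copy() for k, v in self.buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self._buffer_refs()
        for k, v in state.items():
            if k.startswith("buffer:"):
                ref = buffers[k[len("buffer:"):]]
                ref[...] = v
            else:
                params[k].data = np.array(v, dtype=float)

    def _buffer_refs(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in getattr(self, "_buffers", {}).items()}
        for name, m in self._modules.items():
            out.update(m._buffer_refs(prefix + name + "."))
        return out


def uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, pad: int = 0, bias: bool = True) -> None:
        super().__init__()
        self.stride, self.pad = stride, pad
        fan_in = in_ch * kernel
        self.w = self.param("w", uniform_fan_in(rng, (out_ch, in_ch, kernel), fan_in))
        self.b = self.param("b", np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class BatchNorm1d(Module):
    """Normalization over batch and time for (B, C, L) tensors.

    Uses batch statistics while training and exponential running moments at
    evaluation time.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.param("gamma", np.ones(channels))
        self.beta = self.param("beta", np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels),
            "running_var": np.ones(channels),
        }

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(-1)
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self._buffers["running_mean"].reshape(1, -1, 1)
            sd = np.sqrt(self._buffers["running_var"] + self.eps).reshape(1, -1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, rng, in_dim: int, out_dim: int, bias: bool = True):
        super().__init__()
        self.w = self.param("w", uniform_fan_in(rng, (in_dim, out_dim), in_dim))
        self.b = self.param("b", np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out if self.b is None else out + self.b
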