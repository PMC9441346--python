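"""Layer/module system on top of :mod:`sadgan.nn.tensor`.

Modules register parameters and sub-modules through attribute assignment,
expose ``named_parameters`` / ``state_dict`` for checkpointing, and carry a
train/eval flag that batch normalization consults.  Weight initialization is
Kaiming-normal (fan-in) from a caller-supplied :class:`numpy.random.Generator`
so every network build is seed-reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------ traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k in self._buffers:
            yield prefix + k, getattr(self, k)
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def requires_grad_(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag
        return self

    # ---------------------------------------------------------- state dict
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        for k, b in self.named_buffers():
            d["buffer." + k] = np.asarray(b).copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for k, p in params.items():
            if k not in d:
                raise KeyError(f"missing parameter {k!r} in state dict")
            if d[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            p.data = d[k].astype(p.data.dtype).copy()
        # buffers live on nested modules; walk and assign
        def assign(mod: Module, prefix: str):
            for k in list(mod._buffers):
                full = "buffer." + prefix + k
                if full in d:
                    mod._set_buffer(k, d[full].astype(np.asarray(getattr(mod, k)).dtype).copy())
            for k, sub in mod._modules.items():
                assign(sub, prefix + k + ".")
        assign(self, "")

    def astype(self, dtype):
        """Cast all parameters and buffers (used for float64 gradient checks)."""
        for _, p in self.named_parameters():
            p.data = p.data.astype(dtype)
        def cast(mod: Module):
            for k in list(mod._buffers):
                mod._set_buffer(k, np.asarray(getattr(mod, k)).astype(dtype))
            for sub in mod._modules.values():
                cast(sub)
        cast(self)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        self._modules[str(len(self._list))] = mod
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None, dilation: int = 1, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.dilation = dilation
        # default: same-padding for stride-1 dilated conv
        self.padding = dilation * (kernel - 1) // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding,
                      dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalization over (N,H,W) per channel.

    With the batch size of 1 used throughout training this normalizes each
    channel over its spatial extent, i.e. it behaves as instance
    normalization.  Because the networks only ever see per-input statistics
    during training, inference defaults to the same per-input statistics
    (``use_batch_stats_in_eval``); running averages (momentum 0.1) are still
    tracked and can be switched on for evaluation explicitly.
    """

    use_batch_stats_in_eval = True

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch, dtype=DTYPE))
        self.beta = Parameter(np.zeros(ch, dtype=DTYPE))
        self.register_buffer("running_mean", np.zeros(ch, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(ch, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training or self.use_batch_stats_in_eval:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            if self.training:
                self._set_buffer("running_mean",
                                 (1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
                self._set_buffer("running_var",
                                 (1 - self.momentum) * self.running_var
                                 + self.momentum * var.data.reshape(c))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.body = ModuleList(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.body:
            x = m(x)
        return x


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C)."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C)."""
    n, c, h, w = x.shape
    return x.reshape((n, c, h * w)).max(axis=2)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
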