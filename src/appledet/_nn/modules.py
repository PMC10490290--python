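"""Module / parameter containers and the SGD optimizer."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Parameter(Tensor):
    """A learnable tensor.  ``decay`` marks it for weight decay (conv/linear
    weights only, following common practice of exempting norms and biases)."""

    __slots__ = ("decay",)

    def __init__(self, data: np.ndarray, decay: bool = False):
        super().__init__(data, requires_grad=True)
        self.decay = decay


class Module:
    """Lightweight nn.Module analog: parameter discovery via attributes."""

    def __init__(self):
        self._training = True

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for child in self.children():
            yield from child.modules()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- modes -------------------------------------------------------------
    def train(self, mode: bool = True):
        self._training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    @property
    def training(self) -> bool:
        return self._training

    # -- state dict --------------------------------------------------------
    def state_arrays(self, prefix: str = ""):
        """All persistent arrays (parameters + buffers), name -> ndarray."""
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value.data
            elif isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.state_arrays(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.state_arrays(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.state_arrays()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.state_arrays())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, arr in own.items():
            arr[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class SGD:
    """SGD with Nesterov momentum and decoupled-style weight decay on
    parameters flagged ``decay``."""

    def __init__(self, params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 0.0, nesterov: bool = True):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.nesterov = nesterov
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and getattr(p, "decay", False):
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            upd = g + self.momentum * v if self.nesterov else v
            p.data -= self.lr * upd
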