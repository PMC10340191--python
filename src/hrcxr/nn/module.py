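"""Minimal module/parameter machinery for the numpy layer library.

Every layer is a :class:`Module` holding named :class:`Parameter` leaves and
(optionally) child modules.  Layers implement ``forward`` (caching whatever the
matching ``backward`` needs) and ``backward`` which accumulates gradients into
``Parameter.grad`` and returns the gradient with respect to the layer input.
There is no autograd tape: composite modules chain ``backward`` calls in
reverse order by hand, which keeps the execution fully deterministic.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return int(self.data.size)


class Module:
    """Base class; children and parameters are discovered via attributes."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            mods = self.__dict__.setdefault("_modules", {})
            for i, v in enumerate(value):
                mods[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- modes -------------------------------------------------------------
    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for name, m in self._named_buffers():
            state[name] = m
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = {name: p for name, p in self.named_parameters()}
        bufs = dict(self._named_buffers())
        for key, value in state.items():
            if key in own:
                if own[key].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{own[key].data.shape} vs {value.shape}"
                    )
                own[key].data[...] = value
            elif key in bufs:
                bufs[key][...] = value
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def _named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffers", ()):  # set by layers with state
            yield (prefix + name, getattr(self, name))
        for name, m in self._modules.items():
            yield from m._named_buffers(prefix + name + ".")

    # -- interface ---------------------------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
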