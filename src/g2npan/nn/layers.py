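"""Neural-network layers built on the autograd engine.

Layers follow the familiar Module pattern: parameters are discovered by
attribute walking, ``train()``/``eval()`` toggle batch-norm behaviour, and
``state_dict``/``load_state_dict`` move plain numpy arrays in and out (so
checkpoints are ``np.savez`` archives, portable and dependency-free).

Weight initialization is He-uniform from an explicit ``numpy.random.Generator``
— every network in the package is a pure function of (config, seed).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batch_norm, conv2d

_FLOAT = np.float32


class Module:
    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_state(self) -> dict[str, np.ndarray]:
        out = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict) -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                v._collect_state(key + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{key}.{i}.", out)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing keys: {sorted(missing)[:5]} ...")
        for name, v in self._named_slots():
            src = np.asarray(state[name])
            if isinstance(v[0].__dict__[v[1]], Tensor):
                v[0].__dict__[v[1]].data = src.astype(_FLOAT).reshape(
                    v[0].__dict__[v[1]].data.shape
                )
            else:
                v[0].__dict__[v[1]][...] = src

    def _named_slots(self, prefix: str = ""):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, (Tensor, np.ndarray)):
                yield key, (self, name)
            elif isinstance(v, Module):
                yield from v._named_slots(key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_slots(f"{key}.{i}.")

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(_FLOAT)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        fan_in = in_ch * k * k
        self.weight = Tensor(_he_uniform(rng, (out_ch, in_ch, k, k), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=_FLOAT), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(ch, dtype=_FLOAT), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=_FLOAT), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=_FLOAT)
        self.running_var = np.ones(ch, dtype=_FLOAT)

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Tensor(_he_uniform(rng, (in_f, out_f), in_f), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=_FLOAT), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
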