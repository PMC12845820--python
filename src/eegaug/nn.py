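"""Neural-network layers and the AdamW optimizer on top of :mod:`eegaug.autodiff`.

Layers follow the batch-first convention used throughout the package:
signal tensors are ``[batch, channels, time]``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, conv_transpose1d, stack

__all__ = ["Parameter", "Module", "Linear", "Conv1d", "ConvTranspose1d", "GRU", "AdamW"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery by attribute walk, train/eval flag."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            obj = stack_.pop()
            for v in vars(obj).values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, Module):
                    stack_.append(v)
                elif isinstance(v, (list, tuple)):
                    stack_.extend(m for m in v if isinstance(m, Module))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def _set_training(self, flag: bool) -> None:
        self.training = flag
        for v in vars(self).values():
            if isinstance(v, Module):
                v._set_training(flag)
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        m._set_training(flag)

    def train(self) -> "Module":
        self._set_training(True)
        return self

    def eval(self) -> "Module":
        self._set_training(False)
        return self

    # lightweight checkpointing -----------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state dict length mismatch")
        for p, arr in zip(params, state):
            p.data = np.array(arr, dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Parameter(_glorot(rng, (in_features, out_features),
                                        in_features, out_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 zero_init: bool = False):
        fan_in = in_channels * kernel_size
        w = (np.zeros((out_channels, in_channels, kernel_size)) if zero_init
             else _glorot(rng, (out_channels, in_channels, kernel_size),
                          fan_in, out_channels * kernel_size))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_glorot(rng, (in_channels, out_channels, kernel_size),
                                        fan_in, out_channels * kernel_size))
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose1d(x, self.weight, self.bias, self.stride, self.padding)


class GRU(Module):
    """Single-layer unidirectional gated recurrent unit, input [B, T, F]."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        H = hidden_size
        self.hidden_size = H
        self.w_ih = Parameter(_glorot(rng, (input_size, 3 * H), input_size, H))
        self.w_hh = Parameter(_glorot(rng, (H, 3 * H), H, H))
        self.b_ih = Parameter(np.zeros(3 * H))
        self.b_hh = Parameter(np.zeros(3 * H))

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden_size
        h = Tensor(np.zeros((B, H)))
        gi_all = x @ self.w_ih + self.b_ih  # [B, T, 3H]
        outs = []
        for t in range(T):
            gi = gi_all[:, t, :]
            gh = h @ self.w_hh + self.b_hh
            r = (gi[:, :H] + gh[:, :H]).sigmoid()
            z = (gi[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
            n = (gi[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h)
        return stack(outs, axis=1)  # [B, T, H]


class AdamW:
    """Decoupled weight-decay Adam (the optimizer used for all training runs)."""

    def __init__(self, params: list[Parameter], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
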