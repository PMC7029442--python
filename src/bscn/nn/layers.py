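"""Parameterised layers and the SGD optimiser for the NumPy engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "SGD"]


class Module:
    """Base class: recursive parameter discovery by attribute walk."""

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Tensor):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Tensor):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: np.array(p.data, copy=True) for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        mismatches = []
        for name, p in self.named_parameters():
            if name not in state:
                mismatches.append(f"missing: {name}")
                continue
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                mismatches.append(
                    f"shape mismatch: {name} expected {p.data.shape}, got {arr.shape}"
                )
                continue
            p.data = arr.astype(p.data.dtype)
        if mismatches:
            raise ValueError("state load failed: " + "; ".join(mismatches))


class Conv2d(Module):
    """Same-padding convolution with He-normal init (odd square kernel)."""

    def __init__(self, in_ch, out_ch, kernel=3, dilation=1, rng=None,
                 gain=2.0, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(gain / fan_in)
        self.weight = Tensor(
            rng.standard_normal((out_ch, in_ch, kernel, kernel)).astype(dtype) * std,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.dilation = dilation

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class SGD:
    """Stochastic gradient descent with momentum and decoupled-from-nothing
    classic L2 weight decay (decay added to the raw gradient)."""

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state(self):
        return [np.array(v, copy=True) for v in self.velocity]

    def load_state(self, vel):
        if len(vel) != len(self.velocity):
            raise ValueError("optimiser state length mismatch")
        self.velocity = [np.asarray(v).copy() for v in vel]
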