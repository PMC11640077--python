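"""Parameterized layers over the autograd engine.

Weight layout is NHWC-friendly: convolution kernels are stored as
``(kh, kw, c_in, c_out)``.  Initialization is He-normal scaled by fan-in,
drawn from an explicitly passed generator so a fit is reproducible from its
seed alone.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Conv2d", "BatchNorm2d", "ConvBNRelu", "Adam"]


class Conv2d:
    """Same-padded convolution; ``kernel=1`` gives a pointwise convolution."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 1, stride: int = 1,
                 rng: np.random.Generator | None = None,
                 bias_init: float = 0.0) -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * c_in
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, size=(kernel, kernel, c_in, c_out)),
                        requires_grad=True)
        self.b = Tensor(np.full(c_out, bias_init, dtype=np.float32),
                        requires_grad=True)
        self.stride = stride
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, stride=self.stride)

    def params(self) -> list[Tensor]:
        return [self.w, self.b]

    @property
    def n_params(self) -> int:
        """Trainable scalar count: kh*kw*c_in*c_out + c_out."""
        return self.w.data.size + self.b.data.size


class BatchNorm2d:
    def __init__(self, channels: int) -> None:
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.state = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ag.batchnorm2d(x, self.gamma, self.beta, self.state, training)

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class ConvBNRelu:
    """Conv -> BatchNorm -> ReLU, the default block inside the decoder."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None,
                 batch_norm: bool = True) -> None:
        self.conv = Conv2d(c_in, c_out, kernel, stride, rng)
        self.bn = BatchNorm2d(c_out) if batch_norm else None

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        out = self.conv(x)
        if self.bn is not None:
            out = self.bn(out, training)
        return ag.relu(out)

    def params(self) -> list[Tensor]:
        out = self.conv.params()
        if self.bn is not None:
            out += self.bn.params()
        return out


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
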