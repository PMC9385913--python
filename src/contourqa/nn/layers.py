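"""Layer modules composing the autodiff ops into reusable blocks.

Every module takes an explicit ``numpy.random.Generator`` for weight
initialization, so two builds from the same seed have identical parameters.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from contourqa.nn import autograd as ag
from contourqa.nn.autograd import Parameter, Tensor


def _walk(value, kind):
    """Yield every instance of ``kind`` in a value, descending nested lists."""
    if isinstance(value, kind):
        yield value
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _walk(item, kind)


class Module:
    """Minimal container: tracks sub-modules/parameters, training mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            for mod in _walk(v, Module):
                yield mod
                yield from mod.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for mod in [self, *self.modules()]:
            for v in mod.__dict__.values():
                for p in _walk(v, Parameter):
                    if id(p) not in seen:
                        seen.add(id(p))
                        params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for mod in [self, *self.modules()]:
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv1x1(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.w = Parameter(_he_init(rng, (cout, cin), cin))
        self.b = Parameter(np.zeros(cout, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv1x1(x, self.w, self.b)


class Conv3x3(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: tuple[int, int, int] = (1, 1, 1), bias: bool = True):
        super().__init__()
        self.stride = stride
        self.w = Parameter(_he_init(rng, (cout, cin, 3, 3, 3), cin * 27))
        self.b = Parameter(np.zeros(cout, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv3x3(x, self.w, self.b, self.stride)


class DepthwiseConv3x3(Module):
    def __init__(self, channels: int, rng: np.random.Generator,
                 stride: tuple[int, int, int] = (1, 1, 1), bias: bool = False):
        super().__init__()
        self.stride = stride
        self.w = Parameter(_he_init(rng, (channels, 3, 3, 3), 27))
        self.b = Parameter(np.zeros(channels, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.dwconv3x3(x, self.w, self.b, self.stride)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float64)
        self.running_var = np.ones(channels, np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.alpha = Parameter(np.full(channels, init, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ag.prelu(x, self.alpha)


class MBConv(Module):
    """Inverted-bottleneck block: expand 1x1 → depthwise 3x3x3 → project 1x1.

    BatchNorm after each convolution, SiLU after expand and depthwise; a
    residual connection when stride is 1 and the channel count is kept.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 expansion: int = 2, stride: tuple[int, int, int] = (1, 1, 1)):
        super().__init__()
        mid = cin * expansion
        self.expand = Conv1x1(cin, mid, rng, bias=False)
        self.bn1 = BatchNorm3d(mid)
        self.dw = DepthwiseConv3x3(mid, rng, stride=stride)
        self.bn2 = BatchNorm3d(mid)
        self.project = Conv1x1(mid, cout, rng, bias=False)
        self.bn3 = BatchNorm3d(cout)
        self.residual = stride == (1, 1, 1) and cin == cout

    def forward(self, x: Tensor) -> Tensor:
        h = ag.silu(self.bn1(self.expand(x)))
        h = ag.silu(self.bn2(self.dw(h)))
        h = self.bn3(self.project(h))
        if self.residual:
            h = ag.add(h, x)
        return h


class SeparableConvBlock(Module):
    """Depthwise + pointwise convolution with BatchNorm and SiLU."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.dw = DepthwiseConv3x3(channels, rng)
        self.pw = Conv1x1(channels, channels, rng, bias=False)
        self.bn = BatchNorm3d(channels)

    def forward(self, x: Tensor) -> Tensor:
        return ag.silu(self.bn(self.pw(self.dw(x))))


class FastNormalizedFusion(Module):
    """Learnable-weight feature fusion Σ wᵢIᵢ / (ε + Σ wᵢ), wᵢ = max(0, raw)."""

    def __init__(self, n_inputs: int, epsilon: float = 1e-4):
        super().__init__()
        self.weights = Parameter(np.ones(n_inputs, np.float32))
        self.epsilon = epsilon

    def forward(self, inputs: Sequence[Tensor]) -> Tensor:
        return ag.fast_normalized_fusion(list(inputs), self.weights, self.epsilon)
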