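"""Layers and an Adam optimizer built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv3d, depthwise_conv3d

__all__ = [
    "Module", "Dense", "Conv3d", "DepthwiseConv3d", "SqueezeExcite",
    "MBConv3d", "Dropout", "Adam",
]


class Module:
    """Base class; subclasses register parameter Tensors via _param()."""

    def __init__(self):
        self._params: list[Tensor] = []
        self._children: list["Module"] = []
        self.training = True

    def _param(self, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self._params.append(t)
        return t

    def _child(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def train(self) -> None:
        self.training = True
        for c in self._children:
            c.train()

    def eval(self) -> None:
        self.training = False
        for c in self._children:
            c.eval()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = self._param(_he_init(rng, (n_in, n_out), n_in))
        self.b = self._param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = c_in * kernel ** 3
        self.w = self._param(_he_init(rng, (c_out, c_in, kernel, kernel, kernel), fan_in))
        self.b = self._param(np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class DepthwiseConv3d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        super().__init__()
        self.w = self._param(_he_init(rng, (channels, kernel, kernel, kernel), kernel ** 3))
        self.b = self._param(np.zeros(channels))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv3d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class SqueezeExcite(Module):
    """Channel attention: global average pool -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = self._child(Dense(channels, hidden, rng))
        self.fc2 = self._child(Dense(hidden, channels, rng))

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        pooled = x.mean(axis=(2, 3, 4))  # (N, C)
        gate = self.fc2(self.fc1(pooled).swish()).sigmoid()
        return x * gate.reshape(n, c, 1, 1, 1)


class MBConv3d(Module):
    """Mobile inverted bottleneck: expand -> depthwise -> SE -> project.

    Residual connection when stride is 1 and channel counts match.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 expand: int = 2, kernel: int = 3, stride: int = 1,
                 se_reduction: int = 4):
        super().__init__()
        c_mid = c_in * expand
        self.expand = self._child(Conv3d(c_in, c_mid, 1, rng)) if expand != 1 else None
        self.dw = self._child(DepthwiseConv3d(c_mid, kernel, rng,
                                              stride=stride, padding=kernel // 2))
        self.se = self._child(SqueezeExcite(c_mid, se_reduction, rng))
        self.project = self._child(Conv3d(c_mid, c_out, 1, rng))
        self.use_residual = stride == 1 and c_in == c_out

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        if self.expand is not None:
            h = self.expand(h).swish()
        h = self.dw(h).swish()
        h = self.se(h)
        h = self.project(h)
        if self.use_residual:
            h = h + x
        return h


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.random(x.shape) < keep
        return x * (mask / keep)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
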