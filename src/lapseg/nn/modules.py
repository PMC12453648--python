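"""Layer abstractions over the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor, conv2d, reflect_pad2d


class Module:
    """Base class: parameter discovery, state dicts, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def _local_tensors(self):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor):
                yield name, v

    def parameters(self) -> list[Tensor]:
        out = []
        for m in self.modules():
            for _, t in m._local_tensors():
                if t.requires_grad:
                    out.append(t)
        return out

    def named_state(self, prefix: str = ""):
        """All tensors (parameters and buffers), with stable names."""
        for name, t in self._local_tensors():
            yield prefix + name, t
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_state(prefix + name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_state(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict:
        return {k: t.data.copy() for k, t in self.named_state()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_state())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, t in own.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = np.asarray(state[k], dtype=DTYPE).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)


class Conv2d(Module):
    """Same-padding 2-D convolution with He-normal initialisation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, pad_mode: str = "zeros"):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.kernel = kernel
        self.stride = stride
        self.pad = (kernel - 1) // 2
        self.pad_mode = pad_mode

    def __call__(self, x: Tensor) -> Tensor:
        if self.pad_mode == "reflect" and self.pad:
            x = reflect_pad2d(x, self.pad)
            return conv2d(x, self.weight, self.bias, stride=self.stride, pad=0)
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, std, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Per-channel normalisation over (N, H, W) with running statistics."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones((1, ch, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, ch, 1, 1)), requires_grad=True)
        self.running_mean = Tensor(np.zeros((1, ch, 1, 1)))
        self.running_var = Tensor(np.ones((1, ch, 1, 1)))
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            d = x - mu
            var = (d * d).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean.data = (1 - m) * self.running_mean.data + m * mu.data
            self.running_var.data = (1 - m) * self.running_var.data + m * var.data
            xh = d * ((var + self.eps) ** -0.5)
        else:
            xh = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return self.gamma * xh + self.beta


class ConvBlock(Module):
    """Conv -> BatchNorm -> SiLU."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class ResidualBlock(Module):
    """Two conv blocks with an additive skip; the skip is toggleable so the
    contribution of residual connections can be ablated."""

    def __init__(self, ch: int, rng=None, residual: bool = True):
        super().__init__()
        self.c1 = ConvBlock(ch, ch, rng=rng)
        self.conv2 = Conv2d(ch, ch, 3, rng=rng)
        self.bn2 = BatchNorm2d(ch)
        self.residual = residual

    def __call__(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(self.c1(x)))
        if self.residual:
            y = y + x
        return y.silu()
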