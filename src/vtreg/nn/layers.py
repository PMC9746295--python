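"""Network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBlock"]


class Module:
    """Base class: parameter discovery, train/eval mode, (de)serialisation."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self):
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i}"] = p.data.copy()
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"bn{j}_mean"] = m.running_mean.copy()
                state[f"bn{j}_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"p{i}"]).astype(p.data.dtype)
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"bn{j}_mean"]).astype(m.running_mean.dtype)
                m.running_var = np.asarray(state[f"bn{j}_var"]).astype(m.running_var.dtype)

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.load_state_dict(dict(data))


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, init_scale: float | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.pad = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c).astype(np.float32)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c).astype(np.float32)
            xhat = (x - mu) * (var + self.eps).pow(-0.5)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            var = self.running_var.reshape(1, c, 1, 1)
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ConvBlock(Module):
    """conv -> batch norm -> ReLU (batch norm optional)."""

    def __init__(self, in_ch, out_ch, stride=1, batch_norm=True, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, stride=stride, rng=rng)
        self.bn = BatchNorm2d(out_ch) if batch_norm else None

    def __call__(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return x.relu()
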