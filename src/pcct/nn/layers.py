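"""Neural-network building blocks on the autodiff engine.

Convolutions are im2col gathers followed by a matmul; transposed
convolutions zero-upsample with a scatter and then convolve.  All layers are
plain Python objects holding `Tensor` parameters; modules collect parameters
recursively.
"""
from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack = list(self.__dict__.values())
        while stack:
            obj = stack.pop()
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                stack.extend(obj.__dict__.values())
            elif isinstance(obj, (list, tuple)):
                stack.extend(obj)
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match module parameters")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)).astype(np.float32)


_IM2COL_CACHE: dict[tuple, tuple[np.ndarray, tuple[int, int]]] = {}


def _im2col_indices(c: int, h: int, w: int, k: int, stride: int, pad: int):
    """Flat gather indices (with a trailing zero sentinel) for im2col.

    Returns (idx of shape (OH*OW*C*K*K,), (OH, OW)); out-of-bounds taps map
    to index c*h*w, the appended zero column.
    """
    key = (c, h, w, k, stride, pad)
    cached = _IM2COL_CACHE.get(key)
    if cached is not None:
        return cached
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    ys = np.arange(oh) * stride - pad
    xs = np.arange(ow) * stride - pad
    ky, kx = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    # (OH, OW, C, K, K)
    yy = ys[:, None, None, None, None] + ky[None, None, None]
    xx = xs[None, :, None, None, None] + kx[None, None, None]
    cc = np.arange(c)[None, None, :, None, None]
    inside = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    flat = cc * (h * w) + np.clip(yy, 0, h - 1) * w + np.clip(xx, 0, w - 1)
    sentinel = c * h * w
    idx = np.where(np.broadcast_to(inside, flat.shape), flat, sentinel)
    idx = np.ascontiguousarray(
        np.broadcast_to(idx, (oh, ow, c, k, k)).reshape(-1).astype(np.int64)
    )
    result = (idx, (oh, ow))
    _IM2COL_CACHE[key] = result
    return result


class Conv2d(Module):
    """3x3-style convolution; padding defaults to `same` for stride 1."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=None, rng=None, zero_init=False):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel * kernel
        weight = np.zeros((fan_in, c_out), np.float32) if zero_init else _he_init(
            rng, (fan_in, c_out), fan_in
        )
        self.weight = Tensor(weight, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        idx, (oh, ow) = _im2col_indices(c, h, w, self.kernel, self.stride, self.pad)
        flat = ag.reshape(x, (b, c * h * w))
        flat = ag.concat([flat, Tensor(np.zeros((b, 1), x.data.dtype))], axis=1)
        cols = ag.gather_cols(flat, idx)  # (B, OH*OW*C*K*K)
        # 2-D matmul so BLAS sees one big GEMM instead of a batched loop
        cols = ag.reshape(cols, (b * oh * ow, c * self.kernel * self.kernel))
        y = ag.matmul(cols, self.weight) + self.bias  # (B*OH*OW, C_out)
        y = ag.transpose(ag.reshape(y, (b, oh * ow, self.c_out)), (0, 2, 1))
        return ag.reshape(y, (b, self.c_out, oh, ow))


class ConvTranspose2d(Module):
    """Stride-2 upsampling: zero insertion followed by a same convolution."""

    def __init__(self, c_in, c_out, kernel=3, rng=None):
        self.conv = Conv2d(c_in, c_out, kernel=kernel, stride=1, rng=rng)
        self.c_in = c_in
        self._dest_cache: dict[tuple, np.ndarray] = {}

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        dest = self._dest_cache.get((c, h, w))
        if dest is None:
            src = np.arange(c * h * w)
            ci, yi, xi = src // (h * w), (src // w) % h, src % w
            dest = ci * (4 * h * w) + (2 * yi) * (2 * w) + 2 * xi
            self._dest_cache[(c, h, w)] = dest
        flat = ag.reshape(x, (b, c * h * w))
        up = ag.scatter_cols(flat, dest, c * 4 * h * w)
        up = ag.reshape(up, (b, c, 2 * h, 2 * w))
        return self.conv(up)


class Dense(Module):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_he_init(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


class BatchNorm2d(Module):
    """Per-channel normalization over (batch, H, W) with running statistics."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        self.gamma = Tensor(np.ones((1, channels, 1, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), np.float32), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, channels, 1, 1), np.float32)
        self.running_var = np.ones((1, channels, 1, 1), np.float32)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = ag.mean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = ag.mean(xc * xc, axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            mu = Tensor(self.running_mean)
            xc = x - mu
            var = Tensor(self.running_var)
        inv = ag.power(var + self.eps, -0.5)
        return self.gamma * (xc * inv) + self.beta


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.gamma = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = ag.mean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = ag.mean(xc * xc, axis=-1, keepdims=True)
        return self.gamma * (xc * ag.power(var + self.eps, -0.5)) + self.beta


def set_training(module: Module, training: bool) -> None:
    stack = [module]
    while stack:
        obj = stack.pop()
        if isinstance(obj, Module):
            if hasattr(obj, "training"):
                obj.training = training
            stack.extend(obj.__dict__.values())
        elif isinstance(obj, (list, tuple)):
            stack.extend(obj)


class Adam:
    """Adam with the conventional bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
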