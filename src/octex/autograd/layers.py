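"""Neural-network layers built on the :class:`~octex.autograd.tensor.Tensor` tape.

Convolution uses an im2col/col2im formulation so both directions reduce to
BLAS matrix products; this is what keeps a CPU-only training run of the
shallow test-profile backbone in the minutes range.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "MaxPool2d",
    "ReLU",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Tiny container protocol: tracks sub-modules and parameters by attribute."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    yield v

    def named_state(self):
        """Flat name -> ndarray map of parameters and buffers (for checkpoints)."""
        out = {}

        def visit(mod, prefix):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return out

    def load_state(self, state: dict) -> None:
        target = self.named_state()
        missing = set(target) - set(state)
        if missing:
            raise ValueError(f"checkpoint missing arrays: {sorted(missing)[:5]} ...")

        def visit(mod, prefix):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter) or isinstance(v, np.ndarray):
                    arr = np.asarray(state[key])
                    if arr.shape != (v.data.shape if isinstance(v, Parameter) else v.shape):
                        raise ValueError(f"shape mismatch for {key}")
                    if isinstance(v, Parameter):
                        v.data = arr.astype(np.float32)
                    else:
                        setattr(mod, name, arr.astype(v.dtype))
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    view = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (B, C, Ho, Wo, kh, kw) -> (B, Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(b, ho * wo, c * kh * kw)
    return cols, ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int, ho: int, wo: int):
    b, c, h, w = x_shape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(b, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[:, :, i, j]
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (kernel // 2) if pad is None else pad
        self.kernel = kernel
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for rectified nets
        self.weight = Parameter(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        kh = kw = self.kernel
        stride, pad = self.stride, self.pad
        cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
        bsz, n_out = x.shape[0], w.data.shape[0]
        wm = w.data.reshape(n_out, -1)
        cols2 = cols.reshape(bsz * ho * wo, -1)  # flatten: one big GEMM
        out = cols2 @ wm.T  # (B*L, O)
        if b is not None:
            out += b.data
        out_data = np.ascontiguousarray(
            out.reshape(bsz, ho * wo, n_out).transpose(0, 2, 1)
        ).reshape(bsz, n_out, ho, wo)
        x_shape = x.shape
        rq = x.requires_grad or w.requires_grad

        def backward(g):
            g2 = np.ascontiguousarray(
                g.reshape(bsz, n_out, ho * wo).transpose(0, 2, 1)
            ).reshape(bsz * ho * wo, n_out)
            if w.requires_grad:
                w._accum((g2.T @ cols2).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g2.sum(axis=0))
            if x.requires_grad:
                dcols = g2 @ wm  # (B*L, CKK)
                x._accum(_col2im(dcols, x_shape, kh, kw, stride, pad, ho, wo))

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(out_data, parents, backward, rq)


class MaxPool2d(Module):
    """Non-overlapping 2x2 max pooling (kernel == stride == 2)."""

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        r = x.data.reshape(b, c, h // 2, 2, w // 2, 2)
        out_data = r.max(axis=(3, 5))

        def backward(g):
            if not x.requires_grad:
                return
            mask = (r == out_data[:, :, :, None, :, None])
            ties = mask.sum(axis=(3, 5), keepdims=True)
            dx = mask / ties * g[:, :, :, None, :, None]
            x._accum(dx.reshape(b, c, h, w))

        return Tensor._make(out_data, (x,), backward, x.requires_grad)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            xc = x.data - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            self.running_mean += self.momentum * (mu.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.reshape(-1) - self.running_var)
            inv_sd = 1.0 / np.sqrt(var + self.eps)
            xhat = xc * inv_sd
            out_data = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)
            m = float(x.data.size // x.data.shape[1])

            def backward(g):
                if gamma.requires_grad:
                    gamma._accum((g * xhat).sum(axis=axes))
                if beta.requires_grad:
                    beta._accum(g.sum(axis=axes))
                if x.requires_grad:
                    dxh = g * gamma.data.reshape(1, -1, 1, 1)
                    # closed-form through the batch statistics
                    t1 = dxh.sum(axis=axes, keepdims=True) / m
                    t2 = (dxh * xhat).sum(axis=axes, keepdims=True) / m
                    x._accum(inv_sd * (dxh - t1 - xhat * t2))

            return Tensor._make(out_data, (x, gamma, beta), backward,
                                x.requires_grad or gamma.requires_grad or beta.requires_grad)
        # eval: affine transform with frozen statistics
        inv_sd = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, -1, 1, 1)
        mu = self.running_mean.reshape(1, -1, 1, 1)
        scale = gamma.reshape(1, -1, 1, 1) * Tensor(inv_sd.astype(np.float32))
        return (x - Tensor(mu.astype(np.float32))) * scale + beta.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / in_f)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(out_f, in_f)))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
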