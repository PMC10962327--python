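"""Minimal reverse-mode autodiff and 3D network layers on numpy.

This is the computational backend for the adaptive U-Net: a small define-by-
run tape (``Tensor``) with exactly the operations the model needs —
3D convolution (odd kernels, same padding, stride 1), 2x2x2 transposed
convolution for upsampling, 2x2x2 max pooling, batch normalization, ELU,
linear layers, channel concatenation, the k-space dipole forward model as a
differentiable linear operator, and mean-square reductions — plus AdamW and
a cosine-annealing learning-rate schedule with warm restarts.

Convolutions are evaluated by slab-chunked im2col + BLAS matmul; the input
gradient reuses the forward path with a spatially flipped, channel-swapped
kernel, and the weight gradient re-runs im2col on the saved input, so peak
memory stays bounded on large volumes.  All gradients are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# Tape


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t is not self and not t.requires_grad and t._parents == ():
                t.grad = None  # leaves that don't need grads

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # small operator sugar used by the layers
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward, track: bool) -> Tensor:
    out = Tensor(data)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = False
    return out


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Elementwise and reduction ops


def add(a: Tensor, b: Tensor) -> Tensor:
    track = _needs(a, b)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward, track)


def sub(a: Tensor, b: Tensor) -> Tensor:
    track = _needs(a, b)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))

    return _make(a.data - b.data, (a, b), backward, track)


def mul(a: Tensor, b) -> Tensor:
    if not isinstance(b, Tensor):  # scalar
        s = float(b)
        track = _needs(a)

        def backward_s(g):
            a._accumulate(s * g)

        return _make(a.data * s, (a,), backward_s, track)
    track = _needs(a, b)

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward, track)


def mean_sq(a: Tensor) -> Tensor:
    """mean(a**2) as a scalar tensor."""
    track = _needs(a)
    n = a.data.size

    def backward(g):
        a._accumulate((2.0 / n) * float(g) * a.data)

    return _make(np.asarray(np.mean(a.data**2)), (a,), backward, track)


def sum_sq(a: Tensor) -> Tensor:
    """sum(a**2) as a scalar tensor (unnormalized L2-norm-squared mode)."""
    track = _needs(a)

    def backward(g):
        a._accumulate(2.0 * float(g) * a.data)

    return _make(np.asarray(np.sum(a.data**2)), (a,), backward, track)


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    track = _needs(a)
    pos = a.data > 0
    out = np.where(pos, a.data, alpha * np.expm1(a.data))

    def backward(g):
        a._accumulate(g * np.where(pos, 1.0, out + alpha))

    return _make(out, (a,), backward, track)


def reshape(a: Tensor, shape: Sequence[int]) -> Tensor:
    track = _needs(a)
    old = a.data.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward, track)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    track = any(_needs(t) for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, s0, s1 in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(s0, s1)
            t._accumulate(g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward, track)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2D matrix product (used by the linear layers)."""
    track = _needs(a, b)

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward, track)


# ---------------------------------------------------------------------------
# 3D convolution (odd kernel, same padding, stride 1)

_CHUNK_ELEMS = 1 << 22  # ~4M scratch elements per im2col slab


def _conv3d_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    B, C, D, H, W = x.shape
    O, C2, k, _, _ = w.shape
    assert C == C2, (C, C2)
    p = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # (B,C,D,H,W,k,k,k)
    Wm = w.reshape(O, C * k**3)
    out = np.empty((B, O, D, H, W), dtype=np.result_type(x, w))
    slab = max(1, _CHUNK_ELEMS // max(1, C * k**3 * H * W))
    for b in range(B):
        for d0 in range(0, D, slab):
            d1 = min(D, d0 + slab)
            cols = v[b, :, d0:d1].transpose(1, 2, 3, 0, 4, 5, 6).reshape(-1, C * k**3)
            out[b, :, d0:d1] = (
                (cols @ Wm.T).reshape(d1 - d0, H, W, O).transpose(3, 0, 1, 2)
            )
    return out


def _conv3d_grad_w(x: np.ndarray, gout: np.ndarray, k: int) -> np.ndarray:
    B, C, D, H, W = x.shape
    O = gout.shape[1]
    p = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    gW = np.zeros((O, C * k**3), dtype=np.result_type(x, gout))
    slab = max(1, _CHUNK_ELEMS // max(1, C * k**3 * H * W))
    for b in range(B):
        for d0 in range(0, D, slab):
            d1 = min(D, d0 + slab)
            cols = v[b, :, d0:d1].transpose(1, 2, 3, 0, 4, 5, 6).reshape(-1, C * k**3)
            gslab = gout[b, :, d0:d1].reshape(O, -1)
            gW += gslab @ cols
    return gW.reshape(O, C, k, k, k)


def conv3d(x: Tensor, w: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    """Same-padding stride-1 3D convolution (cross-correlation), odd kernel.

    ``x``: (B, C, D, H, W); ``w``: (O, C, k, k, k); ``bias``: (O,).
    """
    k = w.data.shape[2]
    if k % 2 != 1:
        raise ValueError("conv3d supports odd kernels only")
    out = _conv3d_raw(x.data, w.data)
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if bias is None else (x, w, bias)
    track = _needs(*parents)

    def backward(g):
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        w._accumulate(_conv3d_grad_w(x.data, g, k))
        wT = np.flip(w.data, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4)
        x._accumulate(_conv3d_raw(g, np.ascontiguousarray(wT)))

    return _make(out, parents, backward, track)


def conv_transpose3d(x: Tensor, w: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    """2x2x2 transposed convolution with stride 2 (doubles each spatial dim).

    ``x``: (B, C, D, H, W); ``w``: (C, O, 2, 2, 2).  Kernel 2 / stride 2
    tiles the output without overlap.
    """
    B, C, D, H, W = x.shape
    C2, O = w.data.shape[:2]
    assert C == C2
    out8 = np.einsum("bcdhw,coijl->bodihjwl", x.data, w.data, optimize=True)
    out = out8.reshape(B, O, 2 * D, 2 * H, 2 * W)
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if bias is None else (x, w, bias)
    track = _needs(*parents)

    def backward(g):
        g8 = g.reshape(B, O, D, 2, H, 2, W, 2)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        w._accumulate(np.einsum("bodihjwl,bcdhw->coijl", g8, x.data, optimize=True))
        x._accumulate(np.einsum("bodihjwl,coijl->bcdhw", g8, w.data, optimize=True))

    return _make(out, parents, backward, track)


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; spatial dims must be even."""
    B, C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool3d needs even spatial dims, got {(D, H, W)}")
    r = (
        x.data.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(B, C, D // 2, H // 2, W // 2, 8)
    )
    idx = np.argmax(r, axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    track = _needs(x)

    def backward(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(B, C, D, H, W)
        )
        x._accumulate(gx)

    return _make(out, (x,), backward, track)


def dipole_convolve(chi: Tensor, kernel: np.ndarray) -> Tensor:
    """Differentiable k-space dipole forward model on (B, 1, D, H, W).

    The operator F^-1 diag(d) F is linear and self-adjoint for the real,
    even kernel d, so the backward pass applies the same operator to the
    incoming gradient.
    """
    spec = np.fft.fftn(chi.data, axes=(2, 3, 4))
    out = np.real(np.fft.ifftn(spec * kernel, axes=(2, 3, 4)))
    track = _needs(chi)

    def backward(g):
        gs = np.fft.fftn(g, axes=(2, 3, 4))
        chi._accumulate(np.real(np.fft.ifftn(gs * kernel, axes=(2, 3, 4))))

    return _make(out, (chi,), backward, track)


# ---------------------------------------------------------------------------
# Modules


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class with recursive parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterable[Tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def modules(self) -> Iterable["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def astype(self, dtype) -> "Module":
        """Cast all parameters and running buffers (e.g. float32 training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for _, buf in self.named_buffers():
            buf_cast = buf.astype(dtype)
            buf[...] = buf_cast
        return self

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterable[Tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        expected = set(params) | set(buffers)
        given = set(state)
        if expected != given:
            missing = expected - given
            extra = given - expected
            raise ValueError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for name, buf in buffers.items():
            buf[...] = state[name]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init_scale: Optional[float] = None):
        super().__init__()
        std = init_scale if init_scale is not None else math.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, transpose2d(self.weight))
        return add(y, self.bias)


def transpose2d(a: Tensor) -> Tensor:
    track = _needs(a)

    def backward(g):
        a._accumulate(g.T)

    return _make(a.data.T, (a,), backward, track)


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel_size: int = 3, zero_init: bool = False):
        super().__init__()
        fan_in = in_channels * kernel_size**3
        std = 0.0 if zero_init else math.sqrt(2.0 / fan_in)
        shape = (out_channels, in_channels, kernel_size, kernel_size, kernel_size)
        self.weight = Parameter(rng.normal(0.0, std, size=shape) if std else np.zeros(shape))
        self.bias = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * 8
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_channels, out_channels, 2, 2, 2)))
        self.bias = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        gamma, beta = self.weight, self.bias
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu = self.running_mean
            var = self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        bshape = (1, -1, 1, 1, 1)
        xhat = (x.data - mu.reshape(bshape)) * ivar.reshape(bshape)
        out = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)
        track = _needs(x, gamma, beta)
        training = self.training
        n = x.data.size // x.data.shape[1]

        def backward(g):
            beta._accumulate(g.sum(axis=axes))
            gamma._accumulate((g * xhat).sum(axis=axes))
            dxhat = g * gamma.data.reshape(bshape)
            if training:
                s1 = dxhat.sum(axis=axes, keepdims=True)
                s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                gx = (ivar.reshape(bshape) / n) * (n * dxhat - s1 - xhat * s2)
            else:
                gx = dxhat * ivar.reshape(bshape)
            x._accumulate(gx)

        return _make(out, (x, gamma, beta), backward, track)


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def __call__(self, x: Tensor) -> Tensor:
        return elu(x, self.alpha)


# ---------------------------------------------------------------------------
# Optimization


class AdamW:
    """AdamW with decoupled weight decay and per-group learning rates."""

    def __init__(
        self,
        param_groups,
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.99),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        if param_groups and isinstance(param_groups[0], Parameter):
            param_groups = [{"params": list(param_groups), "lr": lr}]
        self.groups = [dict(g) for g in param_groups]
        for g in self.groups:
            g.setdefault("lr", lr)
            g.setdefault("weight_decay", weight_decay)
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m: Dict[int, np.ndarray] = {}
        self._v: Dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for group in self.groups:
            lr = group["lr"]
            wd = group["weight_decay"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                if key not in self._m:
                    self._m[key] = np.zeros_like(p.data)
                    self._v[key] = np.zeros_like(p.data)
                m = self._m[key]
                v = self._v[key]
                m += (1 - b1) * (p.grad - m)
                v += (1 - b2) * (p.grad**2 - v)
                mhat = m / bc1
                vhat = v / bc2
                p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + wd * p.data)


class CosineWarmRestarts:
    """Cosine annealing between eta_init and eta_min with warm restarts.

    Period sequence T_i = max(1, round(T0 * Tmult^i)); at each restart the
    rate jumps back to eta_init.  Fractional steps are supported so the rate
    can be queried mid-period.
    """

    def __init__(self, t0: float = 500, t_mult: float = 0.5,
                 eta_init: float = 1e-3, eta_min: float = 1e-8):
        if t0 <= 0 or t_mult <= 0:
            raise ValueError("schedule periods must be positive")
        self.t0 = float(t0)
        self.t_mult = float(t_mult)
        self.eta_init = eta_init
        self.eta_min = eta_min

    def lr(self, step: float) -> float:
        if step < 0:
            raise ValueError("step must be >= 0")
        t = float(step)
        period = max(1.0, round(self.t0))
        ti = self.t0
        while t >= period - 1e-12 and t > 0:
            if abs(t - period) < 1e-12:
                return self.eta_init  # restart boundary
            t -= period
            ti *= self.t_mult
            period = max(1.0, round(ti))
        frac = t / period
        return self.eta_min + 0.5 * (self.eta_init - self.eta_min) * (1 + math.cos(math.pi * frac))


def schedule_lr(step: float, schedule: CosineWarmRestarts) -> float:
    """Learning rate at ``step`` under the warm-restart cosine schedule."""
    return schedule.lr(step)
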