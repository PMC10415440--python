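"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the neural-network backend for the water-fat separation networks:
a taped ``Tensor`` with the handful of differentiable operations a 2-D
encoder-decoder CNN needs (3x3/1x1 convolution, 2x2 transposed convolution,
2x2 max pooling, batch normalisation, ReLU/sigmoid/softmax, batched matmul,
channel concatenation) plus layer classes, He-uniform initialisation and an
Adam optimiser.  All arithmetic is float32 and single-threaded-deterministic:
identical seeds give identical training trajectories.

Convolutions are lowered to im2col + GEMM so the heavy lifting stays inside
BLAS; the 2x2 stride-2 transposed convolution is an exact shape inverse of
2x2 max pooling, written as an einsum over non-overlapping output blocks.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np

#: Backend float dtype. float32 is the working precision; float64 is used by
#: the test suite for finite-difference gradient verification.
DTYPE = np.float32

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "softmax",
    "reshape",
    "transpose",
    "concat",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "masked_mae",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "SelfAttention2d",
    "Adam",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Reverse sweep from this (scalar or array) node, seeding with ones."""
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _make(out_data, parents, backward) -> Tensor:
    out = Tensor(out_data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(np.matmul(a.data, b.data), (a, b), backward)


def relu(x: Tensor) -> Tensor:
    pos = x.data > 0

    def backward(g):
        x._accumulate(g * pos)

    return _make(np.where(pos, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * y * (1.0 - y))

    return _make(y, (x,), backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis (rows sum to 1)."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        x._accumulate(y * (g - dot))

    return _make(y, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape

    def backward(g):
        x._accumulate(g.reshape(orig))

    return _make(x.data.reshape(shape), (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        x._accumulate(g.transpose(inv))

    return _make(x.data.transpose(axes), (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding stride-1 convolution, odd square kernel; NCHW layout."""
    B, C, H, W = x.data.shape
    Cout, Cin, k, _ = w.data.shape
    assert Cin == C and k % 2 == 1
    p = k // 2
    if k == 1:
        xp = x.data
        cols = x.data.reshape(B, C, H * W)
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        patches = np.empty((B, C, k, k, H, W), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                patches[:, :, i, j] = xp[:, :, i : i + H, j : j + W]
        cols = patches.reshape(B, C * k * k, H * W)
    w2 = w.data.reshape(Cout, C * k * k)
    out = np.matmul(w2, cols).reshape(B, Cout, H, W) + b.data[None, :, None, None]

    def backward(g):
        g2 = g.reshape(B, Cout, H * W)
        if w.requires_grad:
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw.reshape(w.data.shape))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)  # (B, C*k*k, H*W)
            if k == 1:
                x._accumulate(dcols.reshape(B, C, H, W))
            else:
                dpatch = dcols.reshape(B, C, k, k, H, W)
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i : i + H, j : j + W] += dpatch[:, :, i, j]
                x._accumulate(dxp[:, :, p : p + H, p : p + W])

    return _make(out, (x, w, b), backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transposed convolution, kernel 2, stride 2: exact 2x upsampling.

    Weight layout (Cin, Cout, 2, 2); output blocks do not overlap, so the
    operation is a per-pixel linear map into 2x2 output tiles.
    """
    B, C, H, W = x.data.shape
    Cin, Cout, _, _ = w.data.shape
    assert Cin == C
    out6 = np.einsum("bcij,cdpq->bdipjq", x.data, w.data, optimize=True)
    out = out6.reshape(B, Cout, 2 * H, 2 * W) + b.data[None, :, None, None]

    def backward(g):
        g6 = g.reshape(B, Cout, H, 2, W, 2)
        if w.requires_grad:
            w._accumulate(np.einsum("bcij,bdipjq->cdpq", x.data, g6, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(np.einsum("bdipjq,cdpq->bcij", g6, w.data, optimize=True))

    return _make(out, (x, w, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0
    # flatten each 2x2 window; ties (common after ReLU zeros) must route the
    # gradient to exactly one winner, so backward uses argmax, not equality
    xw = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xw = xw.reshape(B, C, H // 2, W // 2, 4)
    idx = xw.argmax(axis=-1)
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxw = np.zeros_like(xw)
        np.put_along_axis(dxw, idx[..., None], g[..., None], axis=-1)
        dx = dxw.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(B, C, H, W))

    return _make(out, (x,), backward)


def masked_mae(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean absolute error over in-mask pixels, averaged across channels.

    ``target`` is (B, C, H, W), ``mask`` (B, H, W) boolean; the mask applies
    to every channel.  An empty mask is a contract violation.
    """
    target = np.asarray(target, dtype=DTYPE)
    m = np.asarray(mask, bool)
    n_pix = int(m.sum())
    if n_pix == 0:
        raise ValueError("masked_mae: empty mask")
    C = pred.data.shape[1]
    mf = m[:, None, :, :].astype(DTYPE)
    diff = pred.data - target
    denom = DTYPE(n_pix * C)
    val = np.abs(diff * mf).sum() / denom

    def backward(g):
        pred._accumulate(g * np.sign(diff) * mf / denom)

    return _make(DTYPE(val), (pred,), backward)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Module:
    """Container with parameter discovery and train/eval mode propagation."""

    training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for mod in (self, *self.modules()):
            for v in mod.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def train(self, flag: bool = True):
        self.training = flag
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    #: names of non-trainable arrays (e.g. batch-norm running stats) that
    #: belong in checkpoints; subclasses override
    buffer_names: tuple[str, ...] = ()

    def _buffers(self):
        for mod in (self, *self.modules()):
            for name in mod.buffer_names:
                yield mod, name

    def state_dict(self) -> dict:
        """Flat name -> array mapping over parameters and buffers."""
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        for j, (mod, name) in enumerate(self._buffers()):
            state[f"b{j}"] = np.asarray(getattr(mod, name)).copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        buffers = list(self._buffers())
        if len(state) != len(params) + len(buffers):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters "
                f"+ {len(buffers)} buffers"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter p{i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr
        for j, (mod, name) in enumerate(buffers):
            setattr(mod, name, np.asarray(state[f"b{j}"], dtype=DTYPE))


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = math.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.weight = Parameter(
            _he_uniform(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel)
        )
        self.bias = Parameter(np.zeros(out_ch, DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 transposed convolution (2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.weight = Parameter(_he_uniform(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch, DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    buffer_names = ("running_mean", "running_var")

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_ch, DTYPE))
        self.beta = Parameter(np.zeros(n_ch, DTYPE))
        self.running_mean = np.zeros(n_ch, DTYPE)
        self.running_var = np.ones(n_ch, DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        use_batch_stats = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = gamma.data[None, :, None, None] * invstd[None, :, None, None]
                if use_batch_stats:
                    n = g.shape[0] * g.shape[2] * g.shape[3]
                    gsum = g.sum(axis=(0, 2, 3), keepdims=True)
                    gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    x._accumulate(gi * (g - gsum / n - xhat * gxsum / n))
                else:
                    x._accumulate(gi * g)

        return _make(out.astype(DTYPE), (x, gamma, beta), backward)


class SelfAttention2d(Module):
    """Spatial query-key-value self-attention with a learnable residual gate.

    1x1 convolutions produce queries/keys at ``n_ch // reduction`` channels
    and values at full width; attention weights are a row-softmax over all
    positions, and the output is ``x + gamma * attention(x)`` with gamma
    initialised to 0 (the block starts as the identity).
    """

    def __init__(self, n_ch: int, rng: np.random.Generator, reduction: int = 8):
        inner = max(n_ch // reduction, 1)
        self.query = Conv2d(n_ch, inner, 1, rng)
        self.key = Conv2d(n_ch, inner, 1, rng)
        self.value = Conv2d(n_ch, n_ch, 1, rng)
        self.gamma = Parameter(np.zeros(1, DTYPE))

    def attention_weights(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        q = reshape(self.query(x), (B, -1, H * W))  # (B, c, P)
        k = reshape(self.key(x), (B, -1, H * W))
        scale = 1.0 / math.sqrt(q.data.shape[1])
        logits = mul(matmul(transpose(q, (0, 2, 1)), k), scale)  # (B, P, P)
        return softmax(logits)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        att = self.attention_weights(x)  # (B, P, P), rows sum to 1
        v = reshape(self.value(x), (B, C, H * W))
        out = matmul(v, transpose(att, (0, 2, 1)))  # (B, C, P)
        out = reshape(out, (B, C, H, W))
        return add(x, mul(self.gamma, out))


class Adam:
    """Adam with per-step adjustable learning rate (for cosine schedules)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
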