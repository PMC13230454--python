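"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in this package is small enough (and CPU-bound enough) that a
compact tape-based engine is preferable to a heavyweight framework.  A
:class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` replays the tape in reverse topological order.
Only the operations the contour-regression network needs are implemented:
broadcast arithmetic, (batched) matmul, reshape/transpose/roll/slicing,
softmax, GELU, patch extraction for 3x3 convolution, and nearest 2x
upsampling.

All computation is deterministic for a fixed seed: numpy in a single
process applies identical floating-point reductions run-to-run.
"""

from __future__ import annotations

import numpy as np

#: dtype of all Tensor data; float32 keeps the activation tape compact.
#: Gradient-check tests switch to float64 via :func:`set_dtype`.
DEFAULT_DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DEFAULT_DTYPE
    DEFAULT_DTYPE = np.dtype(dtype).type


__all__ = [
    "Tensor",
    "set_dtype",
    "no_grad",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Conv2d",
    "Adam",
    "softmax",
    "gelu",
    "upsample2x",
    "trunc_normal",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` (result of a broadcast op) back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


_GRAD_ENABLED = True


class no_grad:
    """Context manager suspending tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_bw_fn", "_prev")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        data = np.asarray(data)
        if data.dtype != DEFAULT_DTYPE:
            data = data.astype(DEFAULT_DTYPE)
        self.data = data
        if not _GRAD_ENABLED:
            requires_grad, _prev = False, ()
        self.requires_grad = requires_grad
        self.grad = None
        self._bw_fn = None
        self._prev = _prev

    @property
    def _backward(self):
        return self._bw_fn

    @_backward.setter
    def _backward(self, fn):
        # without graph edges the closure would only pin memory
        self._bw_fn = fn if self._prev else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # ------------------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * (other ** -1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))
        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(np.matmul(self.data, other.data),
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_sum_to_shape(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_sum_to_shape(gb, other.data.shape))
        out._backward = _bw
        return out

    # ------------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))
        out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = _bw
        return out

    def roll(self, shifts, axes):
        out = Tensor(np.roll(self.data, shifts, axis=axes),
                     self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                back = tuple(-s for s in np.atleast_1d(shifts))
                self._accumulate(np.roll(g, back, axis=axes))
        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
        out._backward = _bw
        return out

    def pad_end(self, amounts) -> "Tensor":
        """Zero-pad the trailing side of the first len(amounts) axes."""
        widths = [(0, int(a)) for a in amounts]
        widths += [(0, 0)] * (self.ndim - len(widths))
        out = Tensor(np.pad(self.data, widths), self.requires_grad, (self,))
        sl = tuple(slice(0, n) for n in self.data.shape)

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g[sl])
        out._backward = _bw
        return out

    def crop_end(self, sizes) -> "Tensor":
        """Keep the leading ``sizes`` elements of the first axes."""
        sl = tuple(slice(0, int(n)) for n in sizes)
        out = Tensor(self.data[sl], self.requires_grad, (self,))
        shape = self.data.shape

        def _bw(g):
            if self.requires_grad:
                widths = [(0, shape[i] - g.shape[i]) for i in range(len(sizes))]
                widths += [(0, 0)] * (g.ndim - len(widths))
                self._accumulate(np.pad(g, widths))
        out._backward = _bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        shape = self.data.shape

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).copy())
                return
            axs = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axs)
            self._accumulate(np.broadcast_to(g, shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        # iterative topological sort to avoid recursion limits on deep graphs
        stack = [(self, iter(self._prev))]
        seen.add(id(self))
        while stack:
            node, it = stack[-1]
            advanced = False
            for child in it:
                if id(child) not in seen:
                    seen.add(id(child))
                    stack.append((child, iter(child._prev)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack.pop()

        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t._prev:  # free interior-node grads; leaves keep theirs
                t.grad = None


# ----------------------------------------------------------------------
# nonlinearities


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))
    out._backward = _bw
    return out


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x: Tensor) -> Tensor:
    """GELU with the tanh approximation (and its exact derivative)."""
    v = x.data
    inner = _GELU_C * (v + 0.044715 * v ** 3)
    t = np.tanh(inner)
    y = 0.5 * v * (1.0 + t)
    out = Tensor(y, x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            sech2 = 1.0 - t ** 2
            d = 0.5 * (1.0 + t) + 0.5 * v * sech2 * _GELU_C * (1.0 + 3 * 0.044715 * v ** 2)
            x._accumulate(g * d)
    out._backward = _bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the last two axes."""
    y = np.repeat(np.repeat(x.data, 2, axis=-2), 2, axis=-1)
    out = Tensor(y, x.requires_grad, (x,))
    sh = x.data.shape

    def _bw(g):
        if x.requires_grad:
            g = g.reshape(sh[:-2] + (sh[-2], 2, sh[-1], 2))
            x._accumulate(g.sum(axis=(-3, -1)))
    out._backward = _bw
    return out


def im2col3x3(x: Tensor) -> Tensor:
    """Extract padded 3x3 patches: (N, C, H, W) -> (N, H, W, C*9)."""
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, h, w, c, 9), dtype=x.data.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[..., k] = xp[:, :, di:di + h, dj:dj + w].transpose(0, 2, 3, 1)
            k += 1
    out = Tensor(cols.reshape(n, h, w, c * 9), x.requires_grad, (x,))

    def _bw(g):
        if not x.requires_grad:
            return
        g = g.reshape(n, h, w, c, 9)
        gp = np.zeros((n, c, h + 2, w + 2), dtype=g.dtype)
        k = 0
        for di in range(3):
            for dj in range(3):
                gp[:, :, di:di + h, dj:dj + w] += g[..., k].transpose(0, 3, 1, 2)
                k += 1
        x._accumulate(gp[:, :, 1:-1, 1:-1])
    out._backward = _bw
    return out


# ----------------------------------------------------------------------
# modules


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module container with recursive parameter discovery."""

    @staticmethod
    def _walk(name, v):
        if isinstance(v, Parameter):
            yield name, v
        elif isinstance(v, Module):
            yield from v.named_parameters(name + ".")
        elif isinstance(v, (list, tuple)):
            for i, item in enumerate(v):
                yield from Module._walk(f"{name}.{i}", item)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix=""):
        out = []
        for k, v in self.__dict__.items():
            out.extend(Module._walk(f"{prefix}{k}", v))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, sd):
        for k, v in self.named_parameters():
            v.data = np.asarray(sd[k], dtype=DEFAULT_DTYPE).reshape(v.data.shape)

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as f:
            self.load_state_dict({k: f[k] for k in f.files})

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) clipped at +/-2 std (weight initialisation)."""
    return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(trunc_normal(rng, (in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.weight + self.bias


class Conv2d(Module):
    """3x3 same-padding convolution, applied as im2col + matmul."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = in_ch * 9
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           (in_ch * 9, out_ch)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> (N, out, H, W)."""
        n, _, h, w = x.shape
        y = im2col3x3(x) @ self.weight + self.bias  # (N, H, W, out)
        return y.transpose(0, 3, 1, 2)


class Adam:
    """Adam with coupled (L2) weight decay."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay=1e-4):
        self.params = list(params)
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.eps, self.wd = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
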