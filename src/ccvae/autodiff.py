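"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set needed by the encoder/decoder networks and
the composite training objective: broadcasting arithmetic, matmul, elementwise
transcendentals, reductions, reshapes, gathers, strided 2-D convolution,
max-pooling and nearest-neighbour upsampling. All computation is float64.

A :class:`Tensor` records its parents and a backward closure; :meth:`Tensor.backward`
runs a topological sweep accumulating gradients into ``.grad`` of every tensor
with ``requires_grad``.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _parents=parents if req else (),
                      _backward=backward if req else None)

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        out_data = self.data ** p

        def bwd(g):
            return ((self, g * p * self.data ** (p - 1.0)),)

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            ga = g @ other.data.swapaxes(-1, -2)
            gb = self.data.swapaxes(-1, -2) @ g
            return ((self, _unbroadcast(ga, self.data.shape)),
                    (other, _unbroadcast(gb, other.data.shape)))

        return self._make(out_data, (self, other), bwd)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: ((self, g * out_data),))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: ((self, g / self.data),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,),
                          lambda g: ((self, g * mask),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,),
                          lambda g: ((self, g * out_data * (1.0 - out_data)),))

    # -- reductions & shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is None:
                return ((self, np.broadcast_to(g, self.data.shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return self._make(self.data.reshape(shape), (self,),
                          lambda g: ((self, g.reshape(old)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._make(self.data.transpose(axes), (self,),
                          lambda g: ((self, g.transpose(inv)),))

    @property
    def T(self):
        if self.data.ndim != 2:
            raise ValueError("T is defined for 2-D tensors")
        return self.transpose(1, 0)

    def gather_flat(self, indices):
        """Select elements of the flattened tensor at ``indices`` (1-D int array)."""
        idx = np.asarray(indices, dtype=np.intp)
        out_data = self.data.reshape(-1)[idx]

        def bwd(g):
            full = np.zeros(self.data.size)
            np.add.at(full, idx, g)
            return ((self, full.reshape(self.data.shape)),)

        return self._make(out_data, (self,), bwd)

    def take_rows(self, indices):
        """Row selection for a 2-D tensor (differentiable fancy indexing)."""
        idx = np.asarray(indices, dtype=np.intp)
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return self._make(out_data, (self,), bwd)

    # -- spatial ops (N, C, H, W) --------------------------------------------
    def pad2d(self, ph: int, pw: int):
        if ph == 0 and pw == 0:
            return self
        out_data = np.pad(self.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

        def bwd(g):
            return ((self, g[:, :, ph:g.shape[2] - ph, pw:g.shape[3] - pw]),)

        return self._make(out_data, (self,), bwd)

    def conv2d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution (cross-correlation). x:(N,C,H,W) w:(O,C,kh,kw)."""
        x = self.pad2d(padding, padding)
        xd, wd = x.data, weight.data
        N, C, H, W = xd.shape
        O, _, kh, kw = wd.shape
        sh = sw = int(stride)
        OH = (H - kh) // sh + 1
        OW = (W - kw) // sw + 1
        s = xd.strides
        cols = np.ascontiguousarray(np.lib.stride_tricks.as_strided(
            xd, (N, C, kh, kw, OH, OW),
            (s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw)))
        # (N,OH,OW,O)
        out = np.tensordot(cols, wd, axes=([1, 2, 3], [1, 2, 3]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        if bias is not None:
            out = out + bias.data.reshape(1, O, 1, 1)

        def bwd(g):
            # g: (N,O,OH,OW)
            gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))  # (O,C,kh,kw)
            gx = np.zeros_like(xd)
            tmp = np.tensordot(g, wd, axes=([1], [0]))  # (N,OH,OW,C,kh,kw)
            for u in range(kh):
                for v in range(kw):
                    gx[:, :, u:u + OH * sh:sh, v:v + OW * sw:sw] += \
                        tmp[:, :, :, :, u, v].transpose(0, 3, 1, 2)
            grads = [(x, gx), (weight, gw)]
            if bias is not None:
                grads.append((bias, g.sum(axis=(0, 2, 3))))
            return tuple(grads)

        parents = (x, weight) if bias is None else (x, weight, bias)
        return self._make(out, parents, bwd)

    def maxpool2d(self, kernel: int = 2, stride: int = None, padding: int = 0):
        stride = kernel if stride is None else stride
        if padding:
            # pad with -inf so padded values never win the max
            xd = np.pad(self.data, ((0, 0), (0, 0), (padding, padding),
                                    (padding, padding)),
                        constant_values=-np.inf)
        else:
            xd = self.data
        N, C, H, W = xd.shape
        k, st = int(kernel), int(stride)
        OH = (H - k) // st + 1
        OW = (W - k) // st + 1
        s = xd.strides
        cols = np.lib.stride_tricks.as_strided(
            xd, (N, C, k, k, OH, OW),
            (s[0], s[1], s[2], s[3], s[2] * st, s[3] * st))
        flat = cols.reshape(N, C, k * k, OH, OW)
        arg = flat.argmax(axis=2)
        out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

        def bwd(g):
            gx = np.zeros((N, C, H, W))
            for u in range(k):
                for v in range(k):
                    mask = arg == (u * k + v)
                    sub = gx[:, :, u:u + OH * st:st, v:v + OW * st:st]
                    sub += g * mask
            if padding:
                gx = gx[:, :, padding:H - padding, padding:W - padding]
            return ((self, gx),)

        return self._make(out, (self,), bwd)

    def upsample_nearest2d(self, scale: int = 2):
        k = int(scale)
        out_data = self.data.repeat(k, axis=2).repeat(k, axis=3)
        N, C, H, W = self.data.shape

        def bwd(g):
            return ((self, g.reshape(N, C, H, k, W, k).sum(axis=(3, 5))),)

        return self._make(out_data, (self,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    req = _GRAD_ENABLED[-1] and any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  _parents=tuple(tensors) if req else (),
                  _backward=bwd if req else None)
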