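"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations that produced
it; :meth:`Tensor.backward` runs the reverse sweep over the recorded graph.
The operation set is exactly what the image-translation networks in this
package need: broadcasting arithmetic, matmul, 2-D convolution via
im2col/col2im, nearest-neighbor upsampling, reductions, concatenation and the
usual pointwise nonlinearities.  Convolution kernels are applied with
symmetric zero padding and arbitrary stride.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]


class _NoGrad:
    _active = False

    def __enter__(self):
        self.prev = _NoGrad._active
        _NoGrad._active = True

    def __exit__(self, *exc):
        _NoGrad._active = self.prev


def no_grad():
    """Context manager disabling graph recording (inference mode)."""
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcasted gradient back to the original operand shape."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad and not _NoGrad._active
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        requires = any(p.requires_grad for p in parents) and not _NoGrad._active
        out = Tensor(data, requires_grad=requires)
        if requires:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        self.grad = g if self.grad is None else self.grad + g

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def pow(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    __pow__ = pow

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor"):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- pointwise nonlinearities -----------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * factor)

        return Tensor._make(self.data * factor, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500.0, 500.0)))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t**2))

        return Tensor._make(t, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only inside the open interval."""
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions and shape ops -----------------------------------------
    def mean(self, axis=None, keepdims: bool = False):
        out_data = self.data.mean(axis=axis, keepdims=keepdims)
        count = self.data.size / out_data.size

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape) / count)

        return Tensor._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def amax(self, axis, keepdims: bool = True):
        """Max along axes; gradient flows to (all) argmax positions."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # split ties evenly so the gradient magnitude is preserved
        norm = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask / norm * g)

        return Tensor._make(out_data if keepdims else out_data.squeeze(axis), (self,), backward)

    def reshape(self, *shape):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # -- image ops (NCHW) --------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1,
               padding: int = 0):
        """2-D convolution, NCHW input, OIHW weight, symmetric zero padding."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        O, Ci, kh, kw = w.shape
        if Ci != C:
            raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Ho = (H + 2 * padding - kh) // stride + 1
        Wo = (W + 2 * padding - kw) // stride + 1

        def im2col():
            # (N, C*kh*kw, Ho*Wo); the copy is transient — rebuilt in backward
            s = xp.strides
            cols = np.lib.stride_tricks.as_strided(
                xp,
                shape=(N, C, kh, kw, Ho, Wo),
                strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
                writeable=False,
            )
            return cols.reshape(N, C * kh * kw, Ho * Wo)

        wmat = w.reshape(O, C * kh * kw)
        out = (wmat @ im2col()).reshape(N, O, Ho, Wo)
        if bias is not None:
            out = out + bias.data.reshape(1, O, 1, 1)
        parents = (self, weight) + ((bias,) if bias is not None else ())

        def backward(g):
            gmat = g.reshape(N, O, Ho * Wo)
            if weight.requires_grad:
                cols2 = im2col()
                gw = np.einsum("nop,nkp->ok", gmat, cols2, optimize=True)
                weight._accumulate(gw.reshape(w.shape))
                del cols2
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gcols = np.einsum("ok,nop->nkp", wmat, gmat, optimize=True)
                gcols = gcols.reshape(N, C, kh, kw, Ho, Wo)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + Ho * stride : stride,
                            j : j + Wo * stride : stride] += gcols[:, :, i, j]
                if padding:
                    gx = gxp[:, :, padding:-padding, padding:-padding]
                else:
                    gx = gxp
                self._accumulate(gx)

        return Tensor._make(out, parents, backward)

    def upsample2x(self):
        """Nearest-neighbor 2x upsampling of an NCHW tensor."""
        out = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            if not self.requires_grad:
                return
            N, C, H2, W2 = g.shape
            gr = g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            self._accumulate(gr)

        return Tensor._make(out, (self,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
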