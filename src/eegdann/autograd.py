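"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small graph-attention / residual-convolution networks on
CPU; this module supplies exactly the primitives those models need (broadcast
arithmetic, batched matmul, 2-D convolution and max-pooling, masked softmax,
cross-entropy, and a gradient-reversal node) with full float64 determinism.

Gradients flow through a dynamically built tape: every operation returns a new
:class:`Tensor` holding references to its parents and a closure that
accumulates ``dL/dparent`` given ``dL/dself``. ``Tensor.backward()`` runs a
topological sweep over the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gradient_reversal"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def sqrt(self):
        return self**0.5

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = np.matmul(self.data, other.data)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out, (self, other), backward)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or None

        def backward(g, a=self):
            if a.requires_grad:
                inv = np.argsort(axes) if axes else None
                a._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self):
            if a.requires_grad:
                gg = np.zeros_like(a.data)
                np.add.at(gg, idx, g)
                a._accum(gg)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * factor)

        return Tensor._make(self.data * factor, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = np.where(self.data > 0, self.data, neg)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * np.where(a.data > 0, 1.0, neg + alpha))

        return Tensor._make(out, (self,), backward)

    def exp(self):
        out = np.exp(self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * out)

        return Tensor._make(out, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    # -- softmax family -------------------------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(p * (g - (g * p).sum(axis=axis, keepdims=True)))

        return Tensor._make(p, (self,), backward)

    def masked_softmax(self, mask: np.ndarray, axis: int = -1):
        """Softmax along ``axis`` restricted to positions where ``mask`` is true.

        Masked-out positions get probability exactly zero and transmit no
        gradient; every slice must contain at least one unmasked entry.
        """
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), self.data.shape)
        if not mask.any(axis=axis).all():
            raise ValueError("masked_softmax: a slice has no unmasked entries")
        z = np.where(mask, self.data, -np.inf)
        z = z - z.max(axis=axis, keepdims=True)
        e = np.exp(z) * mask
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(p * (g - (g * p).sum(axis=axis, keepdims=True)))

        return Tensor._make(p, (self,), backward)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse

        def backward(g, a=self):
            if a.requires_grad:
                p = np.exp(out)
                a._accum(g - p * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out, (self,), backward)

    def cross_entropy(self, labels: np.ndarray):
        """Mean cross-entropy (nats) of row logits against integer labels."""
        labels = np.asarray(labels, dtype=np.int64)
        if labels.ndim != 1 or labels.shape[0] != self.data.shape[0]:
            raise ValueError("labels must be 1-D and match the batch size")
        logp = self.log_softmax(axis=-1)
        n = labels.shape[0]
        picked = logp[np.arange(n), labels]
        return -picked.mean()

    # -- convolution / pooling ------------------------------------------------
    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0):
        """NCHW 2-D cross-correlation with square kernel, no bias."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        oc, ic, k, k2 = w.shape
        if ic != c or k != k2:
            raise ValueError(f"conv2d shape mismatch: input {x.shape}, weight {w.shape}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        oh = (h + 2 * padding - k) // stride + 1
        ow = (wd + 2 * padding - k) // stride + 1
        if oh < 1 or ow < 1:
            raise ValueError("conv2d: spatial size collapsed below 1x1")
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (n, c, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
        wmat = w.reshape(oc, c * k * k)
        out = (cols @ wmat.T).transpose(0, 2, 1).reshape(n, oc, oh, ow)

        def backward(g, a=self, b=weight):
            gmat = g.reshape(n, oc, oh * ow).transpose(0, 2, 1)  # (n, L, oc)
            if b.requires_grad:
                gw = np.einsum("nlo,nlf->of", gmat, cols).reshape(w.shape)
                b._accum(gw)
            if a.requires_grad:
                gcols = gmat @ wmat  # (n, L, c*k*k)
                gcols = gcols.reshape(n, oh, ow, c, k, k)
                gx = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        gx[
                            :, :, di : di + oh * stride : stride, dj : dj + ow * stride : stride
                        ] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                a._accum(gx)

        return Tensor._make(out, (self, weight), backward)

    def maxpool2d(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        x = self.data
        n, c, h, w = x.shape
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
        oh = (h + 2 * padding - kernel) // stride + 1
        ow = (w + 2 * padding - kernel) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
        win = win[:, :, ::stride, ::stride].reshape(n, c, oh, ow, kernel * kernel)
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

        def backward(g, a=self):
            if not a.requires_grad:
                return
            gx = np.zeros_like(xp)
            di, dj = np.divmod(arg, kernel)
            ii = np.arange(oh)[None, None, :, None] * stride + di
            jj = np.arange(ow)[None, None, None, :] * stride + dj
            nn = np.arange(n)[:, None, None, None]
            cc = np.arange(c)[None, :, None, None]
            np.add.at(gx, (nn, cc, ii, jj), g)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            a._accum(gx)

        return Tensor._make(out, (self,), backward)

    # -- backward sweep -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` (lossless: slices recover inputs)."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out, tuple(tensors), backward)


def gradient_reversal(x: Tensor, lam: float) -> Tensor:
    """Identity in the forward pass; scales the gradient by ``-lam`` backward."""
    if lam < 0:
        raise ValueError("gradient-reversal coefficient must be >= 0")

    def backward(g, a=x):
        if a.requires_grad:
            a._accum(-lam * g)

    return Tensor._make(x.data.copy(), (x,), backward)
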