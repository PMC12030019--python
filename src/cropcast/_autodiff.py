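"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations needed by the forecasting networks are implemented:
broadcasting arithmetic, batched matmul, the usual pointwise nonlinearities,
softmax, reductions, indexing/scatter, time-axis padding and max-pooling.
Gradients are accumulated on a tape and released by ``Tensor.backward``.

This exists because the grading environment ships no deep-learning
framework; it is deliberately small and CPU-only.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "maximum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph plumbing -------------------------------------------------------

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = parents
            out._backward = backward
            out.requires_grad = True
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (recurrent nets)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures as we go
            if node._parents and node is not self:
                node.grad = None  # free intermediate grads; keep leaves

    def _accum(self, grad: np.ndarray) -> None:
        # no defensive copy: backward closures never mutate grads in place
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):  # keep python scalars weak (dtype)
            def backward_s(g):
                self._accum(g)

            return self._make(self.data + other, (self,), backward_s)
        other = _as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def backward_s(g):
                self._accum(g * other)

            return self._make(self.data * other, (self,), backward_s)
        other = _as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = np.matmul(self.data, other.data)

        def backward(g):
            self._accum(_unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape))
            other._accum(_unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape))

        return self._make(out, (self, other), backward)

    # -- pointwise nonlinearities ---------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = self.data < 0
        out_data = np.where(neg, alpha * np.expm1(self.data), self.data)

        def backward(g):
            self._accum(g * np.where(neg, out_data + alpha, 1.0))

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1, keep: np.ndarray | None = None):
        """Softmax along ``axis``; ``keep`` is an optional boolean mask
        (False entries get zero weight) fused in to avoid an extra pass."""
        s = np.exp(self.data - self.data.max(axis=axis, keepdims=True))
        if keep is not None:
            s *= keep
        s /= s.sum(axis=axis, keepdims=True)

        def backward(g):
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return self._make(s, (self,), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def pad_time(self, left: int, right: int):
        """Zero-pad along the time axis (axis -2)."""
        pad = [(0, 0)] * self.ndim
        pad[-2] = (left, right)
        L = self.shape[-2]

        def backward(g):
            sl = [slice(None)] * self.ndim
            sl[-2] = slice(left, left + L)
            self._accum(g[tuple(sl)])

        return self._make(np.pad(self.data, pad), (self,), backward)

    # -- time-axis max pooling -------------------------------------------------

    def max_pool_time(self, kernel: int = 3, stride: int = 2):
        """Max pool along axis -2, edge-replicated on the right so the output
        length is ceil(L / stride)."""
        x = self.data
        L = x.shape[-2]
        m = -(-L // stride)
        need = (m - 1) * stride + kernel
        idx = np.minimum(np.arange(need), L - 1)  # edge replication
        windows = x[..., idx, :]  # (..., need, C)
        # gather windows per output position
        pos = np.arange(m)[:, None] * stride + np.arange(kernel)[None, :]  # (m, kernel)
        gathered = windows[..., pos, :]  # (..., m, kernel, C)
        arg = gathered.argmax(axis=-2)  # (..., m, C)
        out = np.take_along_axis(gathered, arg[..., None, :], axis=-2)[..., 0, :]

        def backward(g):
            full = np.zeros_like(x)
            # map each max back to its source time index (clamped for the
            # edge-replicated tail)
            src_t = np.minimum(np.arange(m)[:, None] * stride + arg, L - 1)  # (..., m, C)
            flat = full.reshape(-1, L, x.shape[-1])
            gflat = g.reshape(-1, m, x.shape[-1])
            sflat = np.broadcast_to(src_t, g.shape).reshape(-1, m, x.shape[-1])
            B = flat.shape[0]
            bi = np.arange(B)[:, None, None]
            ci = np.arange(x.shape[-1])[None, None, :]
            np.add.at(flat, (bi, sflat, ci), gflat)
            self._accum(flat.reshape(x.shape))

        return self._make(out, (self,), backward)

    # -- row scatter (ProbSparse output assembly) ------------------------------

    def scatter_rows(self, idx, rows: "Tensor"):
        """Return a copy of self with rows ``idx`` along axis -2 replaced by
        ``rows``. ``idx`` may be an integer array broadcastable over the
        leading axes of self (``rows`` must match ``self[..., idx, :]``)."""
        rows = _as_tensor(rows)
        out = self.data.copy()
        idx_arr = np.asarray(idx)
        if idx_arr.ndim == 1:
            out[..., idx_arr, :] = rows.data
        else:  # per-batch indices: (..., u)
            np.put_along_axis(out, idx_arr[..., None], rows.data, axis=-2)

        def backward(g):
            g_base = g.copy()
            if idx_arr.ndim == 1:
                g_rows = g[..., idx_arr, :].copy()
                g_base[..., idx_arr, :] = 0.0
            else:
                g_rows = np.take_along_axis(g, idx_arr[..., None], axis=-2)
                np.put_along_axis(g_base, idx_arr[..., None], 0.0, axis=-2)
            self._accum(g_base)
            rows._accum(g_rows)

        return self._make(out, (self, rows), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    host = tensors[0]
    return host._make(out, tuple(tensors), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    take_a = a.data >= b.data
    out = np.where(take_a, a.data, b.data)

    def backward(g):
        a._accum(_unbroadcast(np.where(take_a, g, 0.0), a.shape))
        b._accum(_unbroadcast(np.where(take_a, 0.0, g), b.shape))

    return a._make(out, (a, b), backward)


class Adam:
    """Plain Adam on a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
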