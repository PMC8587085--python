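"""Minimal reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine — just the operations the estimation network
needs (dense/convolutional linear maps, pooling, sigmoid/tanh/relu, axis
reductions, concatenation, slicing) with full broadcasting support. All
computation is float64 on the CPU, which keeps runs bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "avg_pool1d", "gru_sequence"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float)  # copy: g may be shared
        else:
            self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                              self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                               other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t * t))

        return self._make(t, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice)) for i in idx)
        )

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:  # basic slices never alias, so += suffices
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accumulate(full)

        return self._make(out_data, (self,), backward)

    # -- backprop ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this tensor through the graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be given for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort (graphs can be deep)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def _out_len(length: int, kernel: int, stride: int, pad: int) -> int:
    return (length + 2 * pad - kernel) // stride + 1


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """1-D cross-correlation: x (B, C, L), w (O, C, K), b (O,) -> (B, O, L')."""
    B, C, L = x.data.shape
    O, Cw, K = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    Lout = _out_len(L, K, stride, pad)
    if Lout < 1:
        raise ValueError(
            f"input length {L} too short for kernel {K} stride {stride} pad {pad}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    # windows view: (B, C, Lout, K)
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride]
    out_data = np.einsum("bclk,ock->bol", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bclk,bol->ock", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k : k + stride * Lout : stride] += np.einsum(
                    "bol,oc->bcl", g, w.data[:, :, k], optimize=True
                )
            x._accumulate(gxp[:, :, pad : pad + L] if pad else gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def gru_sequence(x: Tensor, w_r: Tensor, w_z: Tensor, w_h: Tensor,
                 reverse: bool = False) -> Tensor:
    """Run a GRU over x (B, T, in) -> hidden sequence (B, T, h).

    Gates act on the concatenation [h_prev, x_t] with no biases:
    r = sigmoid([h,x] W_r), z = sigmoid([h,x] W_z),
    c = tanh([r*h, x] W_h), h' = (1-z)*h + z*c.

    Implemented as one fused operation with hand-derived backpropagation
    through time; ``reverse=True`` processes the sequence back-to-front and
    returns outputs aligned to the input's time order.
    """
    B, T, n_in = x.data.shape
    h = w_r.data.shape[1]
    if w_r.data.shape[0] != h + n_in:
        raise ValueError(
            f"gate weights expect input size {w_r.data.shape[0] - h}, got {n_in}"
        )
    xs = x.data[:, ::-1] if reverse else x.data
    # stash per-step activations for the backward pass
    rs = np.empty((T, B, h)); zs = np.empty((T, B, h))
    cs = np.empty((T, B, h)); hs = np.empty((T + 1, B, h))
    hs[0] = 0.0
    wr, wz, wh = w_r.data, w_z.data, w_h.data
    # input projections for all steps at once
    xr = xs @ wr[h:]; xz = xs @ wz[h:]; xh = xs @ wh[h:]
    whr, whz, whh = wr[:h], wz[:h], wh[:h]
    for t in range(T):
        hp = hs[t]
        r = 1.0 / (1.0 + np.exp(-(hp @ whr + xr[:, t])))
        z = 1.0 / (1.0 + np.exp(-(hp @ whz + xz[:, t])))
        c = np.tanh((r * hp) @ whh + xh[:, t])
        rs[t], zs[t], cs[t] = r, z, c
        hs[t + 1] = (1.0 - z) * hp + z * c
    seq = hs[1:].transpose(1, 0, 2)  # (B, T, h) in processing order
    out_data = seq[:, ::-1].copy() if reverse else seq

    def backward(g):
        gseq = g[:, ::-1] if reverse else g  # align to processing order
        dwr = np.zeros_like(wr); dwz = np.zeros_like(wz); dwh = np.zeros_like(wh)
        dxs = np.zeros((B, T, n_in))
        carry = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            dh = gseq[:, t] + carry
            hp, r, z, c = hs[t], rs[t], zs[t], cs[t]
            da_z = dh * (c - hp) * z * (1.0 - z)
            da_c = dh * z * (1.0 - c * c)
            d_rh = da_c @ whh.T
            da_r = d_rh * hp * r * (1.0 - r)
            hx = np.concatenate([hp, xs[:, t]], axis=1)
            dwr += hx.T @ da_r
            dwz += hx.T @ da_z
            dwh += np.concatenate([r * hp, xs[:, t]], axis=1).T @ da_c
            gr = da_r @ wr.T
            gz = da_z @ wz.T
            carry = dh * (1.0 - z) + d_rh * r + gr[:, :h] + gz[:, :h]
            dxs[:, t] = gr[:, h:] + gz[:, h:] + da_c @ wh[h:].T
        if x.requires_grad:
            x._accumulate(dxs[:, ::-1] if reverse else dxs)
        if w_r.requires_grad:
            w_r._accumulate(dwr)
        if w_z.requires_grad:
            w_z._accumulate(dwz)
        if w_h.requires_grad:
            w_h._accumulate(dwh)

    return Tensor._make(out_data, (x, w_r, w_z, w_h), backward)


def avg_pool1d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    """Average pooling over the last axis of x (B, C, L)."""
    B, C, L = x.data.shape
    Lout = _out_len(L, kernel, stride, 0)
    if Lout < 1:
        raise ValueError(f"input length {L} too short for pooling kernel {kernel}")
    win = np.lib.stride_tricks.sliding_window_view(x.data, kernel, axis=2)[:, :, ::stride]
    out_data = win.mean(axis=-1)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for k in range(kernel):
                gx[:, :, k : k + stride * Lout : stride] += g / kernel
            x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)
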