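"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every operation builds a node whose
``_backward`` closure scatters the output gradient to its parents, and
``Tensor.backward`` runs the closures in reverse topological order.  All
arithmetic is float64.  Convolutions are FFT-based (the temporal kernels used
by the multiscale block span up to 250 samples, where direct sliding-window
convolution is both slow and memory-hungry).

Every primitive with a hand-written gradient is covered by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ----- graph plumbing -------------------------------------------------

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g)  # copy: g may be shared between parents
        else:
            self.grad += g

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ----- elementwise arithmetic ----------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        return self._node(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._node(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return self._node(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)

        def backward(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, neg + alpha))

        return self._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._node(out_data, (self,), backward)

    # ----- reductions and shape ops --------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accumulate(g.reshape(self.shape))

        return self._node(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = self.data.transpose(*axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(*inv))

        return self._node(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        simple = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) or k is Ellipsis for k in key)
        )

        def backward(g):
            full = np.zeros_like(self.data)
            if simple:  # basic indexing never repeats an element
                full[key] += g
            else:
                np.add.at(full, key, g)
            self._accumulate(full)

        return self._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        return self._node(out_data, (self, other), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax composed from primitives."""
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # ----- convolution primitives ----------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               dilation: int = 1, padding: str = "same"):
        """Cross-correlation along the last axis.

        self: (B, Cin, T); weight: (Cout, Cin, K) -> (B, Cout, T).
        ``padding`` is 'same' (centered) or 'causal' (left-only, so output at
        time t never sees input beyond t).

        Computed spectrally: each operand is FFT'd once and channel sums are
        contracted in the frequency domain, so neither the forward nor the
        backward pass materializes a (B, Cout, Cin, T) intermediate.  The
        input spectrum is cached for the weight gradient.
        """
        x, w = self.data, weight.data
        B, Ci, T = x.shape
        Co, Ci2, K = w.shape
        if Ci != Ci2:
            raise ValueError(f"conv1d channel mismatch: input {Ci}, weight {Ci2}")
        keff = (K - 1) * dilation + 1
        if keff > T and padding == "same":
            raise ValueError(f"effective kernel {keff} exceeds sequence length {T}")
        wd = np.zeros((Co, Ci, keff))
        wd[..., ::dilation] = w
        if padding == "same":
            pl = (keff - 1) // 2
        elif padding == "causal":
            pl = keff - 1
        else:
            raise ValueError(f"unknown padding {padding!r}")
        pr = keff - 1 - pl
        tp = T + keff - 1
        nfft = next_fast_len(tp, real=True)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        xf = rfft(xp, nfft, axis=-1)
        wf = rfft(wd, nfft, axis=-1)
        # cross-correlation out[t] = sum_k wd[k] xp[t+k]  <->  X * conj(W)
        out_data = irfft(
            np.einsum("bif,oif->bof", xf, wf.conj()), nfft, axis=-1
        )[..., :T]
        if bias is not None:
            out_data = out_data + bias.data[None, :, None]

        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2)))
            gf = rfft(g, nfft, axis=-1)
            if self.requires_grad:
                # dxp = g (full-)convolved with wd, summed over out channels
                dxp = irfft(
                    np.einsum("bof,oif->bif", gf, wf), nfft, axis=-1
                )[..., :tp]
                self._accumulate(dxp[..., pl: pl + T])
            if weight.requires_grad:
                # dwd[k] = sum_t g[t] xp[t+k]  <->  X * conj(G)
                dwd = irfft(
                    np.einsum("bif,bof->oif", xf, gf.conj()), nfft, axis=-1
                )[..., :keff]
                weight._accumulate(dwd[..., ::dilation])

        return self._node(out_data, parents, backward)

    def spatial_collapse(self, weight: "Tensor"):
        """Depthwise convolution over the electrode axis.

        self: (B, F, C, T); weight: (F, M, C) -> (B, F*M, T).  Each temporal
        filter f gets M spatial filters spanning all C electrodes, collapsing
        the electrode axis to one weighted combination per (f, m).
        """
        x, w = self.data, weight.data
        B, F, C, T = x.shape
        F2, M, C2 = w.shape
        if F != F2 or C != C2:
            raise ValueError(
                f"spatial_collapse mismatch: input (F={F}, C={C}), weight (F={F2}, C={C2})"
            )
        out4 = np.einsum("fmc,bfct->bfmt", w, x)
        out_data = out4.reshape(B, F * M, T)

        def backward(g):
            g4 = g.reshape(B, F, M, T)
            if weight.requires_grad:
                weight._accumulate(np.einsum("bfmt,bfct->fmc", g4, x))
            if self.requires_grad:
                self._accumulate(np.einsum("fmc,bfmt->bfct", w, g4))

        return self._node(out_data, (self, weight), backward)

    def avg_pool1d(self, size: int):
        """Non-overlapping mean pooling along the last axis; remainder samples
        beyond the last full window are discarded."""
        *lead, T = self.shape
        n = T // size
        trimmed = self[..., : n * size]
        return trimmed.reshape(*lead, n, size).mean(axis=-1)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor._node(out_data, tuple(tensors), backward)
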