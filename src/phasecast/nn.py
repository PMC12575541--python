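"""Minimal reverse-mode autodiff and neural-network core.

All trainable components of the package (windowed self-attention encoder,
single-pass / autoregressive decoders, recognition and anticipation heads)
are built on the :class:`Tensor` defined here: a dense float64 numpy array
with a recorded operation graph and a topological-order backward pass.

The design goals are, in order: determinism (identical inputs, weights and
seeds give bit-identical outputs on repeated runs), correctness of gradients
(checked against central finite differences in the test suite), and
simplicity. Throughput is adequate for the desk-scale models this package
trains; there is no GPU path and no operator fusion beyond numerically
stable log-softmax and layer-norm primitives.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

#: float dtype of all Tensor data and gradients.  float32 is the working
#: default (the desk-scale models are far from its precision limits and it
#: halves memory traffic); tests that compare against finite differences
#: switch to float64.
DTYPE = np.float32

#: global autograd switch; use the `no_grad` context for inference so no
#: operation graph (with its reference cycles) is built at all.
GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global GRAD_ENABLED
        self._prev = GRAD_ENABLED
        GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global GRAD_ENABLED
        GRAD_ENABLED = self._prev
        return False


def _track(*tensors) -> bool:
    """Whether an op on these operands must join the autodiff graph."""
    return GRAD_ENABLED and any(
        t.requires_grad or t._prev for t in tensors if isinstance(t, Tensor))

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "FeedForward",
    "MultiHeadAttention",
    "TransformerLayer",
    "Adam",
    "sinusoidal_encoding",
    "stable_softmax",
    "cat",
    "cross_entropy",
    "mse_loss",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast when producing it from `shape`."""
    if grad.shape == shape:
        return grad
    # remove leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node in a reverse-mode autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev = _prev

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs from AR rollouts can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # free the graph: break the node<->closure reference cycles so
        # intermediate buffers are reclaimed without waiting for the
        # cyclic garbage collector
        for node in topo:
            if node._prev:
                node._backward = None
                node._prev = ()
                node.grad = None

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        if not _track(self, other):
            return Tensor(self.data + other.data)
        out = Tensor(self.data + other.data, False, (self, other))

        def _bw():
            g = out.grad
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        if not _track(self):
            return Tensor(-self.data)
        out = Tensor(-self.data, False, (self,))
        out._backward = lambda: self._accumulate(-out.grad)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        if not _track(self, other):
            return Tensor(self.data * other.data)
        out = Tensor(self.data * other.data, False, (self, other))

        def _bw():
            g = out.grad
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        if not _track(self, other):
            return Tensor(self.data / other.data)
        out = Tensor(self.data / other.data, False, (self, other))

        def _bw():
            g = out.grad
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = _bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        if not _track(self, other):
            return Tensor(self.data @ other.data)
        out = Tensor(self.data @ other.data, False, (self, other))

        def _bw():
            g = out.grad
            a, b = self.data, other.data
            if self.requires_grad or self._prev:
                if b.ndim == 1:
                    ga = np.expand_dims(g, -1) * b          # (..., m, k)
                elif a.ndim == 1:
                    ga = (b @ np.expand_dims(g, -1))[..., 0]  # (..., k)
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad or other._prev:
                if b.ndim == 1:
                    gb = (np.swapaxes(a, -1, -2)
                          @ np.expand_dims(g, -1))[..., 0]    # (..., k)
                elif a.ndim == 1:
                    gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = _bw
        return out

    # -- elementwise ------------------------------------------------------
    def relu(self) -> "Tensor":
        if not _track(self):
            return Tensor(np.maximum(self.data, 0.0))
        out = Tensor(np.maximum(self.data, 0.0), False, (self,))
        out._backward = lambda: self._accumulate(out.grad * (self.data > 0))
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        if not _track(self):
            return Tensor(y)
        out = Tensor(y, False, (self,))
        out._backward = lambda: self._accumulate(out.grad * (1.0 - y * y))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        if not _track(self):
            return Tensor(y)
        out = Tensor(y, False, (self,))
        out._backward = lambda: self._accumulate(out.grad * y)
        return out

    def log(self) -> "Tensor":
        if not _track(self):
            return Tensor(np.log(self.data))
        out = Tensor(np.log(self.data), False, (self,))
        out._backward = lambda: self._accumulate(out.grad / self.data)
        return out

    def maximum(self, other) -> "Tensor":
        """Elementwise max; ties send the gradient to `self` (left operand)."""
        other = Tensor._lift(other)
        if not _track(self, other):
            return Tensor(np.maximum(self.data, other.data))
        out = Tensor(np.maximum(self.data, other.data), False,
                     (self, other))

        def _bw():
            g = out.grad
            left = self.data >= other.data
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * left, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * ~left, other.shape))

        out._backward = _bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        if not _track(self):
            return Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     False, (self,))

        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        y = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not _track(self):
            return Tensor(y if keepdims else y.squeeze(axis))
        out = Tensor(y if keepdims else y.squeeze(axis), False, (self,))

        def _bw():
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axis)
            buf = np.zeros_like(self.data)
            np.put_along_axis(buf, np.expand_dims(idx, axis), g, axis)
            self._accumulate(buf)

        out._backward = _bw
        return out

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        if not _track(self):
            return Tensor(self.data.reshape(shape))
        out = Tensor(self.data.reshape(shape), False, (self,))
        out._backward = lambda: self._accumulate(out.grad.reshape(self.shape))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        if not _track(self):
            return Tensor(np.swapaxes(self.data, a, b))
        out = Tensor(np.swapaxes(self.data, a, b), False, (self,))
        out._backward = lambda: self._accumulate(np.swapaxes(out.grad, a, b))
        return out

    def __getitem__(self, key) -> "Tensor":
        if not _track(self):
            return Tensor(self.data[key])
        out = Tensor(self.data[key], False, (self,))

        def _bw():
            buf = np.zeros_like(self.data)
            np.add.at(buf, key, out.grad)
            self._accumulate(buf)

        out._backward = _bw
        return out

    # -- fused numerically-stable ops ------------------------------------
    def log_softmax(self, axis: int = -1) -> "Tensor":
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse
        if not _track(self):
            return Tensor(y)
        out = Tensor(y, False, (self,))

        def _bw():
            g = out.grad
            self._accumulate(g - np.exp(y) * g.sum(axis=axis, keepdims=True))

        out._backward = _bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        return self.log_softmax(axis=axis).exp()

    def layer_norm(self, gamma: "Tensor", beta: "Tensor",
                   eps: float = 1e-5) -> "Tensor":
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        if not _track(self, gamma, beta):
            return Tensor(xhat * gamma.data + beta.data)
        out = Tensor(xhat * gamma.data + beta.data,
                     False, (self, gamma, beta))

        def _bw():
            g = out.grad
            d = x.shape[-1]
            gxhat = g * gamma.data
            gx = inv * (gxhat
                        - gxhat.mean(axis=-1, keepdims=True)
                        - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))
            self._accumulate(gx)
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
            beta._accumulate(_unbroadcast(g, beta.shape))

        out._backward = _bw
        return out


def cat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis, with gradient routing."""
    tensors = list(tensors)
    if not _track(*tensors):
        return Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 False, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw():
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * out.data.ndim
            sl[axis] = slice(start, start + s)
            t._accumulate(out.grad[tuple(sl)])
            start += s

    out._backward = _bw
    return out


# -- losses ---------------------------------------------------------------

def cross_entropy(logits: Tensor, targets: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted cross-entropy over the last axis.

    `logits` has shape (..., C) and `targets` integer shape (...).  With
    `class_weights` the per-sample losses are scaled by the weight of the
    true class and the mean is taken over the weight total, matching the
    usual weighted-CE convention (a vector of ones reduces to plain CE).
    """
    targets = np.asarray(targets)
    logp = logits.log_softmax(axis=-1)
    flat = logp.reshape(-1, logits.shape[-1])
    idx = (np.arange(flat.shape[0]), targets.reshape(-1))
    picked = flat[idx]
    if class_weights is None:
        return -picked.mean()
    w = np.asarray(class_weights, dtype=np.float64)[targets.reshape(-1)]
    return -(picked * w).sum() / w.sum()


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=np.float64))
    return (diff * diff).mean()


# -- modules ---------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter discovery, train/eval-free (no dropout)."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        if set(named) != set(state):
            missing = set(named) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for name, arr in state.items():
            if named[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            named[name].data = np.asarray(arr, dtype=DTYPE).copy()

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for key, value in sorted(vars(self).items()):
            out.extend(_named_collect(value, f"{prefix}{key}"))
        return out


def _collect(value) -> Iterable[Parameter]:
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _named_collect(value, name: str) -> Iterable[tuple[str, Parameter]]:
    if isinstance(value, Parameter):
        yield (name, value)
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix=name + ".")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _named_collect(v, f"{name}.{i}")


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = 1.0 / math.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


class FeedForward(Module):
    def __init__(self, d: int, d_hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention.

    Self-attention when `kv` is omitted, cross-attention otherwise; an
    optional additive mask (broadcast to (..., Lq, Lk), -inf for blocked
    positions) implements causal decoding.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 d_kv: int | None = None):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        d_kv = d_model if d_kv is None else d_kv
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_kv, d_model, rng)
        self.wv = Linear(d_kv, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, kv: Tensor | None = None,
                 mask: np.ndarray | None = None) -> Tensor:
        kv = x if kv is None else kv
        b_shape = x.shape[:-2]
        lq, lk = x.shape[-2], kv.shape[-2]
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor, ln: int) -> Tensor:
            return t.reshape(*b_shape, ln, h, dh).swapaxes(-2, -3)

        q = split(self.wq(x), lq)              # (..., h, Lq, dh)
        k = split(self.wk(kv), lk)
        v = split(self.wv(kv), lk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = scores.softmax(axis=-1)
        ctx = attn @ v                          # (..., h, Lq, dh)
        ctx = ctx.swapaxes(-2, -3).reshape(*b_shape, lq, h * dh)
        return self.wo(ctx)


class TransformerLayer(Module):
    """Pre-norm attention + feed-forward block (self- or cross-attending)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 d_kv: int | None = None, d_ff: int | None = None):
        self.attn = MultiHeadAttention(d_model, n_heads, rng, d_kv=d_kv)
        self.ff = FeedForward(d_model, d_ff or 2 * d_model, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, kv: Tensor | None = None,
                 mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), kv=kv, mask=mask)
        return x + self.ff(self.ln2(x))


class Adam:
    """Adam with bias correction; state is keyed by parameter identity order."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def stable_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax of a plain array, computed in float64."""
    z = np.asarray(x, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sinusoidal_encoding(length: int, dim: int,
                        max_wavelength: float = 10000.0) -> np.ndarray:
    """Standard sine/cosine positional encoding, shape (length, dim).

    The lowest-frequency pair is monotone over any window shorter than a
    quarter wavelength, which lets downstream max-pooling retain coarse
    position information.
    """
    pos = np.arange(length, dtype=np.float64)[:, None]
    half = (dim + 1) // 2
    freqs = np.exp(-math.log(max_wavelength) * np.arange(half) / max(half - 1, 1))
    ang = pos * freqs[None, :]
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(ang[:, : (dim + 1) // 2])
    enc[:, 1::2] = np.cos(ang[:, : dim // 2])
    return enc
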