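"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the point-cloud networks in this
package.  It implements exactly the primitives those architectures need
(dense matmul, broadcast arithmetic, ReLU/tanh, axis max/sum/mean, row
gather, concatenation, and a fused weighted softmax cross-entropy) plus
an Adam optimiser.  Everything is float64 by default for reproducibility
across platforms; networks are small enough that speed is dominated by
neighbourhood construction, not arithmetic precision.

Gradient correctness is pinned by central-difference checks in the test
suite rather than by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "matmul",
    "add",
    "sub",
    "mul",
    "relu",
    "leaky_relu",
    "tanh",
    "sqrt",
    "amax",
    "asum",
    "amean",
    "take",
    "concat",
    "reshape",
    "softmax_cross_entropy",
    "Linear",
    "MLP",
    "Adam",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()
        self._grad_owned = False

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph traversal ------------------------------------------------

    def backward(self, grad=None):
        """Reverse-mode sweep from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        # gradients are never mutated in place by op backwards, so the
        # first contribution can be stored by reference; a second
        # contribution allocates (copy-on-accumulate)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def detach(self):
        return Tensor(self.data.copy())


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def _needs_graph(*ts):
    return any(t.requires_grad or t._backward is not None for t in ts)


def _child(data, parents, backward):
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (reverse numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- primitives ----------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._backward:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._backward:
            b._accumulate(a.data.T @ g)

    return _child(out_data, (a, b), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _child(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))

    return _child(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _child(a.data * b.data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        a._accumulate(g * c)

    return _child(a.data * c, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _child(a.data * mask, (a,), backward)


def leaky_relu(a: Tensor, alpha: float = 0.1) -> Tensor:
    slope = np.where(a.data > 0, 1.0, alpha)

    def backward(g):
        a._accumulate(g * slope)

    return _child(a.data * slope, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - out_data**2))

    return _child(out_data, (a,), backward)


def sqrt(a: Tensor, eps: float = 1e-12) -> Tensor:
    out_data = np.sqrt(a.data + eps)

    def backward(g):
        a._accumulate(g * 0.5 / out_data)

    return _child(out_data, (a,), backward)


def amax(a: Tensor, axis: int) -> Tensor:
    """Max over one axis; gradient routes to the first arg-max entry."""
    idx = np.argmax(a.data, axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis).squeeze(axis)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis)
        a._accumulate(ga)

    return _child(out_data, (a,), backward)


def asum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            ga = np.broadcast_to(g, a.data.shape)
        elif keepdims:
            ga = np.broadcast_to(g, a.data.shape)
        else:
            ga = np.broadcast_to(np.expand_dims(g, axis), a.data.shape)
        a._accumulate(np.ascontiguousarray(ga))

    return _child(out_data, (a,), backward)


def amean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(asum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def take(a: Tensor, idx) -> Tensor:
    """Gather rows along axis 0; ``idx`` may be any integer array shape."""
    idx = np.asarray(idx)
    out_data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx.reshape(-1), g.reshape(-1, *a.data.shape[1:]))
        a._accumulate(ga)

    return _child(out_data, (a,), backward)


def concat(parts, axis=-1) -> Tensor:
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for p, gp in zip(parts, np.split(g, splits, axis=axis)):
            p._accumulate(gp)

    return _child(out_data, tuple(parts), backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _child(a.data.reshape(shape), (a,), backward)


def softmax_cross_entropy(logits: Tensor, targets, class_weights=None):
    """Weighted mean cross-entropy over rows of ``logits``.

    Returns (loss Tensor, probabilities array).  ``targets`` is an int
    vector; ``class_weights`` re-weights each sample by its true class
    (inverse-frequency weighting for imbalanced segmentation).
    """
    targets = np.asarray(targets, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = targets.shape[0]
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[targets]
    wsum = w.sum()
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    loss_val = -(w * logp[np.arange(n), targets]).sum() / wsum

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), targets] -= 1.0
        grad *= (w / wsum)[:, None]
        logits._accumulate(g * grad)

    loss = _child(np.asarray(loss_val), (logits,), backward)
    return loss, probs


# -- modules -------------------------------------------------------------


class Linear:
    """Dense layer y = xW + b with He-normal init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, std, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)

    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Stack of Linear+rectifier layers.

    ``activation`` is "relu" or "leaky" (leaky rectifier, slope 0.1 —
    the standard choice for edge-convolution stacks, where a plain ReLU
    can die under the max-pool bottleneck).  With ``final_relu=False``
    the last layer is affine."""

    def __init__(self, widths, rng, final_relu=True, activation="relu"):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.final_relu = final_relu
        self.act = relu if activation == "relu" else leaky_relu

    def __call__(self, x: Tensor) -> Tensor:
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < last or self.final_relu:
                x = self.act(x)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam optimiser (Kingma & Ba) over a flat parameter list."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
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
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
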