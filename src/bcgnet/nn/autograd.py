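"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the network needs are provided; each op records a
closure that routes the upstream gradient to its inputs.  Gradients are
accumulated into ``Tensor.grad`` by :func:`backward`, which walks the tape
in reverse topological order (iteratively, so deep stacks of residual
blocks do not hit the interpreter recursion limit).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "backward"]


class Tensor:
    """An array node in the computation graph.

    ``parents`` and ``_backward`` are set by the op that produced the
    tensor; leaves created by the user have neither.
    """

    __slots__ = ("data", "grad", "requires_grad", "parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self.parents = tuple(parents)
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, copy=True)
    else:
        t.grad = t.grad + g


def make_op(out_data: np.ndarray, inputs, backward_fn) -> Tensor:
    """Create the output tensor of an op.

    ``backward_fn(g)`` must return a gradient per input (``None`` for
    inputs that need none); gradients are accumulated automatically.
    """
    req = any(t.requires_grad for t in inputs)

    if not req:
        return Tensor(out_data)

    def _bw(g):
        grads = backward_fn(g)
        for t, gi in zip(inputs, grads):
            if gi is not None:
                _accumulate(t, gi)

    return Tensor(out_data, requires_grad=True, parents=inputs, backward_fn=_bw)


def backward(root: Tensor, grad: np.ndarray | None = None) -> None:
    """Propagate ``grad`` (default: ones) from ``root`` through the tape."""
    if grad is None:
        grad = np.ones_like(root.data)
    # iterative post-order topological sort
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    if root.requires_grad:
        _accumulate(root, grad)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
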