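"""Tape-based reverse-mode autodiff over numpy arrays.

A :class:`Tensor` wraps a float32 ndarray; operations that receive at
least one gradient-requiring input record a backward closure. Gradients
are accumulated by :meth:`Tensor.backward` in reverse topological
order. Only the operations used by the segmentation head are
implemented; everything runs on the CPU in float32.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True

#: Working dtype of the engine. float32 everywhere in production; tests
#: may switch to float64 for finite-difference gradient checks.
DTYPE = np.float32


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _as_f32(x):
    return np.asarray(x, dtype=DTYPE)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate ``grad`` (defaults to ones) through the tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.accumulate(_as_f32(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t is not self and not t.requires_grad:
                # interior node: free the gradient once consumed
                t.grad = None


class Parameter(Tensor):
    """A leaf tensor holding learnable (or frozen) weights."""

    def __init__(self, data, trainable=True):
        super().__init__(data, requires_grad=trainable)
        self.trainable = trainable

    __slots__ = ("trainable",)


def _make(data, parents, backward):
    """Create an op output, recording the tape only when needed."""
    track = _grad_enabled and any(p.requires_grad or p._prev for p in parents)
    out = Tensor(data)
    if track:
        out.requires_grad = False  # leaf-ness is reserved for Parameters
        out._prev = tuple(parents)
        out._backward = backward
        # interior nodes must participate in accumulation
        out.requires_grad = True
    return out


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Module:
    """Base class with recursive parameter/buffer discovery."""

    def __init__(self):
        self.training = True
        self._buffers = {}

    def register_buffer(self, name, array):
        self._buffers[name] = np.asarray(array, dtype=np.float32)
        setattr(self, name, self._buffers[name])

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{k}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{k}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for k in self._buffers:
            yield f"{prefix}{k}", getattr(self, k)
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def freeze(self):
        """Mark every parameter non-trainable (no gradient tracking)."""
        for p in self.parameters():
            p.requires_grad = False
            p.trainable = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        d = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        for k, v in self.named_buffers():
            d[f"buffer:{k}"] = v.copy()
        return d

    def load_state_dict(self, d):
        params = dict(self.named_parameters())
        for key, arr in d.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data[...] = arr
            else:
                self._assign_buffer(name, arr)

    def _assign_buffer(self, dotted, arr):
        obj = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
        target = getattr(obj, parts[-1])
        target[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)
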