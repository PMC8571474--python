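"""Minimal NumPy neural-network kernel: modules with explicit backprop.

Implements exactly the layer set the classifier needs (linear, ReLU,
dropout, batch norm, 3D convolution/pooling, LSTM) plus Adam and a fused
softmax cross-entropy.  Every module follows the same contract:
``forward(x, train=...)`` caches what ``backward(grad)`` needs; a backward
call consumes the cache of the most recent forward.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "ReLU",
    "Dropout",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "default_dtype",
    "set_default_dtype",
]

# float32 keeps the volumetric path memory-bound workload affordable on one
# CPU; gradient-check tests switch to float64.
_DEFAULT_DTYPE = np.float32


def default_dtype():
    return _DEFAULT_DTYPE


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class; subclasses register parameters and child modules."""

    def __init__(self) -> None:
        self._params: Dict[str, Parameter] = {}
        self._children: Dict[str, "Module"] = {}

    def register(self, name: str, obj):
        if isinstance(obj, Parameter):
            obj.name = name
            self._params[name] = obj
        elif isinstance(obj, Module):
            self._children[name] = obj
        else:  # pragma: no cover
            raise TypeError(type(obj))
        return obj

    def modules(self) -> List["Module"]:
        """This module and all descendants."""
        out: List[Module] = [self]
        for child in self._children.values():
            out.extend(child.modules())
        return out

    def parameters(self) -> List[Parameter]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> List[Tuple[str, Parameter]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, arr in self._buffers().items():
            state[name] = arr.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = self._buffers()
        for name, arr in state.items():
            if name in params:
                params[name].data[...] = arr
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unknown state entry {name}")

    def _buffers(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for name, arr in getattr(self, "_buffer_attrs", {}).items():
            out[prefix + name] = getattr(self, arr)
        for cname, child in self._children.items():
            out.update(child._buffers(prefix + cname + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x, train: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


def _kaiming(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DEFAULT_DTYPE)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = self.register(
            "weight", Parameter(_kaiming(rng, (out_features, in_features), in_features))
        )
        self.bias = self.register("bias", Parameter(np.zeros(out_features)))
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"expected input width {self.in_features}, got {x.shape[-1]}"
            )
        x = np.asarray(x, dtype=self.weight.data.dtype)
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p = p
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        mask = self.rng.random(x.shape) >= self.p
        self._mask = mask.astype(x.dtype) / x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)
        for i, m in enumerate(self.steps):
            self.register(str(i), m)

    def forward(self, x, train: bool = False):
        for m in self.steps:
            x = m.forward(x, train=train)
        return x

    def backward(self, grad):
        for m in reversed(self.steps):
            grad = m.backward(grad)
        return grad


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the
    mean loss.
    """
    n = logits.shape[0]
    probs = softmax(logits)
    idx = np.arange(n)
    loss = -np.log(np.clip(probs[idx, labels], 1e-12, None)).mean()
    grad = probs.copy()
    grad[idx, labels] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.99),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
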