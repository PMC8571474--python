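"""Multi-layer LSTM with BPTT, returning the final hidden state."""

from __future__ import annotations

from typing import List

import numpy as np

from .core import Module, Parameter

__all__ = ["LSTM"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTMLayer(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        h = hidden_size
        scale = 1.0 / np.sqrt(h)
        self.w_ih = self.register(
            "w_ih", Parameter(rng.uniform(-scale, scale, (4 * h, input_size)))
        )
        self.w_hh = self.register(
            "w_hh", Parameter(rng.uniform(-scale, scale, (4 * h, h)))
        )
        self.bias = self.register("bias", Parameter(np.zeros(4 * h)))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, T, input_size) → hidden sequence (N, T, hidden_size)."""
        x = np.asarray(x, dtype=self.w_ih.data.dtype)
        n, t, _ = x.shape
        h = self.hidden_size
        hs = np.zeros((n, t, h), dtype=x.dtype)
        steps = []
        h_prev = np.zeros((n, h), dtype=x.dtype)
        c_prev = np.zeros((n, h), dtype=x.dtype)
        for step in range(t):
            gates = x[:, step] @ self.w_ih.data.T + h_prev @ self.w_hh.data.T + self.bias.data
            i = _sigmoid(gates[:, 0:h])
            f = _sigmoid(gates[:, h : 2 * h])
            g = np.tanh(gates[:, 2 * h : 3 * h])
            o = _sigmoid(gates[:, 3 * h :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_new = o * tc
            steps.append((i, f, g, o, c_prev, tc, h_prev))
            hs[:, step] = h_new
            h_prev, c_prev = h_new, c
        self._cache = (x, steps)
        return hs

    def backward(self, grad_hs: np.ndarray) -> np.ndarray:
        """grad_hs: (N, T, hidden_size) → gradient wrt the input sequence."""
        x, steps = self._cache
        n, t, _ = x.shape
        h = self.hidden_size
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = steps[step]
            dh = grad_hs[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.w_ih.grad += dgates.T @ x[:, step]
            self.w_hh.grad += dgates.T @ h_prev
            self.bias.grad += dgates.sum(axis=0)
            dx[:, step] = dgates @ self.w_ih.data
            dh_next = dgates @ self.w_hh.data
            dc_next = dc * f
        return dx


class LSTM(Module):
    """Stacked LSTM; ``forward`` returns the last step's top-layer hidden state."""

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        num_layers: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.layers: List[_LSTMLayer] = []
        for layer_idx in range(num_layers):
            layer = _LSTMLayer(
                input_size if layer_idx == 0 else hidden_size, hidden_size, rng
            )
            self.register(f"layer{layer_idx}", layer)
            self.layers.append(layer)
        self._t = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.input_size:
            raise ValueError(
                f"expected (N, T, {self.input_size}) input, got {x.shape}"
            )
        self._t = x.shape[1]
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x[:, -1]

    def backward(self, grad_last: np.ndarray) -> np.ndarray:
        n = grad_last.shape[0]
        grad = np.zeros((n, self._t, self.hidden_size), dtype=grad_last.dtype)
        grad[:, -1] = grad_last
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
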