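"""LSTM and GRU cells.

The LSTM follows the concatenated-gate formulation: every gate reads
``[h_{t-1}, x_t]``,

    f_t = sigmoid(W_f [h,x] + b_f)        i_t = sigmoid(W_i [h,x] + b_i)
    c~_t = tanh(W_C [h,x] + b_C)          c_t = f_t * c_{t-1} + i_t * c~_t
    o_t = sigmoid(W_o [h,x] + b_o)        h_t = o_t * tanh(c_t)

and the GRU uses separate input/recurrent matrices with the reset gate
applied to the recurrent term inside the candidate:

    z_t = sigmoid(W_z x_t + U_z h_{t-1})
    r_t = sigmoid(W_r x_t + U_r h_{t-1})
    h~_t = tanh(W x_t + r_t * (U h_{t-1}))
    h_t = (1 - z_t) * h_{t-1} + z_t * h~_t

The :class:`LSTMEncoder` module supports full backpropagation through time
so acoustic encoders can be trained end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ..errors import ShapeError
from .layers import Dense, Module, Param

__all__ = [
    "LSTMCellParams",
    "GRUCellParams",
    "init_lstm_params",
    "init_gru_params",
    "lstm_step",
    "lstm_encode",
    "gru_step",
    "gru_encode",
    "LSTMEncoder",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


@dataclass
class LSTMCellParams:
    """Gate weights over ``[h_{t-1}, x_t]``; each W is (hidden, hidden+input)."""

    W_f: Param
    W_i: Param
    W_C: Param
    W_o: Param
    b_f: Param
    b_i: Param
    b_C: Param
    b_o: Param

    @property
    def hidden_size(self) -> int:
        return self.W_f.value.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.value.shape[1] - self.W_f.value.shape[0]

    def params(self) -> list[Param]:
        return [getattr(self, f.name) for f in fields(self)]


@dataclass
class GRUCellParams:
    """GRU weights: W_* act on x_t (hidden, input), U_* on h (hidden, hidden)."""

    W_z: Param
    U_z: Param
    W_r: Param
    U_r: Param
    W: Param
    U: Param

    @property
    def hidden_size(self) -> int:
        return self.U_z.value.shape[0]

    def params(self) -> list[Param]:
        return [getattr(self, f.name) for f in fields(self)]


def init_lstm_params(
    input_size: int, hidden_size: int, rng: np.random.Generator, scale: float = 0.2
) -> LSTMCellParams:
    """Seeded uniform initialization scaled by ``1 / sqrt(fan_in)``."""
    fan = np.sqrt(hidden_size + input_size)

    def w():
        return Param(
            rng.uniform(-scale, scale, (hidden_size, hidden_size + input_size)) / fan * 4.0
        )

    def b():
        return Param(np.zeros(hidden_size))

    return LSTMCellParams(W_f=w(), W_i=w(), W_C=w(), W_o=w(), b_f=b(), b_i=b(), b_C=b(), b_o=b())


def init_gru_params(
    input_size: int, hidden_size: int, rng: np.random.Generator, scale: float = 0.2
) -> GRUCellParams:
    def w(cols):
        return Param(rng.uniform(-scale, scale, (hidden_size, cols)))

    return GRUCellParams(
        W_z=w(input_size), U_z=w(hidden_size),
        W_r=w(input_size), U_r=w(hidden_size),
        W=w(input_size), U=w(hidden_size),
    )


def lstm_step(x_t, h_prev, c_prev, params: LSTMCellParams):
    """One LSTM step; returns ``(h_t, c_t)``.  Inputs are 1-D vectors."""
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if x_t.size != params.input_size:
        raise ShapeError(
            f"LSTM expects input size {params.input_size}, got {x_t.size}"
        )
    z = np.concatenate([h_prev, x_t])
    f = _sigmoid(params.W_f.value @ z + params.b_f.value)
    i = _sigmoid(params.W_i.value @ z + params.b_i.value)
    c_tilde = np.tanh(params.W_C.value @ z + params.b_C.value)
    c = f * c_prev + i * c_tilde
    o = _sigmoid(params.W_o.value @ z + params.b_o.value)
    h = o * np.tanh(c)
    return h, c


def lstm_encode(sequence: np.ndarray, params: LSTMCellParams, head: Dense) -> np.ndarray:
    """Run the LSTM over a ``(frames, features)`` sequence; return the final
    hidden state passed through the dense head."""
    sequence = np.asarray(sequence, dtype=np.float64)
    if sequence.ndim != 2 or sequence.shape[0] == 0:
        raise ShapeError(f"expected non-empty (frames, features), got {sequence.shape}")
    h = np.zeros(params.hidden_size)
    c = np.zeros(params.hidden_size)
    for t in range(sequence.shape[0]):
        h, c = lstm_step(sequence[t], h, c, params)
    return head.forward(h)


def gru_step(x_t, h_prev, params: GRUCellParams) -> np.ndarray:
    """One GRU step on 1-D vectors."""
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if x_t.size != params.W_z.value.shape[1]:
        raise ShapeError(
            f"GRU expects input size {params.W_z.value.shape[1]}, got {x_t.size}"
        )
    if h_prev.size != params.hidden_size:
        raise ShapeError(
            f"GRU expects hidden size {params.hidden_size}, got {h_prev.size}"
        )
    z = _sigmoid(params.W_z.value @ x_t + params.U_z.value @ h_prev)
    r = _sigmoid(params.W_r.value @ x_t + params.U_r.value @ h_prev)
    h_tilde = np.tanh(params.W.value @ x_t + r * (params.U.value @ h_prev))
    return (1.0 - z) * h_prev + z * h_tilde


def gru_encode(sequence: np.ndarray, params: GRUCellParams) -> np.ndarray:
    """Final hidden state of a GRU run over ``(frames, features)``."""
    h = np.zeros(params.hidden_size)
    for t in range(np.asarray(sequence).shape[0]):
        h = gru_step(sequence[t], h, params)
    return h


class LSTMEncoder(Module):
    """Batched LSTM returning the final hidden state, with full BPTT.

    Input ``(N, T, F)`` (or a single ``(T, F)`` sequence), output ``(N, H)``.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.cell = init_lstm_params(input_size, hidden_size, rng)
        self._cache = None

    def params(self) -> list[Param]:
        return self.cell.params()

    def named_params(self, prefix: str = "") -> dict[str, Param]:
        names = ["W_f", "W_i", "W_C", "W_o", "b_f", "b_i", "b_C", "b_o"]
        return {f"{prefix}{n}": getattr(self.cell, n) for n in names}

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        n, T, feat = x.shape
        H = self.cell.hidden_size
        if feat != self.cell.input_size:
            raise ShapeError(
                f"LSTM expects feature size {self.cell.input_size}, got {feat}"
            )
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        steps = []
        for t in range(T):
            z = np.concatenate([h, x[:, t, :]], axis=1)
            f = _sigmoid(z @ self.cell.W_f.value.T + self.cell.b_f.value)
            i = _sigmoid(z @ self.cell.W_i.value.T + self.cell.b_i.value)
            c_tilde = np.tanh(z @ self.cell.W_C.value.T + self.cell.b_C.value)
            o = _sigmoid(z @ self.cell.W_o.value.T + self.cell.b_o.value)
            c_new = f * c + i * c_tilde
            tanh_c = np.tanh(c_new)
            steps.append((z, f, i, c_tilde, o, c, c_new, tanh_c))
            h = o * tanh_c
            c = c_new
        self._cache = (steps, squeeze, n, H)
        return h[0] if squeeze else h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        steps, squeeze, n, H = self._cache
        grad = np.asarray(grad, dtype=np.float64)
        if squeeze:
            grad = grad[None]
        dh = grad
        dc = np.zeros((n, H))
        dx = np.zeros((n, len(steps), self.cell.input_size))
        for t in range(len(steps) - 1, -1, -1):
            z, f, i, c_tilde, o, c_prev, c_new, tanh_c = steps[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            df = dc * c_prev
            di = dc * c_tilde
            dct = dc * i
            dc_prev = dc * f
            da_f = df * f * (1.0 - f)
            da_i = di * i * (1.0 - i)
            da_c = dct * (1.0 - c_tilde**2)
            da_o = do * o * (1.0 - o)
            self.cell.W_f.grad += da_f.T @ z
            self.cell.W_i.grad += da_i.T @ z
            self.cell.W_C.grad += da_c.T @ z
            self.cell.W_o.grad += da_o.T @ z
            self.cell.b_f.grad += da_f.sum(axis=0)
            self.cell.b_i.grad += da_i.sum(axis=0)
            self.cell.b_C.grad += da_c.sum(axis=0)
            self.cell.b_o.grad += da_o.sum(axis=0)
            dz = (
                da_f @ self.cell.W_f.value
                + da_i @ self.cell.W_i.value
                + da_c @ self.cell.W_C.value
                + da_o @ self.cell.W_o.value
            )
            dh = dz[:, :H]
            dx[:, t, :] = dz[:, H:]
            dc = dc_prev
        return dx[0] if squeeze else dx
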