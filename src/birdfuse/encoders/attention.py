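"""Scaled dot-product attention and sinusoidal positional encoding."""

from __future__ import annotations

import numpy as np

from ..errors import InvalidConfigError, ShapeError
from .layers import Dense, Param

__all__ = ["attention", "positional_encoding", "AttentionBlock"]


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """``softmax(Q K^T / sqrt(d_k)) V`` with row-wise softmax."""
    Q, K, V = (np.atleast_2d(np.asarray(m, dtype=np.float64)) for m in (Q, K, V))
    if Q.shape[1] != K.shape[1]:
        raise ShapeError(f"Q has d_k={Q.shape[1]} but K has d_k={K.shape[1]}")
    if K.shape[0] != V.shape[0]:
        raise ShapeError(f"K has {K.shape[0]} rows but V has {V.shape[0]}")
    scores = Q @ K.T / np.sqrt(K.shape[1])
    scores -= scores.max(axis=1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=1, keepdims=True)
    return weights @ V


def positional_encoding(length: int, d: int) -> np.ndarray:
    """Sinusoidal table: ``PE[pos, 2i] = sin(pos / 10000^(2i/d))`` and the
    cosine in odd columns."""
    if d % 2 != 0:
        raise InvalidConfigError(f"positional encoding dimension must be even, got {d}")
    pos = np.arange(length)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / (10000.0 ** (2.0 * i / d))
    table = np.zeros((length, d))
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle)
    return table


class AttentionBlock:
    """Single-head self-attention with learned projections and positional
    encoding — an optional acoustic encoder variant."""

    def __init__(self, input_size: int, d_k: int, rng: np.random.Generator):
        self.d_k = d_k
        self.proj_q = Dense(input_size, d_k, rng=rng)
        self.proj_k = Dense(input_size, d_k, rng=rng)
        self.proj_v = Dense(input_size, d_k, rng=rng)

    def params(self) -> list[Param]:
        return self.proj_q.params() + self.proj_k.params() + self.proj_v.params()

    def forward(self, sequence: np.ndarray) -> np.ndarray:
        """Positional-encoded self-attention; returns (frames, d_k) context."""
        x = np.atleast_2d(np.asarray(sequence, dtype=np.float64))
        pe = positional_encoding(x.shape[0], x.shape[1] - x.shape[1] % 2)
        x = x.copy()
        x[:, : pe.shape[1]] += pe
        return attention(self.proj_q(x), self.proj_k(x), self.proj_v(x))
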