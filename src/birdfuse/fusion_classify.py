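"""Early/late fusion algebra, softmax classification head and loss.

Early fusion concatenates the visual embedding (first) and the acoustic
embedding (second) into one vector for a single classifier.  Late fusion
forms the convex combination ``alpha * p_visual + (1 - alpha) * p_acoustic``
of the two per-modality probability vectors; ``alpha`` is chosen on a fixed
grid {0, 0.05, ..., 1} by validation accuracy, ties to the smallest value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError, InvalidInputError, ShapeError

__all__ = [
    "Embedding",
    "FusedVector",
    "ClassifierHead",
    "ALPHA_GRID",
    "early_fuse",
    "softmax",
    "classify",
    "cross_entropy",
    "late_fuse",
    "optimize_alpha",
    "predict_label",
]

PROB_CLIP = 1e-12
ALPHA_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 2)


@dataclass(frozen=True)
class Embedding:
    """Fixed-length modality representation."""

    values: np.ndarray = field(repr=False)
    modality: str = "visual"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64).ravel()
        if values.size == 0:
            raise InvalidInputError("embedding must be non-empty")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("embedding contains non-finite values")
        if self.modality not in ("visual", "acoustic"):
            raise InvalidInputError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FusedVector:
    """Concatenation ``[visual, acoustic]`` with recoverable slices."""

    values: np.ndarray = field(repr=False)
    visual_dim: int = 0
    acoustic_dim: int = 0

    @property
    def visual(self) -> np.ndarray:
        return self.values[: self.visual_dim]

    @property
    def acoustic(self) -> np.ndarray:
        return self.values[self.visual_dim :]

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ClassifierHead:
    """Dense softmax head: ``softmax(W_c @ f + b)``; W_c is (classes, dim)."""

    W_c: np.ndarray
    b: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.W_c.shape[0]


def early_fuse(v: Embedding, a: Embedding) -> FusedVector:
    """Concatenate visual-first; lossless (both inputs recoverable by slicing)."""
    if v.modality == a.modality:
        raise InvalidInputError(f"both embeddings claim modality {v.modality!r}")
    visual, acoustic = (v, a) if v.modality == "visual" else (a, v)
    return FusedVector(
        values=np.concatenate([visual.values, acoustic.values]),
        visual_dim=len(visual),
        acoustic_dim=len(acoustic),
    )


def softmax(z: np.ndarray) -> np.ndarray:
    """Exp-normalize with max subtraction; rows sum to 1."""
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise InvalidInputError("softmax of an empty vector")
    if not np.all(np.isfinite(z)):
        raise InvalidInputError("softmax input contains non-finite values")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def classify(f: FusedVector | Embedding | np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Per-class probabilities ``softmax(W_c f + b)``."""
    x = f.values if isinstance(f, (FusedVector, Embedding)) else np.asarray(f, dtype=np.float64)
    if x.shape[-1] != head.W_c.shape[1]:
        raise ShapeError(
            f"classifier expects dim {head.W_c.shape[1]}, got {x.shape[-1]}"
        )
    return softmax(x @ head.W_c.T + head.b)


def cross_entropy(true_onehot: np.ndarray, predicted: np.ndarray) -> float:
    """Mean over rows of ``-sum_j y_j log p_j`` (nats); probabilities are
    clipped at 1e-12 before the log."""
    y = np.atleast_2d(np.asarray(true_onehot, dtype=np.float64))
    p = np.atleast_2d(np.asarray(predicted, dtype=np.float64))
    if y.shape != p.shape:
        raise ShapeError(f"labels {y.shape} vs predictions {p.shape}")
    logp = np.log(np.clip(p, PROB_CLIP, None))
    return float(-(y * logp).sum(axis=1).mean())


def _check_probs(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < -1e-12) or abs(p.sum(axis=-1).max() - 1.0) > 1e-6 or abs(
        p.sum(axis=-1).min() - 1.0
    ) > 1e-6:
        raise InvalidInputError(f"{name} is not a valid probability vector")
    return p


def late_fuse(p_visual: np.ndarray, p_acoustic: np.ndarray, alpha: float) -> np.ndarray:
    """Convex combination ``alpha p_visual + (1 - alpha) p_acoustic``."""
    if not (0.0 <= alpha <= 1.0):
        raise InvalidConfigError(f"alpha must be in [0, 1], got {alpha}")
    pv = _check_probs(p_visual, "p_visual")
    pa = _check_probs(p_acoustic, "p_acoustic")
    if pv.shape != pa.shape:
        raise ShapeError(f"probability shapes differ: {pv.shape} vs {pa.shape}")
    return alpha * pv + (1.0 - alpha) * pa


def predict_label(p: np.ndarray) -> int | np.ndarray:
    """Argmax class index; ties break to the lowest index."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim == 1:
        return int(np.argmax(p))
    return np.argmax(p, axis=1)


def optimize_alpha(
    val_visual_probs: np.ndarray,
    val_acoustic_probs: np.ndarray,
    val_labels: np.ndarray,
) -> float:
    """Grid-search the late-fusion weight on a validation set.

    Evaluates accuracy at every alpha in {0, 0.05, ..., 1} and returns the
    smallest alpha achieving the maximum, so the result always dominates
    both single-modality endpoints.
    """
    labels = np.asarray(val_labels)
    if labels.size == 0:
        raise InvalidInputError("validation set is empty")
    pv = np.atleast_2d(val_visual_probs)
    pa = np.atleast_2d(val_acoustic_probs)
    best_alpha, best_acc = 0.0, -1.0
    for alpha in ALPHA_GRID:
        fused = late_fuse(pv, pa, float(alpha))
        acc = float(np.mean(predict_label(fused) == labels))
        if acc > best_acc + 1e-12:
            best_alpha, best_acc = float(alpha), acc
    return best_alpha
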