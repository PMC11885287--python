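"""Correlation-based feature selection.

Each feature is scored by the maximum absolute Pearson correlation with the
one-vs-rest 0/1 indicator of any class; the top ``k`` (default 21) features
by score are retained, with ties broken by ascending feature name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .audio_features.features import FeatureTable
from .errors import InvalidInputError

__all__ = [
    "CorrelationReport",
    "SelectionResult",
    "class_correlation",
    "select_top_k",
    "save_selection",
    "load_selection",
]

DEFAULT_K = 21


@dataclass(frozen=True)
class CorrelationReport:
    """Per-feature score in [0, 1]."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.scores.items():
            if not (0.0 <= s <= 1.0 + 1e-12):
                raise InvalidInputError(f"score for {name!r} outside [0, 1]: {s}")


@dataclass(frozen=True)
class SelectionResult:
    ranked: tuple[str, ...]
    k: int

    @property
    def selected(self) -> tuple[str, ...]:
        return self.ranked[: self.k]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom <= 0.0:
        return 0.0  # zero-variance convention
    return float((xd * yd).sum() / denom)


def class_correlation(tables: Sequence[FeatureTable]) -> CorrelationReport:
    """Score every feature by max-|Pearson| against one-vs-rest indicators.

    Requires at least 3 clips spanning at least 2 distinct classes; features
    with zero variance (or against a zero-variance indicator) score 0.
    """
    if len(tables) < 3:
        raise InvalidInputError(f"need >= 3 clips, got {len(tables)}")
    labels = [t.label for t in tables]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise InvalidInputError("need >= 2 distinct classes for class correlation")
    names = tables[0].names
    for t in tables[1:]:
        if t.names != names:
            raise InvalidInputError("feature tables have inconsistent columns")
    X = np.stack([t.vector(names) for t in tables])
    indicators = np.stack(
        [np.array([1.0 if l == c else 0.0 for l in labels]) for c in classes]
    )
    scores = {}
    for j, name in enumerate(names):
        scores[name] = max(
            abs(_pearson(X[:, j], indicators[c])) for c in range(len(classes))
        )
    return CorrelationReport(scores=scores)


def select_top_k(report: CorrelationReport, k: int = DEFAULT_K) -> SelectionResult:
    """Rank by descending score (ties by ascending name) and keep the top k."""
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")
    if not report.scores:
        raise InvalidInputError("cannot select from an empty correlation report")
    ranked = tuple(
        sorted(report.scores, key=lambda name: (-report.scores[name], name))
    )
    return SelectionResult(ranked=ranked, k=min(k, len(ranked)))


def save_selection(result: SelectionResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"ranked": list(result.ranked), "k": result.k}, fh, indent=2)
        fh.write("\n")


def load_selection(path: str | Path) -> SelectionResult:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return SelectionResult(ranked=tuple(payload["ranked"]), k=int(payload["k"]))
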