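"""Evaluation metrics: accuracy, macro precision/recall/F1, confusion matrix."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..errors import InvalidInputError

__all__ = ["MetricsReport", "evaluate", "label_encode", "label_decode"]


def label_encode(species_names) -> dict[str, int]:
    """Sorted-unique species names -> 0..K-1."""
    names = list(species_names)
    if not names:
        raise InvalidInputError("cannot label-encode an empty name list")
    return {name: i for i, name in enumerate(sorted(set(names)))}


def label_decode(encoding: dict[str, int]) -> dict[int, str]:
    return {i: name for name, i in encoding.items()}


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray = field(repr=False)  # rows = true class, cols = predicted
    class_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "class_names": list(self.class_names),
            "confusion": self.confusion.astype(int).tolist(),
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def save_confusion_csv(self, path: str | Path) -> None:
        names = self.class_names or tuple(
            f"class{i}" for i in range(self.confusion.shape[0])
        )
        lines = ["true\\pred," + ",".join(names)]
        for i, name in enumerate(names):
            lines.append(name + "," + ",".join(str(int(v)) for v in self.confusion[i]))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def evaluate(
    predictions,
    labels,
    n_classes: int | None = None,
    class_names: tuple[str, ...] = (),
) -> MetricsReport:
    """Compute accuracy and unweighted macro precision/recall/F1.

    ``predictions`` and ``labels`` are integer class indices.  A class never
    predicted gets precision 0; a class absent from ``labels`` gets recall 0.
    """
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(labels, dtype=int)
    if pred.shape != true.shape:
        raise InvalidInputError(
            f"{pred.size} predictions vs {true.size} labels"
        )
    if pred.size == 0:
        raise InvalidInputError("cannot evaluate an empty prediction set")
    k = n_classes or int(max(pred.max(), true.max())) + 1
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (true, pred), 1)

    tp = np.diag(confusion).astype(np.float64)
    support = confusion.sum(axis=1).astype(np.float64)
    predicted = confusion.sum(axis=0).astype(np.float64)
    precision = np.divide(tp, predicted, out=np.zeros(k), where=predicted > 0)
    recall = np.divide(tp, support, out=np.zeros(k), where=support > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom, out=np.zeros(k), where=denom > 0)
    return MetricsReport(
        accuracy=float(np.mean(pred == true)),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        confusion=confusion,
        class_names=tuple(class_names),
    )
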