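"""Per-clip feature tables, summarization and the SET1-SET4 feature sets.

Feature naming and order
------------------------
Per-frame descriptors are summarized to ``<name>_mean`` / ``<name>_std``
(population standard deviation).  The canonical column order of a full
table is:

1. spectral descriptors: ``centroid``, ``bandwidth``, ``rolloff``, ``flux``,
   ``zcr`` (mean then std for each),
2. clip-level scalars: ``tempo_bpm``, ``harmonic_ratio``,
3. ``chroma00`` .. ``chroma11`` (mean/std),
4. MFCCs: ``mfcc01`` .. ``mfcc13``, ``mfcc_d01`` .. ``mfcc_d13``,
   ``mfcc_dd01`` .. ``mfcc_dd13`` (mean/std),
5. GFCCs: ``gfcc01`` .. ``gfcc13`` (mean/std).

Feature sets:

* SET1 - the five spectral descriptors (10 columns),
* SET2 - harmonic ratio, tempo, chroma and MFCC summaries (104 columns),
* SET3 - GFCC summaries (26 columns),
* SET4 - the columns named by a selection result (21 by default).

An optional user hook may register extra clip-level features (the table is
schema-checked, so unknown requested names fail loudly).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np

from ..errors import InvalidInputError, SchemaError
from .cepstral import gfcc_block, mfcc_block
from .io import AudioClip
from .spectral import FrameSpec, chroma, spectral_descriptors, spectrogram, tempo_harmonics

__all__ = [
    "FeatureTable",
    "FEATURE_SET_IDS",
    "summarize",
    "extract_clip_features",
    "feature_set_members",
    "build_feature_set",
    "write_feature_csv",
    "read_feature_csv",
]

FEATURE_SET_IDS = ("SET1", "SET2", "SET3", "SET4")

_DESCRIPTOR_NAMES = ("centroid", "bandwidth", "rolloff", "flux", "zcr")
_SCALAR_NAMES = ("tempo_bpm", "harmonic_ratio")
_CHROMA_NAMES = tuple(f"chroma{i:02d}" for i in range(12))
_MFCC_NAMES = (
    tuple(f"mfcc{i:02d}" for i in range(1, 14))
    + tuple(f"mfcc_d{i:02d}" for i in range(1, 14))
    + tuple(f"mfcc_dd{i:02d}" for i in range(1, 14))
)
_GFCC_NAMES = tuple(f"gfcc{i:02d}" for i in range(1, 14))


def _mean_std(names: Iterable[str]) -> tuple[str, ...]:
    out: list[str] = []
    for n in names:
        out.extend((f"{n}_mean", f"{n}_std"))
    return tuple(out)


@dataclass
class FeatureTable:
    """Named per-clip features plus the species label."""

    features: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        for name, value in self.features.items():
            if not np.isfinite(value):
                raise InvalidInputError(f"feature {name!r} is not finite: {value}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.features)

    def vector(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = tuple(names) if names is not None else self.names
        missing = [n for n in names if n not in self.features]
        if missing:
            raise SchemaError(f"feature table is missing {missing[0]!r}")
        return np.array([self.features[n] for n in names], dtype=np.float64)


def summarize(per_frame: Mapping[str, np.ndarray], label: str = "") -> FeatureTable:
    """Collapse per-frame features to clip-level mean/std columns.

    Each entry may be 1-D ``(frames,)`` or 2-D ``(frames, dims)``; 2-D
    entries expand to ``<name><dim+1:02d>``.  Standard deviation uses the
    population convention, so a single frame yields std 0.
    """
    out: dict[str, float] = {}
    for name, values in per_frame.items():
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[:, None]
            cols = [name]
        else:
            cols = [f"{name}{j + 1:02d}" for j in range(arr.shape[1])]
        if arr.shape[0] < 1:
            raise InvalidInputError(f"feature {name!r} has no frames")
        means = arr.mean(axis=0)
        stds = arr.std(axis=0)  # population std
        for j, col in enumerate(cols):
            out[f"{col}_mean"] = float(means[j])
            out[f"{col}_std"] = float(stds[j])
    return FeatureTable(features=out, label=label)


def extract_clip_features(
    clip: AudioClip,
    label: str = "",
    frame_spec: FrameSpec | None = None,
    extra_features: Callable[[AudioClip], Mapping[str, float]] | None = None,
) -> FeatureTable:
    """Compute the full canonical feature table for one clip.

    ``extra_features`` is a hook for user-supplied clip-level descriptors
    (appended after the canonical columns).
    """
    frame_spec = frame_spec or FrameSpec()
    spect = spectrogram(clip, frame_spec)
    table: dict[str, float] = {}

    desc = spectral_descriptors(spect, clip)
    for name in _DESCRIPTOR_NAMES:
        table.update(summarize({name: desc[name]}).features)

    th = tempo_harmonics(clip, frame_spec)
    table["tempo_bpm"] = th["tempo_bpm"]
    table["harmonic_ratio"] = th["harmonic_ratio"]

    chroma_frames = chroma(spect)
    for j in range(12):
        table.update(summarize({f"chroma{j:02d}": chroma_frames[:, j]}).features)

    mfcc = mfcc_block(spect)
    for j, name in enumerate(_MFCC_NAMES):
        table.update(summarize({name: mfcc[:, j]}).features)

    gfcc = gfcc_block(clip, spec=frame_spec)
    for j, name in enumerate(_GFCC_NAMES):
        table.update(summarize({name: gfcc[:, j]}).features)

    if extra_features is not None:
        for name, value in extra_features(clip).items():
            table[str(name)] = float(value)
    return FeatureTable(features=table, label=label)


def feature_set_members(set_id: str, selection=None) -> tuple[str, ...]:
    """Ordered member column names of a feature set."""
    if set_id == "SET1":
        return _mean_std(_DESCRIPTOR_NAMES)
    if set_id == "SET2":
        return _SCALAR_NAMES + _mean_std(_CHROMA_NAMES) + _mean_std(_MFCC_NAMES)
    if set_id == "SET3":
        return _mean_std(_GFCC_NAMES)
    if set_id == "SET4":
        if selection is None:
            raise InvalidInputError("SET4 requires a SelectionResult")
        return tuple(selection.selected)
    raise SchemaError(f"unknown feature set id {set_id!r}; expected one of {FEATURE_SET_IDS}")


def build_feature_set(table: FeatureTable, set_id: str, selection=None) -> np.ndarray:
    """Assemble the ordered feature vector of ``set_id`` from a table."""
    return table.vector(feature_set_members(set_id, selection))


def write_feature_csv(tables: Iterable[FeatureTable], path: str | Path) -> None:
    """Write tables as CSV: one row per clip, feature columns then ``species``."""
    tables = list(tables)
    if not tables:
        raise InvalidInputError("no feature tables to write")
    names = tables[0].names
    for t in tables[1:]:
        if t.names != names:
            raise SchemaError("feature tables have inconsistent columns")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(names) + ["species"])
        for t in tables:
            writer.writerow([repr(t.features[n]) for n in names] + [t.label])


def read_feature_csv(path: str | Path) -> list[FeatureTable]:
    """Read a feature CSV produced by :func:`write_feature_csv`."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[-1] != "species":
            raise SchemaError(f"feature CSV {path} lacks a trailing 'species' column")
        names = header[:-1]
        tables = []
        for row in reader:
            features = {n: float(v) for n, v in zip(names, row[:-1])}
            tables.append(FeatureTable(features=features, label=row[-1]))
    return tables
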