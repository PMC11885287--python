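"""Dataset manifest: CSV rows of (id, species, image_path, audio_path, split)."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

from ..errors import FormatError, InvalidInputError, SchemaError

__all__ = ["ManifestRow", "DatasetManifest", "read_manifest", "write_manifest"]

MANIFEST_COLUMNS = ("id", "species", "image_path", "audio_path", "split")
SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class ManifestRow:
    id: str
    species: str
    image_path: str
    audio_path: str
    split: str

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise InvalidInputError(
                f"row {self.id!r}: split must be one of {SPLITS}, got {self.split!r}"
            )


@dataclass(frozen=True)
class DatasetManifest:
    """Ordered manifest rows plus the directory paths are relative to."""

    rows: tuple[ManifestRow, ...]
    root: Path = Path(".")

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.id in seen:
                raise InvalidInputError(f"duplicate manifest id {row.id!r}")
            seen.add(row.id)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[ManifestRow]:
        return iter(self.rows)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({row.species for row in self.rows}))

    def subset(self, split: str) -> "DatasetManifest":
        if split not in SPLITS:
            raise InvalidInputError(f"unknown split {split!r}")
        return DatasetManifest(
            rows=tuple(r for r in self.rows if r.split == split), root=self.root
        )

    def resolve_image(self, row: ManifestRow) -> Path:
        return self.root / row.image_path

    def resolve_audio(self, row: ManifestRow) -> Path:
        return self.root / row.audio_path


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write the manifest as UTF-8 CSV with LF line endings."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for row in manifest.rows:
            writer.writerow(
                [row.id, row.species, row.image_path, row.audio_path, row.split]
            )


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest CSV; relative paths resolve against the CSV's directory.

    Columns are keyed by name, so header order is free; a missing column is
    a :class:`SchemaError` and duplicate ids are an :class:`InvalidInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest file {path} does not exist")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [c for c in MANIFEST_COLUMNS if c not in fields]
        if missing:
            raise SchemaError(f"manifest {path} is missing column {missing[0]!r}")
        rows = tuple(
            ManifestRow(
                id=r["id"],
                species=r["species"],
                image_path=r["image_path"],
                audio_path=r["audio_path"],
                split=r["split"],
            )
            for r in reader
        )
    return DatasetManifest(rows=rows, root=path.parent)


def make_manifest(rows: Sequence[ManifestRow], root: str | Path = ".") -> DatasetManifest:
    return DatasetManifest(rows=tuple(rows), root=Path(root))
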