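"""Single-file versioned model archives (.npz with embedded JSON metadata).

The archive stores every model array plus a ``__meta__`` JSON payload with
the format version, model kind, class ordering, the late-fusion alpha when
applicable, and a content hash of the arrays for integrity checking.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np

from ..errors import ModelIOError
from ..train_eval.models import MODEL_CLASSES

__all__ = ["save_model", "load_model", "ARCHIVE_VERSION"]

ARCHIVE_VERSION = 1


def _content_hash(arrays: dict[str, np.ndarray]) -> str:
    digest = hashlib.sha256()
    for key in sorted(arrays):
        digest.update(key.encode())
        digest.update(np.ascontiguousarray(arrays[key]).tobytes())
    return digest.hexdigest()


def save_model(model, path: str | Path, extra_meta: dict | None = None) -> None:
    """Persist any trained model as one ``.npz`` archive."""
    arrays, meta = model.state()
    payload = {
        "version": ARCHIVE_VERSION,
        "kind": model.kind,
        "content_hash": _content_hash(arrays),
        "meta": meta,
    }
    if extra_meta:
        payload["extra"] = extra_meta
    np.savez(
        path,
        __meta__=np.frombuffer(
            json.dumps(payload, sort_keys=True).encode(), dtype=np.uint8
        ),
        **arrays,
    )


def load_model(path: str | Path, expected_kind: str | None = None):
    """Restore a model archive; predictions are bit-identical to pre-save.

    Raises :class:`ModelIOError` on a version or kind mismatch and emits an
    integrity warning if the stored content hash does not match the arrays.
    """
    path = Path(path)
    try:
        with np.load(path) as archive:
            if "__meta__" not in archive:
                raise ModelIOError(f"{path} is not a model archive (no metadata)")
            payload = json.loads(bytes(archive["__meta__"]).decode())
            arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    except (OSError, ValueError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot read model archive {path}: {exc}") from exc
    version = payload.get("version")
    if version != ARCHIVE_VERSION:
        raise ModelIOError(
            f"unsupported archive version {version!r} (supported: {ARCHIVE_VERSION})"
        )
    kind = payload.get("kind")
    if expected_kind is not None and kind != expected_kind:
        raise ModelIOError(
            f"archive {path} holds a {kind!r} model, expected {expected_kind!r}"
        )
    if kind not in MODEL_CLASSES:
        raise ModelIOError(f"archive {path} has unknown model kind {kind!r}")
    if _content_hash(arrays) != payload.get("content_hash"):
        warnings.warn(
            f"model archive {path} failed its integrity check "
            "(metadata hash does not match array contents)",
            UserWarning,
            stacklevel=2,
        )
    return MODEL_CLASSES[kind].from_state(arrays, payload["meta"])
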