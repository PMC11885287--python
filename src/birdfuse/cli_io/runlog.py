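"""JSON-lines run log: timestamped stage events with config hash and seed."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

__all__ = ["RunLog"]


def _file_hash(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()[:16]


class RunLog:
    """Appends one JSON object per event to ``run.log.jsonl``."""

    def __init__(self, path: str | Path, config_hash: str = "", seed: int = 0):
        from .. import __version__

        self.path = Path(path)
        self.config_hash = config_hash
        self.seed = seed
        self.version = __version__

    def event(self, stage: str, message: str, **extra) -> None:
        record = {
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "stage": stage,
            "message": message,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
        }
        record.update(extra)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(record, sort_keys=True) + "\n")

    def artifact(self, stage: str, path: str | Path) -> None:
        """Log a written artifact with its content hash."""
        path = Path(path)
        self.event(stage, f"wrote {path}", artifact=str(path), content_hash=_file_hash(path))
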