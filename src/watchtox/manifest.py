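"""Run manifests: a reproducibility record written beside every output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

__all__ = ["RunManifest", "file_digest", "write_manifest"]


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seeds: list[int]
    input_digests: dict[str, str] = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        command: str,
        config: Mapping,
        seeds: Sequence[int],
        inputs: Sequence[str | Path] = (),
    ) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            command=command,
            config_hash=hashlib.sha256(blob).hexdigest(),
            seeds=list(seeds),
            input_digests={str(p): file_digest(p) for p in inputs},
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2)
        fh.write("\n")
    return path
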