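"""Run manifests: enough metadata to replay any stochastic output exactly."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version


def _tool_version() -> str:
    try:
        return version("rdapso")
    except PackageNotFoundError:
        return "unknown"


def config_hash(config: dict) -> str:
    """Stable SHA-256 digest of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record attached to every stochastic output."""

    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)  # path -> digest

    def to_dict(self) -> dict:
        return {
            "tool": "rdapso",
            "version": _tool_version(),
            "seed": self.seed,
            "config": self.config,
            "config_hash": config_hash(self.config),
            "inputs": self.inputs,
            "created": datetime.now(timezone.utc).isoformat(),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def for_inputs(seed: int, config: dict, paths) -> "RunManifest":
        return RunManifest(seed=seed, config=config,
                           inputs={str(p): file_digest(p) for p in paths})
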