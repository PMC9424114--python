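"""Run manifests: inputs, config hash, seed, version, per invocation."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    config: dict,
    seed: int | None,
    inputs: list | None = None,
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "inputs": {str(p): _digest(Path(p)) for p in (inputs or []) if Path(p).exists()},
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
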