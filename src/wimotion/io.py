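"""Shared file I/O: CSV/JSON with metadata headers, stream files.

Every CSV the tools write starts with ``#``-prefixed metadata lines
(tool version, config hash, the configuration itself) so a result file
is self-describing; readers skip those lines transparently. CSV dialect:
comma separated, dot decimal, one header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Dict

import pandas as pd

from . import __version__


def config_hash(config: Dict[str, Any]) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, meta: Dict[str, Any] | None = None) -> None:
    """Write a CSV with a ``#`` metadata block (version, config hash)."""
    path = Path(path)
    meta = dict(meta or {})
    lines = [f"# wimotion {__version__}"]
    if meta:
        lines.append(f"# config_hash: {config_hash(meta)}")
        for k in sorted(meta):
            lines.append(f"# {k}: {meta[k]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv`, skipping metadata lines."""
    return pd.read_csv(path, comment="#")


def write_json(obj: Any, path, meta: Dict[str, Any] | None = None) -> None:
    doc = {"tool": f"wimotion {__version__}"}
    if meta:
        doc["config"] = meta
        doc["config_hash"] = config_hash(meta)
    doc["data"] = obj
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
        fh.write("\n")


def read_json(path) -> Any:
    with open(path) as fh:
        doc = json.load(fh)
    return doc["data"] if isinstance(doc, dict) and "data" in doc else doc


def write_stream(data: bytes, path) -> None:
    Path(path).write_bytes(data)


def read_stream(path) -> bytes:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input stream not found: {p}")
    return p.read_bytes()
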