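"""Output writers: flag tables, analysis tables, plain-text report, manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "write_flag_table",
    "write_table",
    "render_text_report",
    "write_manifest",
    "file_sha256",
]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_flag_table(profiles: pd.DataFrame, path) -> None:
    """Write per-patient criterion flags as 0/1 CSV."""
    out = profiles.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path, float_format: str = "%.4g") -> None:
    df.to_csv(path, index=False, float_format=float_format)


def render_text_report(tables: Mapping[str, pd.DataFrame]) -> str:
    """Aligned plain-text rendering of the analysis tables."""
    blocks = []
    for title, df in tables.items():
        underline = "=" * len(title)
        blocks.append(f"{title}\n{underline}\n{df.to_string(index=False)}\n")
    return "\n".join(blocks)


def write_manifest(path, **fields) -> None:
    """Record run provenance (seed, config hashes, stage row counts)."""
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True, default=str))
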