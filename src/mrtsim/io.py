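"""Shared columnar text dialect.

Every file the package writes — spectra, lateral profiles, dose grids,
alignment scans — uses one format: '#'-prefixed ``key: value`` metadata
header lines, then a comma-separated table with a header row, UTF-8, '.'
decimal separator.  Metadata values round-trip through YAML so lists and
numbers come back typed.
"""

from __future__ import annotations

import io as _io

import pandas as pd
import yaml

__all__ = ["write_columns", "read_columns"]


def write_columns(path, columns: dict, metadata: dict | None = None,
                  float_format: str = "%.8g") -> None:
    """Write named columns plus a metadata header to ``path``."""
    df = pd.DataFrame(columns)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in (metadata or {}).items():
                dumped = " ".join(
                    line
                    for line in yaml.safe_dump(
                        value, default_flow_style=True, width=2**20
                    ).strip().splitlines()
                    if line.strip() != "..."  # document-end marker
                )
                fh.write(f"# {key}: {dumped}\n")
            df.to_csv(fh, index=False, float_format=float_format)
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_columns(path):
    """Read a columnar file; returns (DataFrame, metadata dict)."""
    meta = {}
    lines = []
    try:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    body = line[1:].strip()
                    if ":" in body:
                        key, _, value = body.partition(":")
                        meta[key.strip()] = yaml.safe_load(value.strip())
                else:
                    lines.append(line)
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    df = pd.read_csv(_io.StringIO("".join(lines)))
    return df, meta
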