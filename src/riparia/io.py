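"""Delimited-text tables with an embedded metadata header.

Every output table starts with a commented YAML block (lines prefixed
``# ``) carrying the fully resolved configuration and seed, so any file can
be re-run from its own header.  No timestamps are written: identical inputs
produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .flow import FlowSeries

__all__ = ["write_table", "read_table", "write_flow_series",
           "read_flow_series"]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            block = yaml.safe_dump(meta, sort_keys=True).rstrip("\n")
            for line in block.split("\n"):
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (frame, meta)."""
    from io import StringIO

    lines = Path(path).read_text().splitlines(keepends=True)
    i = 0
    meta_lines = []
    while i < len(lines) and lines[i].startswith("#"):
        meta_lines.append(lines[i].lstrip("#").rstrip("\n").removeprefix(" "))
        i += 1
    df = pd.read_csv(StringIO("".join(lines[i:])))
    meta = yaml.safe_load("\n".join(meta_lines)) if meta_lines else {}
    return df, meta or {}


def write_flow_series(series: FlowSeries, path,
                      meta: dict | None = None) -> None:
    """Water-level record as 2-column text (time in yr, level in m)."""
    df = pd.DataFrame({"time": series.times, "level": series.levels})
    base = {"units": {"time": "yr", "level": "m"}}
    if meta:
        base.update(meta)
    write_table(df, path, base)


def read_flow_series(path) -> FlowSeries:
    df, _ = read_table(path)
    if not {"time", "level"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns time,level")
    return FlowSeries(df["time"].to_numpy(float), df["level"].to_numpy(float))
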