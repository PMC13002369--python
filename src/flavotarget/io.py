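"""Readers/writers for the plain-text side formats (target CSV, GMT)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd


def write_target_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format compound->gene table as CSV (deterministic bytes)."""
    if list(table.columns) != ["compound_id", "gene_symbol"]:
        raise ValueError("target table must have columns compound_id, gene_symbol")
    table.to_csv(path, index=False, lineterminator="\n")


def read_target_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype=str)
    if list(table.columns) != ["compound_id", "gene_symbol"]:
        raise ValueError(f"{path}: expected columns compound_id, gene_symbol")
    table["gene_symbol"] = table["gene_symbol"].str.upper()
    return table


def target_table_to_lists(table: pd.DataFrame) -> dict[str, list[str]]:
    """Collapse the long table to compound -> ordered unique gene list."""
    out: dict[str, list[str]] = {}
    for cid, sub in table.groupby("compound_id", sort=True):
        seen: dict[str, None] = {}
        for g in sub["gene_symbol"]:
            seen.setdefault(str(g).upper(), None)
        out[str(cid)] = list(seen)
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, tab-separated symbols)."""
    collection: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name = fields[0]
        collection[name] = {g.strip().upper() for g in fields[2:] if g.strip()}
    return collection


def write_gmt(collection: Mapping[str, set[str]], path: str | Path,
              description: str = "na") -> None:
    lines = []
    for name in sorted(collection):
        genes = sorted(collection[name])
        lines.append("\t".join([name, description, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
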