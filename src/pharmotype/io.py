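"""Readers and writers for the package's plain-text interchange formats.

Matrices are TSV with proteins as rows and samples as columns; an empty field
is a missing value. Gene sets use the standard GMT line format
(``name<TAB>description<TAB>member1<TAB>member2...``). Interaction edges are a
three-column TSV (``protein_a``, ``protein_b``, ``score``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a proteins x samples log2 intensity matrix; NaN marks missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "protein"
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="protein", na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets as ``{name: [members...]}`` (descriptions dropped)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = fields[2:]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_edges(path: str | Path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    expected = {"protein_a", "protein_b", "score"}
    if not expected.issubset(edges.columns):
        raise ValueError(f"edge table must have columns {sorted(expected)}")
    return edges


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
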