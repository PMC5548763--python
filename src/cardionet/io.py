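"""File-format adapters: TSV matrices, feature lists, edge tables, GMT.

All tabular formats are headered, tab-separated text with LF or CRLF line
endings.  Parsers validate headers strictly and report the offending file
and line on error.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ParseError


def _float_repr(x: float) -> str:
    return repr(float(x))


# --- expression matrices --------------------------------------------------

def write_expression_tsv(values: pd.DataFrame, path) -> Path:
    """Write a feature × sample intensity matrix; first column ``feature``."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("feature\t" + "\t".join(map(str, values.columns)) + "\n")
        for feature, row in values.iterrows():
            fh.write(str(feature) + "\t"
                     + "\t".join(_float_repr(v) for v in row) + "\n")
    return path


def read_expression_tsv(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty expression file")
    header = lines[0].split("\t")
    if header[0] != "feature":
        raise ParseError(path, 1,
                         f"first column must be 'feature', got {header[0]!r}")
    sample_cols = header[1:]
    if len(set(sample_cols)) != len(sample_cols):
        raise ParseError(path, 1, "duplicate sample columns")
    index = []
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(path, lineno,
                             f"expected {len(header)} fields, got {len(parts)}")
        index.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-numeric intensity: {exc}")
    frame = pd.DataFrame(rows, index=pd.Index(index, name="feature"),
                         columns=sample_cols)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(path, None, f"duplicate feature id {dup!r}")
    return frame


# --- plain feature lists --------------------------------------------------

def write_feature_list(features, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for f in features:
            fh.write(f"{f}\n")
    return path


def read_feature_list(path) -> list[str]:
    path = Path(path)
    with open(path) as fh:
        return [line for line in fh.read().splitlines() if line.strip()]


# --- two-column interaction tables ---------------------------------------

INTERACTION_HEADER = ("regulator", "target")


def write_interaction_table(pairs, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(INTERACTION_HEADER) + "\n")
        for reg, target in pairs:
            fh.write(f"{reg}\t{target}\n")
    return path


def read_interaction_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty interaction table")
    header = tuple(lines[0].split("\t"))
    if header != INTERACTION_HEADER:
        raise ParseError(path, 1,
                         f"expected header {INTERACTION_HEADER}, got {header}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(path, lineno,
                             f"expected 2 fields, got {len(parts)}")
        rows.append(parts)
    return pd.DataFrame(rows, columns=list(INTERACTION_HEADER))


# --- GMT annotation sets --------------------------------------------------

def write_gmt(sets: dict[str, set], path,
              descriptions: dict[str, str] | None = None) -> Path:
    path = Path(path)
    descriptions = descriptions or {}
    with open(path, "w", newline="") as fh:
        for term in sorted(sets):
            members = "\t".join(sorted(map(str, sets[term])))
            desc = descriptions.get(term, "")
            fh.write(f"{term}\t{desc}\t{members}\n" if members
                     else f"{term}\t{desc}\n")
    return path


def read_gmt(path) -> tuple[dict[str, set], dict[str, str]]:
    path = Path(path)
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh.read().splitlines(), start=1):
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(path, lineno,
                                 "GMT rows need at least term and description")
            term = parts[0]
            if term in sets:
                raise ParseError(path, lineno, f"duplicate term {term!r}")
            descriptions[term] = parts[1]
            sets[term] = {p for p in parts[2:] if p}
    return sets, descriptions


# --- derived tables -------------------------------------------------------

def write_labels_tsv(labels: pd.DataFrame, path) -> Path:
    """Feature × timepoint integer label matrix (long TSV not needed)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("feature\t" + "\t".join(map(str, labels.columns)) + "\n")
        for feature, row in labels.iterrows():
            fh.write(str(feature) + "\t"
                     + "\t".join(str(int(v)) for v in row) + "\n")
    return path


def read_labels_tsv(path) -> pd.DataFrame:
    frame = read_expression_tsv(path)
    return frame.astype(int)


def write_edge_list(edges, path) -> Path:
    """Edges as ``source  target  type  sign  pcc`` TSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("source\ttarget\ttype\tsign\tpcc\n")
        for e in edges:
            pcc = "" if pd.isna(e.pcc) else _float_repr(e.pcc)
            fh.write(f"{e.source}\t{e.target}\t{e.etype}\t{e.sign}\t{pcc}\n")
    return path


def read_edge_list(path):
    from .regnet import Edge
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != ["source", "target", "type",
                                             "sign", "pcc"]:
        raise ParseError(path, 1, "bad edge-list header")
    edges = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(path, lineno, f"expected 5 fields, got {len(parts)}")
        src, dst, etype, sign, pcc = parts
        try:
            edges.append(Edge(src, dst, etype, int(sign),
                              float(pcc) if pcc else float("nan")))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
    return edges


def write_partition_tsv(module_of: dict[str, int], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("node\tmodule\n")
        for node in sorted(module_of):
            fh.write(f"{node}\t{module_of[node]}\n")
    return path


def read_partition_tsv(path) -> dict[str, int]:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != ["node", "module"]:
        raise ParseError(path, 1, "bad partition header")
    out = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 fields, got {len(parts)}")
        out[parts[0]] = int(parts[1])
    return out


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
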