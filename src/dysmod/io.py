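"""Readers and writers for the pipeline's plain-text formats.

Expression travels as a gene-by-sample TSV plus a sample→group label TSV;
gene sets as GMT; interactions as a 4-column TSV; networks as edge-list TSV
or GraphML; ground truth and manifests as JSON. Every writer accepts an
optional comment line (used by the pipeline to stamp the config hash);
readers skip leading ``#`` lines.
"""
from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CASE, CONTROL, ExpressionMatrix, GeneSetCollection, InteractionSet


def _open_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            yield lineno, line.rstrip("\n")


def _write_frame(df: pd.DataFrame, path, comment: str | None, index: bool, index_label=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def write_expression_table(
    m: ExpressionMatrix, path, labels_path, comment: str | None = None
) -> None:
    _write_frame(m.values, path, comment, index=True, index_label="gene")
    labels = m.groups.rename("group").rename_axis("sample").reset_index()
    _write_frame(labels, labels_path, comment, index=False)


def read_expression_table(path, labels_path) -> ExpressionMatrix:
    """Load and validate an expression TSV plus its sample-label TSV.

    Duplicate gene ids are rejected with their line numbers; every sample
    column must carry a case/control label; non-numeric cells are rejected
    naming the offending gene and sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    gene_col = df.columns[0]
    dup_mask = df[gene_col].duplicated(keep=False)
    if dup_mask.any():
        lines = (df.index[dup_mask] + 2).tolist()  # +1 header, +1 one-based
        raise ValueError(
            f"duplicate gene ids {sorted(set(df.loc[dup_mask, gene_col]))[:3]} "
            f"at data lines {lines[:6]}"
        )
    df = df.set_index(gene_col)
    values = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            values[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"malformed numeric cell in sample column '{col}', gene(s) {list(bad[:3])}"
            ) from None
    labels = pd.read_csv(labels_path, sep="\t", comment="#", dtype=str)
    groups = pd.Series(labels["group"].values, index=labels["sample"].values, name="group")
    values = values.rename_axis(None)
    unlabeled = [s for s in values.columns if s not in groups.index]
    if unlabeled:
        raise ValueError(f"samples without labels: {unlabeled[:5]}")
    bad = set(groups.loc[list(values.columns)]) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    return ExpressionMatrix(values, groups)


def write_gmt(sets: GeneSetCollection, path, comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for term in sets.sets:
            members = "\t".join(sorted(sets.sets[term]))
            fh.write(f"{term}\t{sets.names.get(term, term)}\t{members}\n")


def read_gmt(path, category: str = "term") -> GeneSetCollection:
    """Parse a GMT file: term, description, tab-separated members per line.

    Duplicate members within a line collapse (set semantics); a line with
    fewer than 3 fields is an error naming its line number; an empty file
    yields an empty collection.
    """
    sets: dict = {}
    names: dict = {}
    for lineno, line in _open_lines(path):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has {len(fields)} fields, expected >= 3")
        term, name, members = fields[0], fields[1], fields[2:]
        sets[term] = frozenset(members)
        names[term] = name
    if not sets:
        return GeneSetCollection(sets={}, names={}, category=category)
    return GeneSetCollection(sets=sets, names=names, category=category)


def write_interactions(ints: InteractionSet, path, comment: str | None = None) -> None:
    _write_frame(ints.edges, path, comment, index=False)


def read_interactions(path) -> InteractionSet:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"regulator": str, "target": str, "type": str, "score": float},
    )
    return InteractionSet(df)


def write_table(df: pd.DataFrame, path, comment: str | None = None, index: bool = False) -> None:
    """Generic result-table writer (TSV with optional comment header)."""
    _write_frame(df, path, comment, index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_graphml(g: nx.Graph, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)


def write_edge_list(g: nx.Graph, path, comment: str | None = None) -> None:
    rows = [(u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)]
    df = pd.DataFrame(sorted(rows), columns=["source", "target", "weight"])
    _write_frame(df, path, comment, index=False)


def read_edge_list(path) -> nx.Graph:
    df = read_table(path, dtype={"source": str, "target": str, "weight": float})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight))
    return g


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
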