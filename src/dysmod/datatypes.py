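"""Shared data containers for the dysfunction-module pipeline.

Containers are thin dataclasses around pandas objects; validation happens at
construction so downstream stages can assume the documented invariants.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Reserved label for genes left unassigned by module detection.
GRAY = "gray"
CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with case/control sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample, on a log-like
        additive scale.
    groups
        Series mapping every sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        bad = set(self.groups.loc[list(self.values.columns)]) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be case/control, got {sorted(bad)}")
        self.groups = self.groups.loc[list(self.values.columns)]
        n_nan = int(self.values.isna().any(axis=1).sum())
        if n_nan:
            log.warning("dropping %d genes with missing values", n_nan)
            self.values = self.values.dropna(axis=0)
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[samples].copy(), self.groups.loc[samples].copy())

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes].copy(), self.groups.copy())


@dataclass
class GeneSetCollection:
    """Named annotation terms mapped to gene-identifier sets (GMT semantics)."""

    sets: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)
    category: str = "term"

    def __post_init__(self) -> None:
        empty = [t for t, g in self.sets.items() if len(g) == 0]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")
        self.sets = {t: frozenset(g) for t, g in self.sets.items()}
        for t in self.sets:
            self.names.setdefault(t, t)

    @property
    def term_ids(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> frozenset:
        out: set = set()
        for g in self.sets.values():
            out |= g
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


NCRNA = "ncRNA"
TF = "TF"
_EDGE_COLS = ["regulator", "target", "type", "score"]


@dataclass
class InteractionSet:
    """Typed regulator→target edges with optional confidence scores.

    ``edges`` has columns regulator/target/type/score; score may be NaN for
    unscored (TF-style) edges. Duplicate (regulator, target) pairs are invalid.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _EDGE_COLS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"interaction table missing columns {missing}")
        self.edges = self.edges[_EDGE_COLS].reset_index(drop=True)
        dup = self.edges.duplicated(subset=["regulator", "target"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate regulator→target edges")
        bad_type = set(self.edges["type"]) - {NCRNA, TF}
        if bad_type:
            raise ValueError(f"unknown regulator types {sorted(bad_type)}")
        score = self.edges["score"].astype(float)
        scored = score.dropna()
        if ((scored < 0) | (scored > 1)).any():
            raise ValueError("interaction scores must lie in [0,1]")
        self.edges["score"] = score

    @property
    def regulators(self) -> list[str]:
        return sorted(self.edges["regulator"].unique())

    def targets_of(self, regulator: str) -> frozenset:
        return frozenset(self.edges.loc[self.edges["regulator"] == regulator, "target"])

    def of_type(self, regulator_type: str) -> "InteractionSet":
        return InteractionSet(self.edges[self.edges["type"] == regulator_type].copy())

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ModulePartition:
    """Assignment of genes to coexpression modules plus module summaries.

    Non-gray labels are integers 1..M ordered by decreasing module size; the
    string ``"gray"`` marks unassigned genes. Eigengenes, hub genes and
    variance explained are attached after module detection.
    """

    module_of_gene: pd.Series
    eigengenes: pd.DataFrame | None = None      # modules x samples
    hub_gene: dict = field(default_factory=dict)
    variance_explained: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.module_of_gene.index.has_duplicates:
            raise ValueError("duplicate gene ids in partition")

    @property
    def modules(self) -> list[int]:
        labels = {m for m in self.module_of_gene if m != GRAY}
        return sorted(labels)

    def genes_in(self, module) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])

    @property
    def module_sizes(self) -> dict:
        return {m: int((self.module_of_gene == m).sum()) for m in self.modules}

    @property
    def n_gray(self) -> int:
        return int((self.module_of_gene == GRAY).sum())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.module_of_gene.index)
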