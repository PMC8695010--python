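"""Regulator ("pivot") analysis of coexpression modules.

A pivot is a regulator (ncRNA or TF) with at least two targets inside a
module whose target-module overlap is hypergeometrically significant
(raw p < 0.01 by default, no multiplicity correction). Regulators significant
in more modules rank as core pivots. ncRNA and TF scans run independently;
scored ncRNA edges are pre-filtered at score >= 0.5 while unscored TF edges
pass through.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import NCRNA, TF, InteractionSet, ModulePartition
from .enrich import benjamini_hochberg, hypergeometric_upper_tail

log = logging.getLogger(__name__)

MIN_OVERLAP = 2

PIVOT_COLUMNS = ["regulator", "type", "module", "k", "K", "n", "N", "p", "significant"]


def filter_by_score(raw: InteractionSet, score_min: float = 0.5) -> InteractionSet:
    """Drop scored edges below ``score_min`` (inclusive >=); unscored edges
    (TF-style) always pass."""
    if not 0 <= score_min <= 1:
        raise ValueError("score_min must lie in [0, 1]")
    edges = raw.edges
    keep = edges["score"].isna() | (edges["score"] >= score_min)
    log.info("score filter >= %.2f kept %d of %d edges", score_min, int(keep.sum()), len(edges))
    return InteractionSet(edges[keep].copy())


@dataclass
class PivotRecord:
    """One regulator-module hypergeometric test that met the >= 2-target rule."""

    regulator_id: str
    regulator_type: str
    module: int
    overlap: int
    module_in_background: int
    targets_in_background: int
    background_size: int
    p: float
    significant: bool


def pivot_test(
    regulator_targets: frozenset,
    module_genes: frozenset,
    background: frozenset,
    p_cut: float = 0.01,
    min_overlap: int = MIN_OVERLAP,
    restrict_module: bool = True,
) -> tuple | None:
    """Hypergeometric regulator-module association, or None below the
    ≥``min_overlap``-target rule.

    Targets are intersected with the background universe; by default the
    module is restricted to the background too (``restrict_module=False``
    requires module ⊆ background and uses the full module size as K).
    Returns (k, K, n, N, p, significant).
    """
    if not background:
        raise ValueError("empty background universe")
    targets = frozenset(regulator_targets) & background
    module = frozenset(module_genes)
    if restrict_module:
        module &= background
    elif not module <= background:
        raise ValueError("module genes must be a subset of the background")
    k = len(targets & module)
    if k < min_overlap:
        return None
    K, n, N = len(module), len(targets), len(background)
    p = hypergeometric_upper_tail(k, K=K, n=n, N=N)
    return k, K, n, N, p, bool(p < p_cut)


def scan_pivots(
    interactions: InteractionSet,
    partition: ModulePartition,
    background: frozenset | None = None,
    p_cut: float = 0.01,
    min_overlap: int = MIN_OVERLAP,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Run pivot_test for every (regulator, non-gray module) pair.

    The default background for each regulator type is the union of all
    targets of that type intersected with the partition's genes; passing
    ``background`` overrides it for both types (e.g. the full analyzed-gene
    universe). Raw p gates significance; ``bh_correct=True`` instead applies
    BH across all emitted tests of one type. Output is sorted by (type, p).
    """
    part_genes = frozenset(partition.gene_ids)
    modules = {m: frozenset(partition.genes_in(m)) for m in partition.modules}
    frames = []
    for typ in (NCRNA, TF):
        sub = interactions.of_type(typ)
        if len(sub) == 0:
            continue
        bg = background if background is not None else frozenset(sub.edges["target"]) & part_genes
        if not bg:
            log.warning("empty %s background after intersection; skipping type", typ)
            continue
        rows = []
        for reg in sub.regulators:
            targets = sub.targets_of(reg)
            for mod in partition.modules:
                res = pivot_test(
                    targets, modules[mod], bg, p_cut=p_cut, min_overlap=min_overlap
                )
                if res is None:
                    continue
                k, K, n, N, p, sig = res
                rows.append((reg, typ, mod, k, K, n, N, p, sig))
        if not rows:
            continue
        df = pd.DataFrame(rows, columns=PIVOT_COLUMNS)
        if bh_correct:
            q = benjamini_hochberg(df["p"].to_numpy())
            df["q"] = q
            df["significant"] = q < p_cut
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=PIVOT_COLUMNS)
    out = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["type", "p", "regulator", "module"], kind="stable")
        .reset_index(drop=True)
    )
    sig = out[out["significant"]]
    n_pairs = len(sig)
    n_regs = sig["regulator"].nunique()
    assert n_pairs >= n_regs, "pair count must be >= distinct-regulator count"
    log.info(
        "pivot scan: %d records, %d significant pairs over %d regulators",
        len(out), n_pairs, n_regs,
    )
    return out


def rank_core_pivots(records: pd.DataFrame) -> pd.DataFrame:
    """Rank regulators by the number of modules they significantly regulate.

    Ties break by best (smallest) p, then lexicographic regulator id. Only
    significant records contribute; an all-null input gives an empty summary.
    """
    sig = records[records["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=["regulator", "type", "n_modules", "best_p"])
    grouped = (
        sig.groupby("regulator")
        .agg(type=("type", "first"), n_modules=("module", "nunique"), best_p=("p", "min"))
        .reset_index()
    )
    grouped = grouped.sort_values(
        ["n_modules", "best_p", "regulator"], ascending=[False, True, True], kind="stable"
    )
    return grouped.reset_index(drop=True)


def regulator_module_network(records: pd.DataFrame) -> nx.Graph:
    """Bipartite regulator-module graph over significant records.

    Edge weight is -log10(p) with p floored at 1e-300; nodes carry a
    ``kind`` attribute (``regulator`` with its type, or ``module``).
    """
    g = nx.Graph()
    sig = records[records["significant"]]
    for row in sig.itertuples(index=False):
        mod_node = f"module:{row.module}"
        g.add_node(row.regulator, kind="regulator", regulator_type=row.type)
        g.add_node(mod_node, kind="module", module=int(row.module))
        g.add_edge(row.regulator, mod_node, weight=float(-np.log10(max(row.p, 1e-300))))
    return g
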