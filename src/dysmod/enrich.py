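"""Hypergeometric over-representation of annotation terms in modules.

For a module of n genes in a universe of N annotated genes and a term
covering K of them, the over-representation p-value is the upper tail

    p = sum_{x = k}^{min(K, n)} C(K, x) C(N-K, n-x) / C(N, n)

evaluated in log space for numerical stability. Benjamini-Hochberg q-values
are computed within each (module, category) family and records must clear
both a raw-p and a q cutoff to be reported.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, ModulePartition

log = logging.getLogger(__name__)


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact in log space.

    ``k``: observed overlap, ``K``: term size, ``n``: draw (module) size,
    ``N``: universe size.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    hi = min(K, n)
    if not 0 <= k <= hi:
        raise ValueError(f"overlap k={k} outside [0, min(K,n)={hi}]")
    if k == 0:
        return 1.0
    x = np.arange(max(k, n - (N - K)), hi + 1)
    log_terms = (
        _lchoose(K, x) + _lchoose(N - K, n - x) - _lchoose(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _lchoose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_modules(
    partition: ModulePartition,
    sets: GeneSetCollection,
    p_cut: float = 0.01,
    q_cut: float = 0.01,
    universe: str = "annotated",
) -> pd.DataFrame:
    """Test every (non-gray module, term) pair with overlap >= 1.

    The universe is the intersection of partition genes with the collection's
    gene space (``universe="annotated"``, clusterProfiler-like) or all
    partition genes (``universe="all"``). BH correction runs within each
    module; records are retained iff p < p_cut and q < q_cut, sorted by p.
    """
    part_genes = set(partition.gene_ids)
    if universe == "annotated":
        uni = part_genes & set(sets.all_genes())
    elif universe == "all":
        uni = part_genes
    else:
        raise ValueError("universe must be 'annotated' or 'all'")
    if not uni:
        raise ValueError("empty universe: no partition gene carries an annotation")
    N = len(uni)
    term_genes = {t: g & uni for t, g in sets.sets.items()}
    out = []
    for mod in partition.modules:
        mod_genes = set(partition.genes_in(mod)) & uni
        n = len(mod_genes)
        if n == 0:
            continue
        rows = []
        for term in sorted(sets.sets):
            tg = term_genes[term]
            k = len(tg & mod_genes)
            if k < 1:
                continue
            p = hypergeometric_upper_tail(k, K=len(tg), n=n, N=N)
            rows.append((mod, sets.category, term, k, len(tg), n, N, p))
        if not rows:
            continue
        df = pd.DataFrame(
            rows, columns=["module", "category", "term", "k", "K", "n", "N", "p"]
        )
        df["q"] = benjamini_hochberg(df["p"].to_numpy())
        out.append(df[(df["p"] < p_cut) & (df["q"] < q_cut)])
    if not out:
        return pd.DataFrame(
            columns=["module", "category", "term", "k", "K", "n", "N", "p", "q"]
        )
    res = pd.concat(out, ignore_index=True).sort_values(
        ["p", "module", "term"], kind="stable"
    )
    log.info("%d enriched (module, term) records retained", len(res))
    return res.reset_index(drop=True)


def term_module_edges(records: pd.DataFrame) -> pd.DataFrame:
    """Bipartite term-module edge list from enrichment records, weighted by
    -log10(p) (p floored at 1e-300)."""
    edges = records[["term", "module", "p"]].copy()
    edges["weight"] = -np.log10(np.maximum(edges.pop("p"), 1e-300))
    return edges
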