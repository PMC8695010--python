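"""Weighted coexpression network construction and module detection.

The pipeline follows the standard weighted-coexpression recipe: raise the
absolute Pearson correlation to a soft power beta chosen so the connectivity
distribution approximates a scale-free law, convert adjacency to topological
overlap (shared-neighbor cohesion), cluster 1 - TOM by average linkage with a
static height cut, discard undersized clusters into the reserved "gray"
label, and summarize each surviving module by its eigengene (first principal
component) and hub gene (maximal eigengene correlation, kME).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import GRAY, ExpressionMatrix, ModulePartition

log = logging.getLogger(__name__)

DEFAULT_POWERS = tuple(range(1, 21))


def correlation_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Gene-gene Pearson correlation; constant-expression rows are excluded
    with a warning (correlation undefined)."""
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for gene-gene correlation")
    vals = m.values.to_numpy()
    sd = vals.std(axis=1)
    keep = sd > 0
    if not keep.all():
        log.warning("excluding %d constant-expression genes", int((~keep).sum()))
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant genes")
    genes = m.values.index[keep]
    r = np.corrcoef(vals[keep])
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame(r, index=genes, columns=genes)


def adjacency_from_correlation(r: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold adjacency: |r|^beta (unsigned) or ((1+r)/2)^beta (signed)."""
    base = (1.0 + r.to_numpy()) / 2.0 if signed else np.abs(r.to_numpy())
    a = base ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=r.index, columns=r.columns)


def connectivity(adjacency: pd.DataFrame) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = adjacency.to_numpy()
    return a.sum(axis=1) - np.diag(a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log connectivity histogram regression.

    Connectivities are binned into ``n_bins`` equal-width bins; R^2 is the
    squared Pearson correlation of log10(frequency) against log10(mean k)
    over nonempty bins. High R^2 indicates an approximately scale-free law.
    """
    k = np.asarray(k, dtype=float)
    if (k < 0).any():
        raise ValueError("connectivities must be nonnegative")
    if len(np.unique(k)) < n_bins:
        raise ValueError(f"need at least {n_bins} distinct connectivities")
    counts, edges = np.histogram(k, bins=n_bins)
    sums, _ = np.histogram(k, bins=edges, weights=k)
    nonempty = counts > 0
    mean_k = sums[nonempty] / counts[nonempty]
    freq = counts[nonempty] / k.size
    ok = mean_k > 0
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable bins; distribution too degenerate")
    x = np.log10(mean_k[ok])
    y = np.log10(freq[ok])
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class SoftThresholdResult:
    """Chosen soft power with per-power scale-free fit diagnostics."""

    beta: int
    fit_r2_by_power: dict = field(default_factory=dict)
    mean_connectivity_by_power: dict = field(default_factory=dict)


def pick_soft_threshold(
    m: ExpressionMatrix,
    powers: tuple = DEFAULT_POWERS,
    r2_cut: float = 0.85,
    signed: bool = False,
    n_bins: int = 10,
    min_mean_connectivity: float = 1.0,
    fallback_beta: int = 6,
    r: pd.DataFrame | None = None,
) -> SoftThresholdResult:
    """Choose the smallest power whose scale-free fit reaches ``r2_cut``.

    Powers that depress mean connectivity below ``min_mean_connectivity`` are
    not eligible: with the network that sparse the topological-overlap signal
    degenerates even if the log-log fit keeps improving. When no eligible
    power reaches the cut, the conventional unsigned-network default
    ``fallback_beta`` is used (the standard recommendation when scale-free
    fit saturates slowly). Powers whose connectivity distribution is too
    degenerate to bin are recorded as NaN. A precomputed correlation matrix
    may be passed to avoid recomputation.
    """
    if len(powers) == 0:
        raise ValueError("empty power grid")
    powers = tuple(sorted(int(b) for b in powers))
    if r is None:
        r = correlation_matrix(m)
    base = (1.0 + r.to_numpy()) / 2.0 if signed else np.abs(r.to_numpy())
    fits: dict = {}
    mean_k: dict = {}
    for beta in powers:
        a = base ** beta
        np.fill_diagonal(a, 1.0)
        k = a.sum(axis=1) - 1.0
        mean_k[beta] = float(k.mean())
        try:
            fits[beta] = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            fits[beta] = float("nan")
    eligible = [b for b in powers if mean_k[b] >= min_mean_connectivity]
    passing = [b for b in eligible if np.isfinite(fits[b]) and fits[b] >= r2_cut]
    if passing:
        beta = passing[0]
    else:
        beta = min(fallback_beta, max(powers))
        log.warning(
            "no eligible power reached R2 >= %.2f; using fallback beta=%d", r2_cut, beta
        )
    fit = fits.get(beta, float("nan"))
    log.info("soft threshold beta=%d (R2=%.3f)", beta, fit)
    return SoftThresholdResult(beta=beta, fit_r2_by_power=fits, mean_connectivity_by_power=mean_k)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu * a_uj; diagonal fixed at 1.
    """
    a = adjacency.to_numpy()
    _check_adjacency(a)
    k = a.sum(axis=1) - 1.0
    aa = a @ a
    l = aa - 2.0 * a  # removes u=i and u=j terms (unit diagonal)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def _check_adjacency(a: np.ndarray, tol: float = 1e-10) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=tol):
        raise ValueError("adjacency must be symmetric")
    if (a < -tol).any() or (a > 1 + tol).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0, atol=tol):
        raise ValueError("adjacency diagonal must be 1")


def detect_modules(
    tom: pd.DataFrame, min_module_size: int = 30, cut_height: float = 0.99
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Flat clusters are read off at dissimilarity ``cut_height``; clusters
    smaller than ``min_module_size`` are relabeled gray, survivors are
    renumbered 1..M by decreasing size (ties by first appearance).
    """
    if not 0 < cut_height < 1:
        raise ValueError("cut_height must lie in (0, 1)")
    d = 1.0 - tom.to_numpy()
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size]
    # order: decreasing size, then smallest raw label for determinism
    ordered = sorted(keep.index, key=lambda c: (-keep[c], c))
    relabel = {c: i + 1 for i, c in enumerate(ordered)}
    labels = [relabel.get(c, GRAY) for c in raw]
    part = ModulePartition(pd.Series(labels, index=tom.index, dtype=object))
    if not part.modules:
        log.warning("all genes gray: no cluster reached min_module_size=%d", min_module_size)
    log.info(
        "detected %d modules (%d genes gray of %d)", len(part.modules), part.n_gray, len(labels)
    )
    return part


def module_eigengenes(m: ExpressionMatrix, p: ModulePartition) -> ModulePartition:
    """Attach eigengenes (first PC of the gene-standardized module submatrix).

    Eigengenes are scaled to unit variance and sign-oriented so their mean
    correlation with module genes is nonnegative; the fraction of variance
    explained by the first component is recorded per module.
    """
    samples = m.sample_ids
    rows = {}
    varexp = {}
    for mod in p.modules:
        genes = [g for g in p.genes_in(mod) if g in m.values.index]
        x = m.values.loc[genes].to_numpy()
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        xs = (x - mu) / sd
        if len(genes) == 1:
            pc = xs[0]
            varexp[mod] = 1.0
        else:
            _, s, vt = np.linalg.svd(xs, full_matrices=False)
            pc = vt[0]
            varexp[mod] = float(s[0] ** 2 / (s ** 2).sum())
        pc = pc - pc.mean()
        pc_sd = pc.std(ddof=1)
        if pc_sd > 0:
            pc = pc / pc_sd
        if _mean_cor_with_rows(xs, pc) < 0:
            pc = -pc
        rows[mod] = pc
    eig = pd.DataFrame(rows, index=samples).T if rows else pd.DataFrame(columns=samples)
    return ModulePartition(
        module_of_gene=p.module_of_gene.copy(),
        eigengenes=eig,
        hub_gene=dict(p.hub_gene),
        variance_explained=varexp,
    )


def _mean_cor_with_rows(xs: np.ndarray, v: np.ndarray) -> float:
    vc = v - v.mean()
    vn = np.linalg.norm(vc)
    xc = xs - xs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    ok = (norms > 0) & (vn > 0)
    if not ok.any():
        return 0.0
    return float((xc[ok] @ vc / (norms[ok] * vn)).mean())


def hub_genes(m: ExpressionMatrix, p: ModulePartition) -> ModulePartition:
    """Attach per-module hub genes: the member maximizing |kME|, the absolute
    correlation with the module eigengene; exact ties break lexicographically."""
    if p.eigengenes is None:
        raise ValueError("eigengenes must be computed before hub genes")
    hubs = {}
    for mod in p.modules:
        genes = sorted(g for g in p.genes_in(mod) if g in m.values.index)
        me = p.eigengenes.loc[mod].to_numpy()
        kme = np.array([_cor(m.values.loc[g].to_numpy(), me) for g in genes])
        best = np.abs(kme).max()
        candidates = [g for g, v in zip(genes, kme) if abs(abs(v) - best) <= 1e-12]
        hubs[mod] = min(candidates)
    return ModulePartition(
        module_of_gene=p.module_of_gene.copy(),
        eigengenes=p.eigengenes.copy(),
        hub_gene=hubs,
        variance_explained=dict(p.variance_explained),
    )


def _cor(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(xc @ yc / (nx * ny))


def intramodular_hub_genes(adjacency: pd.DataFrame, p: ModulePartition) -> dict:
    """Alternative hub criterion: maximal intramodular connectivity sum(a)."""
    hubs = {}
    for mod in p.modules:
        genes = sorted(g for g in p.genes_in(mod) if g in adjacency.index)
        sub = adjacency.loc[genes, genes].to_numpy()
        k_in = sub.sum(axis=1) - 1.0
        best = k_in.max()
        candidates = [g for g, v in zip(genes, k_in) if abs(v - best) <= 1e-12]
        hubs[mod] = min(candidates)
    return hubs


def module_relationship_network(
    p: ModulePartition, eigengene_cor_cut: float = 0.5
) -> pd.DataFrame:
    """Module-module edges (i < j) wherever |cor(ME_i, ME_j)| >= cut.

    Returns an edge table with columns module_a, module_b, cor. A cut of 0
    yields the complete graph on modules.
    """
    if p.eigengenes is None or len(p.modules) < 2:
        raise ValueError("need eigengenes for at least 2 modules")
    mods = p.modules
    rows = []
    for i, a in enumerate(mods):
        for b in mods[i + 1 :]:
            c = _cor(p.eigengenes.loc[a].to_numpy(), p.eigengenes.loc[b].to_numpy())
            if abs(c) >= eigengene_cor_cut:
                rows.append((a, b, c))
    return pd.DataFrame(rows, columns=["module_a", "module_b", "cor"])
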