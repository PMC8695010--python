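"""Normalization and empirical-Bayes moderated differential expression.

The two-group moderated t-test shrinks per-gene residual variances toward a
pooled prior estimated by the classic moment method on log-variances: with
residual variance ``s2_g`` on ``d`` degrees of freedom,

    e_g = log(s2_g) - psi(d/2) + log(d/2)

has mean ``log(s0^2) + psi(d0/2) - log(d0/2)`` and excess variance
``psi'(d0/2)`` under a scaled inverse-chi-square prior with hyperparameters
``(d0, s0^2)``. Solving the trigamma equation gives ``d0``; the posterior
variance ``s2_post = (d0*s0^2 + d*s2)/(d0 + d)`` then yields a t-statistic
referred to Student's t with ``d0 + d`` degrees of freedom (normal when
``d0`` is infinite).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CASE, CONTROL, ExpressionMatrix

log = logging.getLogger(__name__)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    After normalization the sorted values of each column equal the
    across-column mean of sorted values; ties within a column receive the mean
    of the reference values over their rank range. Idempotent, rank-preserving
    within columns.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = m.values.to_numpy()
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned, minlength=len(uniq))
        counts = np.bincount(inverse, minlength=len(uniq))
        out[:, j] = (sums / counts)[inverse]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), m.groups.copy()
    )


def subtract_background(m: ExpressionMatrix, offset: float) -> ExpressionMatrix:
    """Constant-offset background subtraction (floored at zero)."""
    vals = np.maximum(m.values - offset, 0.0)
    return ExpressionMatrix(vals, m.groups.copy())


@dataclass
class PriorEstimate:
    """Empirical-Bayes variance prior: degrees of freedom d0 (may be inf) and
    prior variance s0_2."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.s0_2 <= 0:
            raise ValueError("require d0 >= 0 and s0_2 > 0")


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve psi'(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive; y must be > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: float) -> PriorEstimate:
    """Moment estimator of the variance prior from observed residual variances.

    Zero variances (log-degenerate) are excluded with a warning; if the excess
    variance of the log-variances is non-positive the prior is degenerate
    (d0 = inf) and every posterior variance collapses to s0_2.
    """
    s2 = np.asarray(s2, dtype=float)
    if d <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    pos = s2 > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 genes with positive variance")
    if not pos.all():
        log.warning("excluding %d zero variances from prior estimation", int((~pos).sum()))
    e = np.log(s2[pos]) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # degenerate prior: variances are exchangeable, pool them directly
        d0 = np.inf
        s0_2 = float(np.mean(s2[pos]))
    return PriorEstimate(d0=d0, s0_2=s0_2)


def moderated_t_test(m: ExpressionMatrix, prior: PriorEstimate | None = None) -> pd.DataFrame:
    """Two-group moderated t-test, case minus control.

    Returns a table indexed by gene with columns logFC, s2, s2_post, t,
    P.Value, adj.P.Val and df_residual; the fitted prior is stored in
    ``result.attrs["prior"]``. Passing ``prior`` explicitly overrides the
    empirical-Bayes fit (d0 = 0 reproduces the ordinary pooled t-test).
    """
    case = m.samples_in_group(CASE)
    ctrl = m.samples_in_group(CONTROL)
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    xc = m.values[case].to_numpy()
    xn = m.values[ctrl].to_numpy()
    logfc = xc.mean(axis=1) - xn.mean(axis=1)
    d = n1 + n2 - 2
    ss = ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xn - xn.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d
    if prior is None:
        prior = estimate_prior(s2, d)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_2)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_2 + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    t = np.where(logfc == 0, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "P.Value": p,
            "adj.P.Val": q,
            "df_residual": float(d),
        },
        index=m.values.index,
    )
    table.attrs["prior"] = prior
    table.attrs["direction"] = "case-minus-control"
    return table


def select_differential_genes(table: pd.DataFrame, p_cutoff: float = 0.01) -> list[str]:
    """Genes with raw P.Value strictly below the cutoff, sorted ascending.

    A cutoff of exactly 1 returns every gene (p-values of 1 included).
    """
    if not 0 < p_cutoff <= 1:
        raise ValueError("p_cutoff must lie in (0, 1]")
    mask = table["P.Value"] < p_cutoff if p_cutoff < 1 else np.ones(len(table), dtype=bool)
    hits = table.loc[mask, "P.Value"].sort_values(kind="stable")
    log.info("selected %d differential genes at p < %g", len(hits), p_cutoff)
    return list(hits.index)
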