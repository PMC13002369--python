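"""Gene-wise differential expression with optional variance moderation.

logFC is mean(disease) - mean(control) on the log2 scale. The moderated
test shrinks per-gene sample variances toward an inverse-gamma prior fitted
across genes by moments (the classical empirical-Bayes trick for small
per-group sample sizes), which augments the t degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .study import ExpressionStudy


class DiffExprError(ValueError):
    pass


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order of input kept).

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise DiffExprError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DiffExprError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _moment_inverse_gamma(s2: np.ndarray) -> tuple[float, float]:
    """Fit an inverse-gamma(a, b) prior to sample variances by moments.

    mean = b/(a-1), var = b^2 / ((a-1)^2 (a-2))  =>  a = m^2/v + 2.
    Returns (a, b); falls back to a vague prior when the across-gene
    variance is degenerate.
    """
    m = float(s2.mean())
    v = float(s2.var(ddof=1)) if s2.size > 1 else 0.0
    if v <= 1e-12 or m <= 0:
        return 1e-6, 1e-6 * max(m, 1e-12)  # effectively no shrinkage
    a = m * m / v + 2.0
    b = m * (a - 1.0)
    return a, b


def fit_gene_models(
    study: ExpressionStudy,
    moderated: bool = True,
    lfc_thresh: float = 1.0,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression table for every gene.

    Returns a DataFrame indexed by gene with columns logFC, t, p, q and
    significant (q < q_thresh and |logFC| >= lfc_thresh). Unmoderated mode
    is the textbook pooled-variance two-sample t; moderated mode replaces
    each pooled variance s_g^2 by its posterior mean under the
    moment-matched inverse-gamma prior and tests on d + 2a degrees of
    freedom.
    """
    mask = study.disease_mask
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n0 < 2:
        raise DiffExprError(
            f"need >= 2 samples per condition (disease={n1}, control={n0})"
        )
    X = study.values
    x1, x0 = X[:, mask], X[:, ~mask]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    logfc = m1 - m0
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((x0 - m0[:, None]) ** 2).sum(axis=1)
    d = n1 + n0 - 2
    s2 = (ss1 + ss0) / d

    if moderated:
        a, b = _moment_inverse_gamma(s2)
        s2_tilde = (b + 0.5 * d * s2) / (a + 0.5 * d - 1.0)
        df = d + 2.0 * a
        s2_used = s2_tilde
    else:
        df = float(d)
        s2_used = s2

    se = np.sqrt(s2_used * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "q": q,
            "significant": (q < q_thresh) & (np.abs(logfc) >= lfc_thresh),
        },
        index=pd.Index(study.genes, name="gene"),
    )
    return table


def select_degs(
    table: pd.DataFrame, lfc_thresh: float = 1.0, q_thresh: float = 0.05
) -> list[str]:
    """Genes meeting both |logFC| and BH-q thresholds, in table order."""
    if lfc_thresh < 0 or q_thresh < 0:
        raise DiffExprError("thresholds must be non-negative")
    keep = (table["q"] < q_thresh) & (table["logFC"].abs() >= lfc_thresh)
    return list(table.index[keep])
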