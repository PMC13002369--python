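"""Redundancy-aware target prioritization.

Zoo models often rediscover each other's importance profile; counting each
as an independent vote inflates genes favored by over-represented model
families. Models whose importance vectors correlate strongly (Spearman rho
above a threshold, default 0.85) are clustered by connected components and
every member of a cluster of size c gets weight 1/c, making the weighted
selection frequency invariant to cloning a model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

DEFAULT_RHO = 0.85


class RankError(ValueError):
    pass


def spearman_matrix(importances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho between model importance vectors (model x gene).

    Ties get average ranks. A constant vector has undefined rank
    correlation; rho against any other vector is defined as 0 (and 1 on the
    diagonal).
    """
    if importances.shape[1] < 2:
        raise RankError("importance vectors need >= 2 genes")
    values = importances.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, values)
    constant = ranks.std(axis=1) <= 1e-12
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=importances.index, columns=importances.index)


def cluster_and_weight(
    corr: pd.DataFrame, rho: float = DEFAULT_RHO
) -> tuple[list[list[str]], dict[str, float]]:
    """Connected components of the rho-thresholded model graph and 1/|C|
    weights per member."""
    if not 0 < rho < 1:
        raise RankError("rho must lie in (0, 1)")
    models = list(corr.index)
    adj = (corr.to_numpy(dtype=float) > rho).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for m, lab in zip(models, labels):
        clusters[lab].append(m)
    clusters = [sorted(c) for c in clusters]
    clusters.sort(key=lambda c: c[0])
    weights = {m: 1.0 / len(c) for c in clusters for m in c}
    return clusters, weights


def weighted_selection_frequency(
    selected: Mapping[str, frozenset | set],
    weights: Mapping[str, float],
) -> tuple[pd.Series, list[str]]:
    """wsf(g) = sum_m w_m 1[g in selected_m] / sum_m w_m, plus the ranking
    (descending wsf, lexicographic tie-break)."""
    if set(selected) != set(weights):
        raise RankError("selected sets and weights cover different model ids")
    for m, w in weights.items():
        if w <= 0:
            raise RankError(f"weight for model {m!r} must be positive")
    total = sum(weights.values())
    score: dict[str, float] = {}
    for m, genes in selected.items():
        for g in genes:
            score[g] = score.get(g, 0.0) + weights[m]
    wsf = pd.Series({g: v / total for g, v in score.items()}, dtype=float)
    wsf = wsf.sort_index()
    ranking = sorted(wsf.index, key=lambda g: (-wsf[g], g))
    return wsf, ranking


@dataclass
class RedundancyReport:
    importances: pd.DataFrame
    correlation: pd.DataFrame
    rho: float
    clusters: list[list[str]]
    weights: dict[str, float]
    wsf: pd.Series
    ranking: list[str]

    def ranking_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.ranking,
                "wsf": [self.wsf[g] for g in self.ranking],
                "rank": np.arange(1, len(self.ranking) + 1),
            }
        )


def rank_targets(records: Sequence, rho: float = DEFAULT_RHO) -> RedundancyReport:
    """End-to-end prioritization from zoo ModelRecords.

    Models with an all-zero importance vector sit in singleton clusters and
    contribute no selections.
    """
    importances = pd.DataFrame(
        {r.spec.spec_id: r.importance for r in records}
    ).T
    corr = spearman_matrix(importances)
    clusters, weights = cluster_and_weight(corr, rho)
    selected = {
        r.spec.spec_id: (
            frozenset() if float(r.importance.abs().sum()) == 0.0 else r.selected
        )
        for r in records
    }
    wsf, ranking = weighted_selection_frequency(selected, weights)
    return RedundancyReport(importances, corr, rho, clusters, weights, wsf, ranking)
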