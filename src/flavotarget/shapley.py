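"""Kernel SHAP, Shapley interaction indices and SHAP-based gene ranking.

Shapley values attribute the deviation of a prediction from the background
mean fairly across features. Kernel SHAP estimates them by weighted least
squares over feature coalitions with the Shapley kernel

    pi(s) = (M - 1) / (C(M, s) * s * (M - s)),

where a coalition keeps the instance's values on its member features and
averages predictions over background replacements elsewhere. The infinite
weights at s in {0, M} are handled by imposing the efficiency constraint
(sum of attributions = f(x) - base value) exactly in the solve. Panels of
at most 12 genes are enumerated exhaustively (deterministic); larger panels
use paired coalition sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .metrics import mann_whitney_auc
from .study import ExpressionStudy

EXACT_LIMIT = 12
INTERACTION_LIMIT = 10


class ShapError(ValueError):
    pass


@dataclass
class ShapExplanation:
    phi: np.ndarray
    base_value: float
    fx: float


def _coalition_value(
    predict: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
    mask: np.ndarray,
) -> float:
    data = background.copy()
    data[:, mask] = instance[mask]
    return float(np.mean(predict(data)))


def _solve_constrained_wls(
    Z: np.ndarray, v: np.ndarray, w: np.ndarray, fx: float, base: float
) -> np.ndarray:
    """Weighted least squares for phi with sum(phi) = fx - base imposed by
    eliminating the last feature (the standard Kernel SHAP reduction)."""
    M = Z.shape[1]
    if M == 1:
        return np.array([fx - base])
    eyAdj = v - base - Z[:, -1] * (fx - base)
    Zt = Z[:, :-1] - Z[:, -1:]
    A = (Zt * w[:, None]).T @ Zt
    b = (Zt * w[:, None]).T @ eyAdj
    phi_head = np.linalg.lstsq(A, b, rcond=None)[0]
    return np.append(phi_head, (fx - base) - phi_head.sum())


def _kernel_weight(M: int, s: int) -> float:
    return (M - 1) / (comb(M, s) * s * (M - s))


def _exact_masks(M: int) -> np.ndarray:
    """All 2^M - 2 proper coalition masks in deterministic order."""
    masks = np.zeros((2**M - 2, M), dtype=bool)
    for code in range(1, 2**M - 1):
        for j in range(M):
            masks[code - 1, j] = bool(code >> j & 1)
    return masks


def kernel_shap(
    predict: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
    n_coalitions: int = 2048,
    seed: int | None = None,
    method: str = "auto",
) -> ShapExplanation:
    """Shapley attributions for one instance.

    ``predict`` maps a samples x M array to probabilities; ``background``
    is the reference sample set masked-out features are drawn from. Up to
    ``EXACT_LIMIT`` features every proper coalition is enumerated; beyond
    that ``n_coalitions`` coalitions are sampled in complement pairs with
    sizes drawn from the Shapley kernel. ``method`` forces ``"exact"`` or
    ``"sampling"`` regardless of the size heuristic.
    """
    if method not in ("auto", "exact", "sampling"):
        raise ShapError(f"unknown method {method!r}")
    background = np.atleast_2d(np.asarray(background, dtype=float))
    instance = np.asarray(instance, dtype=float).ravel()
    M = instance.size
    if M == 0:
        raise ShapError("instance has no features")
    if background.shape[0] == 0 or background.shape[1] != M:
        raise ShapError("background must be a non-empty sample x M matrix")

    base = float(np.mean(predict(background)))
    fx = float(predict(instance.reshape(1, -1))[0])
    if M == 1:
        return ShapExplanation(np.array([fx - base]), base, fx)

    exact = method == "exact" or (method == "auto" and M <= EXACT_LIMIT)
    if exact and M > 20:
        raise ShapError("exact enumeration is limited to 20 features")
    if exact:
        masks = _exact_masks(M)
        w = np.array([_kernel_weight(M, int(m.sum())) for m in masks])
    else:
        rng = np.random.default_rng(
            child_seed(seed if seed is not None else 0, "kernel-shap")
        )
        sizes = np.arange(1, M)
        p = np.array([(M - 1) / (s * (M - s)) for s in sizes], dtype=float)
        p /= p.sum()
        masks_list: list[np.ndarray] = []
        n_pairs = max(1, int(n_coalitions) // 2)
        for _ in range(n_pairs):
            s = int(rng.choice(sizes, p=p))
            members = rng.choice(M, size=s, replace=False)
            mask = np.zeros(M, dtype=bool)
            mask[members] = True
            masks_list.append(mask)
            masks_list.append(~mask)  # paired complement: variance reduction
        masks = np.array(masks_list)
        w = np.ones(len(masks))

    v = np.array(
        [_coalition_value(predict, background, instance, m) for m in masks]
    )
    phi = _solve_constrained_wls(masks.astype(float), v, w, fx, base)
    return ShapExplanation(phi, base, fx)


def kernel_shap_table(
    predict: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instances: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Exact Kernel SHAP for many instances sharing one background.

    Requires at most ``EXACT_LIMIT`` features. The coalition design matrix
    is shared across instances, so the weighted normal equations are
    factorized once. Returns (phi table, base value).
    """
    X = instances.to_numpy(dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n, M = X.shape
    if M > EXACT_LIMIT:
        raise ShapError(f"exact enumeration supports at most {EXACT_LIMIT} features")
    base = float(np.mean(predict(background)))
    fx = predict(X)
    if M == 1:
        phi = (fx - base).reshape(-1, 1)
        return pd.DataFrame(phi, index=instances.index, columns=instances.columns), base

    masks = _exact_masks(M)
    w = np.array([_kernel_weight(M, int(m.sum())) for m in masks])
    nb = background.shape[0]
    V = np.empty((len(masks), n))
    for i, m in enumerate(masks):
        # rows: for each instance, the whole background with coalition
        # features replaced by that instance's values
        tiled = np.tile(background, (n, 1))
        inst_rep = np.repeat(X, nb, axis=0)
        tiled[:, m] = inst_rep[:, m]
        V[i] = predict(tiled).reshape(n, nb).mean(axis=1)

    Z = masks.astype(float)
    Zt = Z[:, :-1] - Z[:, -1:]
    A = (Zt * w[:, None]).T @ Zt
    EyAdj = V - base - np.outer(Z[:, -1], fx - base)
    B = (Zt * w[:, None]).T @ EyAdj
    head = np.linalg.lstsq(A, B, rcond=None)[0]          # (M-1) x n
    tail = (fx - base) - head.sum(axis=0)
    phi = np.vstack([head, tail]).T                       # n x M
    return pd.DataFrame(phi, index=instances.index, columns=instances.columns), base


def mean_abs_shap(phi_table: pd.DataFrame) -> pd.Series:
    """Global importance: mean over samples of |phi_g|, sorted descending
    with lexicographic tie-break (absolute values avoid the cancellation
    that plain SHAP sums suffer from)."""
    if len(phi_table) < 1:
        raise ShapError("phi table needs at least one sample")
    m = phi_table.abs().mean(axis=0)
    order = sorted(m.index, key=lambda g: (-m[g], str(g)))
    return m.loc[order]


def shap_interactions(
    predict: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
) -> np.ndarray:
    """Pairwise Shapley interaction index by exact enumeration (M <= 10).

    Off-diagonal (i, j): sum over S excluding i, j of
    |S|! (M - |S| - 2)! / (2 (M - 1)!) times the discrete second difference
    v(S+ij) - v(S+i) - v(S+j) + v(S). The diagonal holds main effects so
    each row sums to that feature's Shapley value.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    instance = np.asarray(instance, dtype=float).ravel()
    M = instance.size
    if M == 0:
        raise ShapError("instance has no features")
    if M > INTERACTION_LIMIT:
        raise ShapError(
            f"exact interaction enumeration supports at most {INTERACTION_LIMIT} features"
        )

    values: dict[int, float] = {}
    for code in range(2**M):
        mask = np.array([(code >> j) & 1 for j in range(M)], dtype=bool)
        values[code] = _coalition_value(predict, background, instance, mask)

    from math import factorial

    phi = _exact_phi_from_values(values, M)
    inter = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            total = 0.0
            for code in range(2**M):
                if code >> i & 1 or code >> j & 1:
                    continue
                s = bin(code).count("1")
                weight = (
                    factorial(s) * factorial(M - s - 2) / (2.0 * factorial(M - 1))
                )
                delta = (
                    values[code | 1 << i | 1 << j]
                    - values[code | 1 << i]
                    - values[code | 1 << j]
                    + values[code]
                )
                total += weight * delta
            inter[i, j] = inter[j, i] = total
    for i in range(M):
        inter[i, i] = phi[i] - inter[i].sum()
    return inter


def _exact_phi_from_values(values: dict[int, float], M: int) -> np.ndarray:
    """Shapley values from a complete coalition-value table (permutation
    formula, used internally and as the small-M oracle)."""
    from math import factorial

    phi = np.zeros(M)
    for i in range(M):
        for code in range(2**M):
            if code >> i & 1:
                continue
            s = bin(code).count("1")
            weight = factorial(s) * factorial(M - s - 1) / factorial(M)
            phi[i] += weight * (values[code | 1 << i] - values[code])
    return phi


def single_gene_auc(study: ExpressionStudy, genes: Sequence[str]) -> pd.Series:
    """Mann-Whitney AUC of each gene's raw expression as a disease score."""
    genes = [g.upper() for g in genes]
    missing = [g for g in genes if g not in set(study.genes)]
    if missing:
        raise ShapError(f"genes absent from study: {missing}")
    y = study.labels
    frame = study.frame()
    return pd.Series(
        {g: mann_whitney_auc(y, frame.loc[g].to_numpy()) for g in genes},
        name="auc",
    )


def tidy_phi(phi_table: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Long-format (sample, gene, value, phi) table for external plotting."""
    rows = []
    for sample in phi_table.index:
        for gene in phi_table.columns:
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "value": float(features.loc[sample, gene]),
                    "phi": float(phi_table.loc[sample, gene]),
                }
            )
    return pd.DataFrame(rows)
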