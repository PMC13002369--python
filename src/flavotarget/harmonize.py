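"""Batch harmonization: surrogate-variable estimation, parametric
empirical-Bayes location/scale correction (ComBat), and PCA diagnostics.

The correction follows the standard parametric location/scale model: after
standardizing each gene against its design fit, per-batch location (gamma)
and scale (delta^2) effects are estimated, shrunk toward batch-level priors
(Normal for location, inverse-gamma for scale) by method-of-moments
empirical Bayes, and removed. The biological condition is always part of
the standardization design so the disease/control contrast is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from ._seeds import child_seed
from .study import DISEASE, ExpressionStudy

EB_TOL = 1e-6
EB_MAX_ITER = 100


class HarmonizeError(ValueError):
    pass


class ConfoundingError(HarmonizeError):
    """Batch and condition cannot be separated (a batch is single-condition)."""


# ---------------------------------------------------------------------------
# Surrogate variable estimation (residual SVD + permutation parallel analysis)
# ---------------------------------------------------------------------------


@dataclass
class SurrogateVariableSet:
    """Estimated latent covariates of unmodeled expression heterogeneity."""

    k: int
    sv_matrix: np.ndarray  # samples x k, orthonormal columns
    permutation_p: list[float]


def _condition_design(study: ExpressionStudy) -> np.ndarray:
    return np.column_stack([np.ones(study.n_samples), study.labels.astype(float)])


def estimate_surrogates(
    study: ExpressionStudy,
    n_permutations: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> SurrogateVariableSet:
    """Estimate surrogate variables from condition-adjusted residuals.

    Gene-wise expression is regressed on the condition design; the residual
    matrix is decomposed by SVD and the number of retained components k is
    set by permutation parallel analysis: a component is kept while its
    variance share exceeds the (1 - alpha) quantile of the share obtained
    after independently permuting each residual row, stopping at the first
    failure.
    """
    if n_permutations <= 0:
        raise HarmonizeError("n_permutations must be a positive integer")
    counts = np.bincount(study.labels, minlength=2)
    if counts.min() < 2:
        raise HarmonizeError("need >= 2 samples per condition")
    X = study.values
    W = _condition_design(study)
    beta, *_ = linalg.lstsq(W, X.T)
    resid = X - (W @ beta).T
    max_k = min(study.n_samples, study.n_genes)

    sv = linalg.svdvals(resid)
    total = (sv**2).sum()
    if total <= 1e-12:
        return SurrogateVariableSet(0, np.empty((study.n_samples, 0)), [])
    shares = sv**2 / total

    # residual-space projector: permuted rows are re-residualized against
    # the design so the null matches the observed matrix's constraints
    proj = np.eye(study.n_samples) - W @ linalg.solve(W.T @ W, W.T)
    rng = np.random.default_rng(child_seed(seed, "sva.permutation"))
    null_shares = np.empty((n_permutations, len(sv)))
    for b in range(n_permutations):
        perm = rng.permuted(resid, axis=1) @ proj
        psv = linalg.svdvals(perm)
        null_shares[b] = psv**2 / (psv**2).sum()

    thresholds = np.quantile(null_shares, 1.0 - alpha, axis=0)
    pvals: list[float] = []
    k = 0
    for i in range(len(sv)):
        p = (1 + np.sum(null_shares[:, i] >= shares[i])) / (n_permutations + 1)
        if shares[i] > thresholds[i]:
            k += 1
            pvals.append(float(p))
        else:
            break
    k = min(k, max_k)
    _, _, vt = linalg.svd(resid, full_matrices=False)
    return SurrogateVariableSet(k, vt[:k].T.copy(), pvals)


# ---------------------------------------------------------------------------
# Parametric empirical-Bayes batch correction
# ---------------------------------------------------------------------------


@dataclass
class CombatModel:
    """Fitted location/scale batch-correction model.

    Per-gene grand mean / condition coefficients / pooled variance, raw and
    EB-shrunk per-batch location and scale estimates, and the batch-level
    hyperparameters of the Normal location and inverse-gamma scale priors.
    """

    batches: list[str]
    grand_mean: np.ndarray            # alpha_g
    design_coef: np.ndarray           # condition (+ covariate) coefficients x genes
    pooled_var: np.ndarray            # sigma_g^2
    gamma_hat: dict[str, np.ndarray]
    gamma_star: dict[str, np.ndarray]
    delta_hat_sq: dict[str, np.ndarray]
    delta_star_sq: dict[str, np.ndarray]
    location_prior: dict[str, tuple[float, float]]   # (gamma_bar, tau_bar_sq)
    scale_prior: dict[str, tuple[float, float]]      # inverse-gamma (lambda, theta)
    flagged_genes: list[str] = field(default_factory=list)
    use_eb: bool = True


def _aprior(delta_hat_sq: np.ndarray) -> float:
    m, s2 = delta_hat_sq.mean(), delta_hat_sq.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat_sq: np.ndarray) -> float:
    m, s2 = delta_hat_sq.mean(), delta_hat_sq.var(ddof=1)
    return (m * s2 + m**3) / s2


def combat_adjust(
    study: ExpressionStudy,
    use_eb: bool = True,
    covariates: np.ndarray | None = None,
) -> tuple[ExpressionStudy, CombatModel]:
    """Remove per-batch location/scale effects from an expression study.

    With ``use_eb`` the per-batch per-gene estimates are shrunk toward
    method-of-moments priors and iterated to convergence; without it the raw
    estimates are used (useful as an oracle-checkable baseline). Genes with
    zero variance inside any batch cannot support scale shrinkage; they are
    flagged and restored unadjusted.
    """
    batches = study.cohort_ids
    if len(batches) < 2:
        raise HarmonizeError("combat_adjust requires >= 2 batches")
    cohort_arr = study.cohort_labels
    y = study.labels
    for b in batches:
        members = cohort_arr == b
        if members.sum() < 2:
            raise HarmonizeError(f"batch {b!r} has fewer than 2 samples")
        if len(np.unique(y[members])) < 2:
            raise ConfoundingError(
                f"batch {b!r} contains a single condition; batch and "
                "condition effects cannot be separated"
            )

    X = study.values
    n_genes, n_samples = X.shape
    batch_design = np.column_stack(
        [(cohort_arr == b).astype(float) for b in batches]
    )
    bio = y.astype(float)[:, None]
    if covariates is not None:
        covariates = np.asarray(covariates, float)
        if covariates.shape[0] != n_samples:
            raise HarmonizeError("covariates must be a sample x c matrix")
        bio = np.hstack([bio, covariates])
    W = np.hstack([batch_design, bio])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ConfoundingError("design matrix is rank-deficient")

    B_hat = linalg.solve(W.T @ W, W.T @ X.T)          # (n_batch + c) x genes
    n_per_batch = batch_design.sum(axis=0)
    grand_mean = (n_per_batch / n_samples) @ B_hat[: len(batches)]
    var_pooled = ((X - (W @ B_hat).T) ** 2).mean(axis=1)

    stand_mean = grand_mean[:, None] + (bio @ B_hat[len(batches):]).T
    sigma = np.sqrt(var_pooled)
    ok_var = sigma > 1e-12
    sigma_safe = np.where(ok_var, sigma, 1.0)
    Z = (X - stand_mean) / sigma_safe[:, None]

    gamma_hat: dict[str, np.ndarray] = {}
    gamma_star: dict[str, np.ndarray] = {}
    delta_hat_sq: dict[str, np.ndarray] = {}
    delta_star_sq: dict[str, np.ndarray] = {}
    loc_prior: dict[str, tuple[float, float]] = {}
    scale_prior: dict[str, tuple[float, float]] = {}

    degenerate = ~ok_var
    for b in batches:
        members = cohort_arr == b
        Zb = Z[:, members]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        gamma_hat[b] = g_hat
        delta_hat_sq[b] = d_hat
        degenerate |= d_hat <= 1e-12
    flagged = [study.genes[i] for i in np.flatnonzero(degenerate)]
    keep = ~degenerate

    Z_adj = Z.copy()
    for b in batches:
        members = cohort_arr == b
        n_b = int(members.sum())
        g_hat = gamma_hat[b][keep]
        d_hat = delta_hat_sq[b][keep]
        if use_eb and keep.sum() >= 3:
            gamma_bar = float(g_hat.mean())
            tau_sq = float(g_hat.var(ddof=1))
            lam = float(_aprior(d_hat))
            theta = float(_bprior(d_hat))
            loc_prior[b] = (gamma_bar, tau_sq)
            scale_prior[b] = (lam, theta)
            Zb = Z[np.ix_(keep, members)]
            g_star, d_star = g_hat.copy(), d_hat.copy()
            for _ in range(EB_MAX_ITER):
                g_new = (n_b * tau_sq * g_hat + d_star * gamma_bar) / (
                    n_b * tau_sq + d_star
                )
                sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (theta + 0.5 * sum2) / (n_b / 2.0 + lam - 1.0)
                change = max(
                    np.abs(g_new - g_star).max(initial=0.0),
                    np.abs(d_new - d_star).max(initial=0.0),
                )
                g_star, d_star = g_new, d_new
                if change < EB_TOL:
                    break
        else:
            g_star, d_star = g_hat, d_hat
            loc_prior[b] = (float("nan"), float("nan"))
            scale_prior[b] = (float("nan"), float("nan"))

        full_g = np.zeros(n_genes)
        full_d = np.ones(n_genes)
        full_g[keep] = g_star
        full_d[keep] = d_star
        gamma_star[b] = full_g
        delta_star_sq[b] = full_d
        block = Z_adj[np.ix_(keep, members)]
        Z_adj[np.ix_(keep, members)] = (block - g_star[:, None]) / np.sqrt(
            d_star
        )[:, None]

    X_adj = Z_adj * sigma_safe[:, None] + stand_mean
    X_adj[degenerate] = X[degenerate]  # restored unadjusted

    model = CombatModel(
        batches=batches,
        grand_mean=grand_mean,
        design_coef=B_hat[len(batches):],
        pooled_var=var_pooled,
        gamma_hat=gamma_hat,
        gamma_star=gamma_star,
        delta_hat_sq=delta_hat_sq,
        delta_star_sq=delta_star_sq,
        location_prior=loc_prior,
        scale_prior=scale_prior,
        flagged_genes=flagged,
        use_eb=use_eb,
    )
    return study.with_values(X_adj), model


# ---------------------------------------------------------------------------
# PCA diagnostics
# ---------------------------------------------------------------------------


def pca_embed(study: ExpressionStudy, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the top-k PCs of the gene-centered matrix.

    Returns a sample table with columns PC1..PCk plus cohort/condition, and
    the per-component variance-explained fractions. Deterministic sign
    convention: each component's largest-magnitude gene loading is positive.
    """
    if k <= 0:
        raise HarmonizeError("k must be a positive integer")
    if k > min(study.n_genes, study.n_samples):
        raise HarmonizeError("k exceeds matrix dimensions")
    Xc = study.values - study.values.mean(axis=1, keepdims=True)
    U, s, Vt = linalg.svd(Xc, full_matrices=False)
    # loadings live in U's columns; flip so the largest |loading| is positive
    for i in range(len(s)):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            U[:, i] *= -1
            Vt[i] *= -1
    total = (s**2).sum()
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    coords = (Vt[:k].T * s[:k])  # samples x k
    table = pd.DataFrame(
        coords, index=study.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    table["cohort"] = [study.cohort[sm] for sm in study.samples]
    table["condition"] = [study.condition[sm] for sm in study.samples]
    table.index.name = "sample_id"
    return table, frac[:k]
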