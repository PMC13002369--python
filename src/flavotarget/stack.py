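"""AUC-gated stacking of zoo base models.

Base models whose training out-of-fold AUC exceeds the gate (default 0.945)
contribute their OOF probabilities as meta-features for a ridge-penalized
logistic meta-learner fitted by IRLS. The ensemble is compared against the
best single model and an unweighted probability average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import binary_metrics
from .zoo import ModelRecord, predict_record

DEFAULT_GATE = 0.945


class StackError(ValueError):
    pass


class EmptyGateError(StackError):
    """No base model cleared the AUC gate; lower the threshold."""


def build_meta_features(
    records: Sequence[ModelRecord], gate: float = DEFAULT_GATE
) -> tuple[pd.DataFrame, list[str]]:
    """OOF-probability meta-feature matrix of gate-passing base models.

    Columns ordered by descending training OOF AUC, ties by spec id. The
    meta-features are strictly out-of-fold, so refitting base models on the
    full data cannot alter them.
    """
    if not records:
        raise StackError("no model records supplied")
    index = records[0].oof.index
    for r in records[1:]:
        if not r.oof.index.equals(index):
            raise StackError("records do not share a sample set")
    retained = [r for r in records if r.train_auc > gate]
    if not retained:
        raise EmptyGateError(
            f"no base model has training OOF AUC > {gate}; "
            "lower the gate threshold"
        )
    retained.sort(key=lambda r: (-r.train_auc, r.spec.spec_id))
    ids = [r.spec.spec_id for r in retained]
    matrix = pd.DataFrame({r.spec.spec_id: r.oof for r in retained})[ids]
    return matrix, ids


@dataclass
class StackedEnsemble:
    gate: float
    retained_ids: list[str]
    intercept: float
    coef: np.ndarray                 # one weight per retained model
    train_oof_auc: float
    n_iter: int
    converged: bool
    comparison: pd.DataFrame | None = field(default=None, repr=False)

    def predict_from_meta(self, meta: pd.DataFrame | np.ndarray) -> np.ndarray:
        M = (
            meta[self.retained_ids].to_numpy(dtype=float)
            if isinstance(meta, pd.DataFrame)
            else np.asarray(meta, dtype=float)
        )
        z = self.intercept + M @ self.coef
        return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "gate": self.gate,
                    "retained_ids": self.retained_ids,
                    "intercept": self.intercept,
                    "coef": self.coef.tolist(),
                    "train_oof_auc": self.train_oof_auc,
                    "converged": self.converged,
                },
                indent=2,
            )
        )


def fit_meta(
    meta: pd.DataFrame,
    labels,
    l2: float = 1e-4,
    gate: float = DEFAULT_GATE,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> StackedEnsemble:
    """Ridge-penalized logistic meta-learner fitted by IRLS.

    The small default penalty keeps coefficients finite when meta-features
    separate the classes (base models near AUC 1 often do). The intercept
    is unpenalized. Convergence: gradient max-norm below ``tol``.
    """
    M = meta.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)
    if M.shape[1] < 1:
        raise StackError("need at least one meta-feature")
    if not np.isfinite(M).all():
        raise StackError("meta-features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise StackError("both classes must be present")
    X = np.hstack([np.ones((M.shape[0], 1)), M])
    pen = np.full(X.shape[1], float(l2))
    pen[0] = 0.0
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-z))
        grad = X.T @ (y - p) - pen * beta
        if np.abs(grad).max() < tol:
            converged = True
            break
        w = np.maximum(p * (1 - p), 1e-10)
        H = (X * w[:, None]).T @ X + np.diag(pen)
        beta = beta + np.linalg.solve(H, grad)
    if not converged:
        import warnings

        warnings.warn(f"meta-learner IRLS stopped at {max_iter} iterations", stacklevel=2)
    ens = StackedEnsemble(
        gate=gate,
        retained_ids=list(meta.columns),
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        train_oof_auc=float("nan"),
        n_iter=it,
        converged=converged,
    )
    ens.train_oof_auc = binary_metrics(y.astype(int), ens.predict_from_meta(meta))["auc"]
    return ens


def compare_ensembles(
    ensemble: StackedEnsemble,
    records: Sequence[ModelRecord],
    labels,
    validation: Mapping[str, tuple[pd.DataFrame, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Stacking vs best single model vs simple averaging.

    Rows: (cohort, strategy); columns AUC/accuracy/F1. Training rows use
    OOF probabilities; validation entries are scored from base-model
    probability matrices supplied per cohort (columns = retained ids).
    """
    y = np.asarray(labels, dtype=int)
    by_id = {r.spec.spec_id: r for r in records}
    retained = [by_id[i] for i in ensemble.retained_ids]
    meta = pd.DataFrame({r.spec.spec_id: r.oof for r in retained})[
        ensemble.retained_ids
    ]
    best = max(retained, key=lambda r: (r.train_auc, r.spec.spec_id))

    rows = []
    strategies = {
        "stacking": ensemble.predict_from_meta(meta),
        "best_single": best.oof.to_numpy(),
        "simple_average": meta.to_numpy().mean(axis=1),
    }
    for name, prob in strategies.items():
        rows.append({"cohort": "train_oof", "strategy": name,
                     **binary_metrics(y, prob)})
    if validation:
        for cohort, (val_meta, val_y) in validation.items():
            val_probs = {
                "stacking": ensemble.predict_from_meta(val_meta),
                "best_single": val_meta[best.spec.spec_id].to_numpy(),
                "simple_average": val_meta[ensemble.retained_ids]
                .to_numpy()
                .mean(axis=1),
            }
            for name, prob in val_probs.items():
                rows.append({"cohort": cohort, "strategy": name,
                             **binary_metrics(val_y, prob)})
    table = pd.DataFrame(rows)
    ensemble.comparison = table
    return table


def base_probability_matrix(
    records: Sequence[ModelRecord],
    retained_ids: Sequence[str],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Probability matrix of the refit base models on new samples."""
    by_id = {r.spec.spec_id: r for r in records}
    return pd.DataFrame(
        {i: predict_record(by_id[i], features) for i in retained_ids},
        index=features.index,
    )[list(retained_ids)]


def stacked_predict_function(
    records: Sequence[ModelRecord],
    ensemble: StackedEnsemble,
    panel_genes: Sequence[str],
):
    """Compose refit base models + meta-learner into one probability
    function over samples x panel arrays (the SHAP prediction target)."""
    by_id = {r.spec.spec_id: r for r in records}
    retained = [by_id[i] for i in ensemble.retained_ids]
    panel = list(panel_genes)

    def predict(X: np.ndarray) -> np.ndarray:
        frame = pd.DataFrame(np.asarray(X, dtype=float), columns=panel)
        meta = np.column_stack([predict_record(r, frame) for r in retained])
        return ensemble.predict_from_meta(meta)

    return predict
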