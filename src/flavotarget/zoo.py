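"""The multi-algorithm model zoo: enumeration, nested cross-validation,
out-of-fold probabilities, per-cohort metrics, importances and selected
gene sets.

Twelve classifier families (lasso, ridge, enet, svm, glmboost, plsr-glm,
stepglm, rf, gbm, lda, naive-bayes, xgboost) are combined with optional
feature-selector stages. All tuning happens inside the outer training
folds (5-fold stratified by default, inner 5-fold grid on AUC) so the
out-of-fold probabilities that feed stacking are leakage-free.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._seeds import child_seed
from .estimators import (
    ComponentwiseLogitBoost,
    PLSLogisticRegression,
    StepwiseLogisticRegression,
)
from .metrics import binary_metrics, mann_whitney_auc
from .study import ExpressionStudy


class ZooError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

#: importance kinds: "coef" = |standardized coefficient| from the (scaled)
#: linear fit; "impurity" = tree impurity importances; "permutation" =
#: out-of-fold permutation importance (10 repeats).


def _scaled(clf) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _final(est):
    return est[-1] if isinstance(est, Pipeline) else est


# grids are ordered most-regularized first so score ties resolve toward the
# stronger penalty
CLASSIFIERS: dict[str, dict] = {
    "lasso": dict(
        factory=lambda seed: _scaled(
            LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=2000,
                               random_state=seed)
        ),
        grid={"clf__C": [0.1, 1.0]},
        importance="coef",
        sparse=True,
    ),
    "ridge": dict(
        factory=lambda seed: _scaled(LogisticRegression(max_iter=2000)),
        grid={"clf__C": [0.1, 1.0]},
        importance="coef",
        sparse=False,
    ),
    "enet": dict(
        factory=lambda seed: _scaled(
            LogisticRegression(
                solver="saga", l1_ratio=0.5, max_iter=5000, random_state=seed
            )
        ),
        grid={"clf__C": [0.1, 1.0]},
        importance="coef",
        sparse=True,
    ),
    "svm": dict(
        # sigmoid-calibrated linear SVM so the zoo gets probabilities
        factory=lambda seed: _scaled(
            CalibratedClassifierCV(
                SVC(kernel="linear", random_state=seed),
                method="sigmoid", cv=3, ensemble=False,
            )
        ),
        grid={"clf__estimator__C": [0.1, 1.0]},
        importance="permutation",
        sparse=False,
    ),
    "glmboost": dict(
        factory=lambda seed: ComponentwiseLogitBoost(),
        grid={"n_steps": [50, 100]},
        importance="coef",
        sparse=True,
    ),
    "plsr-glm": dict(
        factory=lambda seed: PLSLogisticRegression(),
        grid={"n_components": [1, 2]},
        importance="permutation",
        sparse=False,
    ),
    "stepglm": dict(
        factory=lambda seed: StepwiseLogisticRegression(max_features=8),
        grid={},
        importance="coef",
        sparse=True,
    ),
    "rf": dict(
        factory=lambda seed: RandomForestClassifier(
            n_estimators=80, random_state=seed, n_jobs=1
        ),
        grid={"max_depth": [3, None]},
        importance="impurity",
        sparse=False,
    ),
    "gbm": dict(
        factory=lambda seed: GradientBoostingClassifier(
            n_estimators=60, random_state=seed
        ),
        grid={},
        importance="impurity",
        sparse=False,
    ),
    "lda": dict(
        factory=lambda seed: _scaled(LinearDiscriminantAnalysis()),
        grid={},
        importance="coef",
        sparse=False,
    ),
    "naive-bayes": dict(
        factory=lambda seed: GaussianNB(),
        grid={},
        importance="permutation",
        sparse=False,
    ),
    "xgboost": dict(
        factory=lambda seed: XGBClassifier(
            n_estimators=60,
            max_depth=3,
            learning_rate=0.3,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
            tree_method="hist",
        ),
        grid={},
        importance="impurity",
        sparse=False,
    ),
}

FAMILIES: tuple[str, ...] = tuple(CLASSIFIERS)


def _select_nonzero(coef: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.abs(coef) > 1e-10)


def _selector_lasso(X, y, seed):
    est = _scaled(LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                     max_iter=2000, random_state=seed)).fit(X, y)
    return _select_nonzero(_final(est).coef_[0])


def _selector_enet(X, y, seed):
    est = _scaled(
        LogisticRegression(solver="saga", l1_ratio=0.5,
                           C=1.0, max_iter=5000, random_state=seed)
    ).fit(X, y)
    return _select_nonzero(_final(est).coef_[0])


def _selector_glmboost(X, y, seed):
    est = ComponentwiseLogitBoost().fit(X, y)
    return _select_nonzero(est.coef_[0])


def _selector_stepglm(X, y, seed):
    est = StepwiseLogisticRegression(max_features=8).fit(X, y)
    return np.array(sorted(est.features_), dtype=int)


def _top_half(importance: np.ndarray) -> np.ndarray:
    if importance.max(initial=0.0) <= 0:
        return np.array([], dtype=int)
    cut = np.median(importance)
    keep = np.flatnonzero(importance >= cut)
    return keep


def _selector_rf(X, y, seed):
    est = RandomForestClassifier(n_estimators=80, random_state=seed, n_jobs=1)
    est.fit(X, y)
    return _top_half(est.feature_importances_)


def _selector_xgb(X, y, seed):
    est = XGBClassifier(
        n_estimators=60, max_depth=3, learning_rate=0.3, random_state=seed,
        n_jobs=1, verbosity=0, eval_metric="logloss", tree_method="hist",
    )
    est.fit(X, y)
    return _top_half(est.feature_importances_)


def _selector_svm_rfe(X, y, seed):
    n_keep = max(1, X.shape[1] // 2)
    rfe = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=n_keep)
    rfe.fit(X, y)
    return np.flatnonzero(rfe.support_)


SELECTORS: dict[str, Callable] = {
    "lasso": _selector_lasso,
    "enet": _selector_enet,
    "glmboost": _selector_glmboost,
    "stepglm": _selector_stepglm,
    "rf-filter": _selector_rf,
    "xgb-filter": _selector_xgb,
    "svm-rfe": _selector_svm_rfe,
}


# ---------------------------------------------------------------------------
# Spec enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    spec_id: str
    selector: str | None
    classifier: str


def enumerate_models(
    classifiers: Sequence[str] = FAMILIES,
    selectors: Sequence[str] = (),
    include_standalone: bool = True,
) -> list[ModelSpec]:
    """Deterministic spec list: each classifier standalone, then each
    enabled (selector, classifier) pair in configuration order."""
    for name in classifiers:
        if name not in CLASSIFIERS:
            raise ZooError(f"unknown classifier family {name!r}")
    for name in selectors:
        if name not in SELECTORS:
            raise ZooError(f"unknown selector {name!r}")
    specs: list[ModelSpec] = []
    if include_standalone:
        for clf in classifiers:
            specs.append(ModelSpec(clf, None, clf))
    for sel, clf in itertools.product(selectors, classifiers):
        specs.append(ModelSpec(f"{sel}>{clf}", sel, clf))
    if not specs:
        raise ZooError("model registry configuration is empty")
    return specs


def manifest_text(specs: Sequence[ModelSpec]) -> str:
    lines = [f"{i + 1}\t{s.spec_id}" for i, s in enumerate(specs)]
    lines.append(f"total\t{len(specs)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cross-validated fitting
# ---------------------------------------------------------------------------


@dataclass
class ModelRecord:
    spec: ModelSpec
    tuned_params: dict
    oof: pd.Series                       # sample -> P(disease)
    metrics: dict                        # {"overall": {...}, "per_cohort": {...}}
    importance: pd.Series                # gene -> non-negative real
    selected: frozenset
    fitted: dict = field(repr=False, default=None)       # {"estimator", "genes"}
    fold_models: list = field(repr=False, default=None)  # [(test_idx, est, gene_idx)]

    @property
    def train_auc(self) -> float:
        return self.metrics["overall"]["auc"]


def _param_combos(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


def _inner_search(family: dict, X: np.ndarray, y: np.ndarray, seed: int):
    """Fit the family on (X, y) choosing grid params by inner stratified CV
    on AUC; ties resolve to the earliest (most regularized) combination."""
    combos = _param_combos(family["grid"])
    best_combo = combos[0]
    if len(combos) > 1:
        n_splits = min(5, int(np.bincount(y).min()))
        if n_splits >= 2:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            best_score = -np.inf
            for combo in combos:
                scores = []
                for tr, te in skf.split(X, y):
                    est = clone(family["factory"](seed)).set_params(**combo)
                    est.fit(X[tr], y[tr])
                    scores.append(mann_whitney_auc(y[te], est.predict_proba(X[te])[:, 1]))
                score = float(np.mean(scores))
                if score > best_score + 1e-12:
                    best_score, best_combo = score, combo
    est = clone(family["factory"](seed)).set_params(**best_combo)
    est.fit(X, y)
    return est, best_combo


def _coef_importance(est, X: np.ndarray) -> np.ndarray:
    final = _final(est)
    coef = np.abs(np.ravel(final.coef_))
    if isinstance(est, Pipeline) or isinstance(final, ComponentwiseLogitBoost):
        return coef  # fitted on standardized inputs already
    return coef * X.std(axis=0)


def _oof_permutation_importance(
    fold_models, X: np.ndarray, y: np.ndarray, oof: np.ndarray,
    n_repeats: int, seed: int,
) -> np.ndarray:
    base = mann_whitney_auc(y, oof)
    rng = np.random.default_rng(seed)
    imp = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drop = 0.0
        for _ in range(n_repeats):
            oof_perm = oof.copy()
            touched = False
            for test_idx, est, gene_idx in fold_models:
                if j not in gene_idx:
                    continue
                touched = True
                Xt = X[np.ix_(test_idx, gene_idx)].copy()
                pos = gene_idx.index(j)
                Xt[:, pos] = Xt[rng.permutation(len(test_idx)), pos]
                oof_perm[test_idx] = est.predict_proba(Xt)[:, 1]
            if touched:
                drop += base - mann_whitney_auc(y, oof_perm)
        imp[j] = max(drop / n_repeats, 0.0)
    return imp


def run_cv(
    spec: ModelSpec,
    features: pd.DataFrame,
    labels,
    k_folds: int = 5,
    seed: int = 0,
    cohorts: Sequence[str] | None = None,
) -> ModelRecord:
    """Nested cross-validation of one zoo spec.

    For each outer fold the selector (if any) and classifier tuning see the
    training folds only; held-out probabilities are assembled into the
    out-of-fold vector. Importances and the selected gene set come from a
    final refit on the full training data.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    genes = list(features.columns)
    counts = np.bincount(y, minlength=2)
    for cls, cnt in enumerate(counts):
        if cnt < k_folds:
            raise ZooError(
                f"class {cls} has {cnt} samples, fewer than k_folds={k_folds}"
            )
    family = CLASSIFIERS[spec.classifier]
    fold_seed = child_seed(seed, f"zoo.{spec.spec_id}")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=fold_seed)

    oof = np.full(len(y), np.nan)
    fold_models: list[tuple[np.ndarray, object, list[int]]] = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        if spec.selector is not None:
            sel_idx = SELECTORS[spec.selector](X[tr], y[tr], fold_seed + f)
            sel_idx = sorted(int(i) for i in sel_idx) or list(range(len(genes)))
        else:
            sel_idx = list(range(len(genes)))
        est, _ = _inner_search(family, X[np.ix_(tr, sel_idx)], y[tr], fold_seed + f)
        oof[te] = est.predict_proba(X[np.ix_(te, sel_idx)])[:, 1]
        fold_models.append((te, est, sel_idx))
    assert not np.isnan(oof).any()

    metrics = {"overall": binary_metrics(y, oof), "per_cohort": {}}
    if cohorts is not None:
        cohorts = np.asarray(cohorts)
        for c in dict.fromkeys(cohorts):
            m = cohorts == c
            if len(np.unique(y[m])) == 2:
                metrics["per_cohort"][str(c)] = binary_metrics(y[m], oof[m])

    # full-data refit for the deployable model, importances and selection
    if spec.selector is not None:
        full_sel = SELECTORS[spec.selector](X, y, fold_seed + k_folds)
        full_sel = sorted(int(i) for i in full_sel) or list(range(len(genes)))
    else:
        full_sel = list(range(len(genes)))
    fitted_est, tuned = _inner_search(
        family, X[:, full_sel], y, fold_seed + k_folds + 1
    )

    importance = np.zeros(len(genes))
    kind = family["importance"]
    if kind == "coef":
        importance[full_sel] = _coef_importance(fitted_est, X[:, full_sel])
    elif kind == "impurity":
        importance[full_sel] = np.asarray(fitted_est.feature_importances_, float)
    elif kind == "permutation":
        importance = _oof_permutation_importance(
            fold_models, X, y, oof, n_repeats=10,
            seed=child_seed(seed, f"zoo.perm.{spec.spec_id}"),
        )
    else:  # pragma: no cover - registry is closed
        raise ZooError(f"unknown importance kind {kind!r}")

    if family["sparse"]:
        sel_mask = importance > 1e-10
    else:
        positive = importance > 0
        if positive.any():
            cut = np.percentile(importance, 75)
            sel_mask = (importance > cut) & positive
            if not sel_mask.any():
                sel_mask = positive & (importance >= importance.max())
        else:
            sel_mask = positive
    selected = frozenset(g for g, s in zip(genes, sel_mask) if s)

    return ModelRecord(
        spec=spec,
        tuned_params=dict(tuned),
        oof=pd.Series(oof, index=features.index, name=spec.spec_id),
        metrics=metrics,
        importance=pd.Series(importance, index=genes, name=spec.spec_id),
        selected=selected,
        fitted={"estimator": fitted_est, "genes": [genes[i] for i in full_sel]},
        fold_models=fold_models,
    )


def predict_record(record: ModelRecord, features: pd.DataFrame) -> np.ndarray:
    """P(disease) from the full-train refit on a samples x panel matrix."""
    cols = record.fitted["genes"]
    return record.fitted["estimator"].predict_proba(
        features.loc[:, cols].to_numpy(dtype=float)
    )[:, 1]


def external_feature_matrix(
    val_study: ExpressionStudy,
    panel_genes: Sequence[str],
    train_means: pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Validation samples x panel matrix; absent genes mean-imputed from
    training. Returns the matrix and the gene-coverage fraction."""
    panel = [g.upper() for g in panel_genes]
    present = [g for g in panel if g in set(val_study.genes)]
    if not present:
        raise ZooError("validation study shares no panel genes with training")
    coverage = len(present) / len(panel)
    if coverage < 0.5:
        warnings.warn(
            f"validation gene coverage {coverage:.0%} below 50%; "
            "imputing missing panel genes from training means",
            stacklevel=2,
        )
    frame = val_study.feature_frame(present)
    out = pd.DataFrame(index=frame.index, columns=panel, dtype=float)
    for g in panel:
        out[g] = frame[g] if g in present else float(train_means[g])
    return out, coverage


def evaluate_external(
    record: ModelRecord,
    val_study: ExpressionStudy,
    panel_genes: Sequence[str],
    train_means: pd.Series,
) -> dict:
    """Metrics of the refit model on one external validation study."""
    Xv, coverage = external_feature_matrix(val_study, panel_genes, train_means)
    prob = predict_record(record, Xv)
    out = binary_metrics(val_study.labels, prob)
    out["coverage"] = coverage
    return out
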