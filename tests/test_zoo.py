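"""Model zoo: spec enumeration, leakage-free nested CV, the Mann-Whitney
AUC oracle, stratification and external evaluation."""

import numpy as np
import pandas as pd
import pytest

from flavotarget.metrics import MetricError, mann_whitney_auc
from flavotarget.study import ExpressionStudy
from flavotarget.zoo import (
    FAMILIES,
    ModelSpec,
    ZooError,
    enumerate_models,
    evaluate_external,
    external_feature_matrix,
    manifest_text,
    predict_record,
    run_cv,
)

from conftest import make_study


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def test_standalone_enumeration_counts_twelve():
    specs = enumerate_models(selectors=())
    assert len(specs) == 12
    assert len({s.spec_id for s in specs}) == 12


def test_selector_pairs_double_the_count():
    specs = enumerate_models(selectors=("lasso",))
    assert len(specs) == 24


def test_unknown_family_rejected():
    with pytest.raises(ZooError):
        enumerate_models(classifiers=("lasso", "deep-net"))
    with pytest.raises(ZooError):
        enumerate_models(selectors=("pca",))


def test_manifest_bytes_stable():
    a = manifest_text(enumerate_models(selectors=("lasso", "rf-filter")))
    b = manifest_text(enumerate_models(selectors=("lasso", "rf-filter")))
    assert a == b
    assert a.endswith("total\t36\n")


# ---------------------------------------------------------------------------
# AUC oracle
# ---------------------------------------------------------------------------


def _auc_brute_force(y, s):
    pos = [v for v, t in zip(s, y) if t == 1]
    neg = [v for v, t in zip(s, y) if t == 0]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def test_auc_matches_pairwise_oracle_with_ties():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n = rng.integers(10, 60)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        assert mann_whitney_auc(y, s) == pytest.approx(
            _auc_brute_force(y, s), abs=1e-12
        )


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=50)
    y[0], y[1] = 0, 1
    s = rng.normal(size=50)
    base = mann_whitney_auc(y, s)
    for f in (np.exp, np.tanh, lambda x: 3 * x + 7, lambda x: x**3):
        assert mann_whitney_auc(y, f(s)) == pytest.approx(base, abs=1e-12)


def test_auc_requires_both_classes():
    with pytest.raises(MetricError):
        mann_whitney_auc(np.ones(5), np.arange(5))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _toy_features(n=100, d=4, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    X = rng.normal(size=(n, d))
    X[y == 1, :2] += sep
    cols = [f"G{i}" for i in range(d)]
    return pd.DataFrame(X, columns=cols,
                        index=[f"S{i}" for i in range(n)]), y


@pytest.mark.parametrize("classifier", ["lasso", "rf", "lda"])
def test_separable_toy_reaches_perfect_oof_auc(classifier):
    X, y = _toy_features(sep=10.0)
    rec = run_cv(ModelSpec(classifier, None, classifier), X, y, seed=1)
    assert rec.train_auc == pytest.approx(1.0)


def test_permuted_labels_score_at_chance():
    aucs = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        X, y = _toy_features(n=60, sep=0.0, seed=seed)
        rng.shuffle(y)
        if np.bincount(y, minlength=2).min() < 5:
            continue
        rec = run_cv(ModelSpec("lda", None, "lda"), X, y, seed=seed)
        aucs.append(rec.train_auc)
    assert 0.4 < np.mean(aucs) < 0.6


def test_oof_probabilities_come_from_held_out_models():
    """Each sample is predicted exactly once, by the estimator fitted on
    the complementary folds (no test-fold leakage by construction)."""
    X, y = _toy_features(n=60, sep=2.0, seed=5)
    rec = run_cv(ModelSpec("lasso", None, "lasso"), X, y, seed=7)
    Xm = X.to_numpy()
    covered = np.zeros(len(y), dtype=int)
    for test_idx, est, sel in rec.fold_models:
        covered[test_idx] += 1
        np.testing.assert_allclose(
            rec.oof.to_numpy()[test_idx],
            est.predict_proba(Xm[np.ix_(test_idx, sel)])[:, 1],
        )
    assert (covered == 1).all()


def test_stratified_fold_proportions():
    X, y = _toy_features(n=96, sep=1.0, seed=6)
    y[:60], y[60:] = 1, 0  # 5:3 imbalance
    rec = run_cv(ModelSpec("lda", None, "lda"), X, y, seed=3)
    global_pos = y.sum() / len(y)
    for test_idx, _, _ in rec.fold_models:
        fold_pos = y[test_idx].sum()
        expected = global_pos * len(test_idx)
        assert abs(fold_pos - expected) <= 1.0


def test_small_class_rejected():
    X, y = _toy_features(n=12, sep=1.0)
    y[:] = 0
    y[:3] = 1  # only 3 positives, fewer than 5 folds
    with pytest.raises(ZooError, match="class 1"):
        run_cv(ModelSpec("lda", None, "lda"), X, y, seed=0)


def test_selector_restricts_feature_use():
    X, y = _toy_features(n=80, sep=6.0, seed=9)
    rec = run_cv(ModelSpec("lasso>lda", "lasso", "lda"), X, y, seed=4)
    assert set(rec.fitted["genes"]) <= set(X.columns)
    assert rec.selected <= set(X.columns)
    # importance lives only on genes available to the classifier
    zeroed = set(X.columns) - set(rec.fitted["genes"])
    assert all(rec.importance[g] == 0 for g in zeroed)


# ---------------------------------------------------------------------------
# external evaluation
# ---------------------------------------------------------------------------


def _study_from_features(X, y, cohort="V1"):
    genes = list(X.columns)
    samples = list(X.index)
    return ExpressionStudy(
        genes, samples, X.to_numpy().T,
        {s: cohort for s in samples},
        {s: ("disease" if t else "control") for s, t in zip(samples, y)},
    )


def test_identity_validation_matches_training_refit():
    X, y = _toy_features(n=60, sep=3.0, seed=10)
    rec = run_cv(ModelSpec("ridge", None, "ridge"), X, y, seed=2)
    val = _study_from_features(X, y)
    out = evaluate_external(rec, val, list(X.columns), X.mean(axis=0))
    refit_auc = mann_whitney_auc(y, predict_record(rec, X))
    assert out["auc"] == pytest.approx(refit_auc, abs=1e-12)
    assert out["coverage"] == 1.0


def test_flipped_validation_labels_mirror_auc():
    X, y = _toy_features(n=60, sep=3.0, seed=11)
    rec = run_cv(ModelSpec("ridge", None, "ridge"), X, y, seed=2)
    out = evaluate_external(rec, _study_from_features(X, y), list(X.columns),
                            X.mean(axis=0))
    flipped = evaluate_external(rec, _study_from_features(X, 1 - y),
                                list(X.columns), X.mean(axis=0))
    assert flipped["auc"] == pytest.approx(1.0 - out["auc"], abs=1e-12)


def test_missing_genes_mean_imputed_with_warning():
    X, y = _toy_features(n=40, sep=3.0, seed=12)
    val = _study_from_features(X.iloc[:, :1], y)  # 1 of 4 genes present
    with pytest.warns(UserWarning, match="coverage"):
        Xv, coverage = external_feature_matrix(val, list(X.columns), X.mean(axis=0))
    assert coverage == 0.25
    for g in X.columns[1:]:
        np.testing.assert_allclose(Xv[g].to_numpy(), X[g].mean())


def test_no_shared_genes_rejected():
    X, y = _toy_features(n=40, sep=3.0, seed=13)
    other = X.rename(columns={c: f"Z{c}" for c in X.columns})
    val = _study_from_features(other, y)
    with pytest.raises(ZooError):
        external_feature_matrix(val, list(X.columns), X.mean(axis=0))


def test_synthetic_held_out_cohort_scores_high():
    """A held-out cohort from the same generator is classified with
    AUC >= 0.9 at effect 2."""
    from flavotarget.synth import SyntheticConfig, generate_cohorts

    cfg = SyntheticConfig(n_cohorts=2, samples_per_cohort=((40, 40), (20, 20)),
                         n_genes=300, n_informative=4, effect_size=2.0,
                         batch_shift_sd=0.5, batch_scale_sd=0.1, seed=55)
    full, truth = generate_cohorts(cfg)
    train_samples = [s for s in full.samples if full.cohort[s] == "COHORT1"]
    val_samples = [s for s in full.samples if full.cohort[s] == "COHORT2"]
    idx_t = [full.samples.index(s) for s in train_samples]
    idx_v = [full.samples.index(s) for s in val_samples]
    train = ExpressionStudy(full.genes, train_samples, full.values[:, idx_t],
                            full.cohort, full.condition)
    val = ExpressionStudy(full.genes, val_samples, full.values[:, idx_v],
                          full.cohort, full.condition)
    panel = truth.informative_genes
    X = train.feature_frame(panel)
    rec = run_cv(ModelSpec("ridge", None, "ridge"), X, train.labels, seed=1)
    out = evaluate_external(rec, val, panel, X.mean(axis=0))
    assert out["auc"] >= 0.9
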