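"""Harmonization: surrogate-variable calibration, the standardize-restore
oracle for the no-shrinkage path, batch-effect removal, signal preservation
and the PCA diagnostics."""

import numpy as np
import pytest
from scipy import stats

from flavotarget.harmonize import (
    CombatModel,
    ConfoundingError,
    HarmonizeError,
    combat_adjust,
    estimate_surrogates,
    pca_embed,
)
from flavotarget.study import ExpressionStudy
from flavotarget.synth import SyntheticConfig, generate_cohorts

from conftest import make_study


# ---------------------------------------------------------------------------
# surrogate variables
# ---------------------------------------------------------------------------


def test_pure_noise_yields_no_surrogates():
    """Under the null (no batch, no signal) k=0 in >= 90% of replicates."""
    zeros = 0
    for rep in range(20):
        cfg = SyntheticConfig(n_cohorts=1, samples_per_cohort=((15, 15),),
                             n_genes=300, n_informative=0, effect_size=0.0,
                             batch_shift_sd=0.0, batch_scale_sd=0.0,
                             seed=100 + rep)
        study, _ = generate_cohorts(cfg)
        svs = estimate_surrogates(study, n_permutations=20, alpha=0.05,
                                  seed=rep)
        zeros += svs.k == 0
    assert zeros >= 18


def test_planted_batch_axis_is_detected():
    cfg = SyntheticConfig(n_cohorts=2, samples_per_cohort=((15, 15), (15, 15)),
                         n_genes=500, n_informative=0, effect_size=0.0,
                         batch_shift_sd=3.0, batch_scale_sd=0.0, noise_sd=1.0,
                         seed=41)
    study, _ = generate_cohorts(cfg)
    svs = estimate_surrogates(study, n_permutations=20, seed=1)
    assert svs.k >= 1
    batch = (study.cohort_labels == study.cohort_ids[0]).astype(float)
    r = np.corrcoef(svs.sv_matrix[:, 0], batch)[0, 1]
    assert abs(r) > 0.9


def test_sv_columns_orthonormal(planted_study):
    study, _ = planted_study
    svs = estimate_surrogates(study, n_permutations=10, seed=2)
    if svs.k:
        gram = svs.sv_matrix.T @ svs.sv_matrix
        np.testing.assert_allclose(gram, np.eye(svs.k), atol=1e-10)


def test_zero_permutations_rejected(null_study):
    with pytest.raises(HarmonizeError):
        estimate_surrogates(null_study, n_permutations=0)


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


def _standardize_restore_oracle(study):
    """Independent per-gene oracle for the no-shrinkage path: standardize
    against the batch+condition fit, remove raw per-batch mean/sd on the
    standardized scale, restore."""
    X = study.values.astype(float)
    batches = study.cohort_ids
    cohort = study.cohort_labels
    y = study.labels.astype(float)
    out = np.empty_like(X)
    for g in range(X.shape[0]):
        x = X[g]
        design = np.column_stack(
            [(cohort == b).astype(float) for b in batches] + [y]
        )
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        n_i = np.array([(cohort == b).sum() for b in batches], float)
        alpha = float(n_i @ coef[: len(batches)] / n_i.sum())
        fitted = design @ coef
        sigma = np.sqrt(np.mean((x - fitted) ** 2))
        stand_mean = alpha + y * coef[-1]
        z = (x - stand_mean) / sigma
        z_adj = np.empty_like(z)
        for b in batches:
            m = cohort == b
            z_adj[m] = (z[m] - z[m].mean()) / z[m].std(ddof=1)
        out[g] = z_adj * sigma + stand_mean
    return out


def test_no_eb_matches_standardize_restore_oracle(planted_study):
    study, _ = planted_study
    corrected, model = combat_adjust(study, use_eb=False)
    oracle = _standardize_restore_oracle(study)
    np.testing.assert_allclose(corrected.values, oracle, atol=1e-8)


def test_single_batch_rejected():
    study = make_study(np.random.default_rng(0).normal(size=(10, 12)), 6, 6)
    with pytest.raises(HarmonizeError):
        combat_adjust(study)


def test_confounded_batch_rejected():
    rng = np.random.default_rng(1)
    # batch 2 is all-disease: inseparable from condition
    study = make_study(
        rng.normal(size=(10, 12)), 6, 6,
        cohorts=["A"] * 3 + ["B"] * 3 + ["A"] * 6,
    )
    with pytest.raises(ConfoundingError):
        combat_adjust(study)


def _batch_rejection_fraction(study, alpha=0.05):
    groups = [study.values[:, study.cohort_labels == c].T for c in study.cohort_ids]
    _, p = stats.f_oneway(*groups, axis=0)
    return float((p < alpha).mean())


def test_eb_correction_removes_batch_structure():
    """Planted shifts push the batch-ANOVA rejection fraction far above
    alpha; after correction it falls to at most alpha (+ binomial noise)."""
    cfg = SyntheticConfig(n_cohorts=2, samples_per_cohort=((30, 30), (30, 30)),
                         n_genes=2000, n_informative=0, effect_size=0.0,
                         batch_shift_sd=1.0, batch_scale_sd=0.25, seed=7)
    study, _ = generate_cohorts(cfg)
    before = _batch_rejection_fraction(study)
    corrected, _ = combat_adjust(study, use_eb=True)
    after = _batch_rejection_fraction(corrected)
    half = 3 * np.sqrt(0.05 * 0.95 / 2000)
    assert before > 0.5
    assert after <= 0.05 + half


def test_condition_effect_preserved(planted_study):
    """The planted disease effect survives correction (difference of the
    oracle estimates before vs after < 0.1 * effect size)."""
    study, truth = planted_study

    def oracle_effect(st):
        diffs = []
        for gene in truth.informative_genes:
            row = st.values[st.genes.index(gene)]
            for cid in st.cohort_ids:
                m = st.cohort_labels == cid
                diffs.append(row[m & st.disease_mask].mean()
                             - row[m & ~st.disease_mask].mean())
        return float(np.mean(diffs))

    corrected, _ = combat_adjust(study, use_eb=True)
    assert abs(oracle_effect(corrected) - oracle_effect(study)) < 0.1 * truth.effect_size


def test_eb_shrinkage_contracts(planted_study):
    study, _ = planted_study
    _, model = combat_adjust(study, use_eb=True)
    keep = [g not in set(model.flagged_genes) for g in study.genes]
    for b in model.batches:
        gamma_bar = model.location_prior[b][0]
        raw = np.abs(model.gamma_hat[b][keep] - gamma_bar)
        shrunk = np.abs(model.gamma_star[b][keep] - gamma_bar)
        assert np.all(shrunk <= raw + 1e-12)


def test_correction_is_idempotent(planted_study):
    """Without shrinkage the per-batch estimates vanish exactly on a second
    pass; with shrinkage the deliberate EB residual remains but contracts
    strongly."""
    study, _ = planted_study
    corrected_raw, _ = combat_adjust(study, use_eb=False)
    _, second_raw = combat_adjust(corrected_raw, use_eb=False)
    for b in second_raw.batches:
        assert np.abs(second_raw.gamma_hat[b]).max() < 1e-6
    corrected_eb, first_eb = combat_adjust(study, use_eb=True)
    _, second_eb = combat_adjust(corrected_eb, use_eb=True)
    for b in second_eb.batches:
        assert (np.abs(second_eb.gamma_hat[b]).max()
                < 0.25 * np.abs(first_eb.gamma_hat[b]).max())


def test_zero_variance_gene_restored_unadjusted():
    rng = np.random.default_rng(3)
    values = rng.normal(size=(5, 16))
    values[0] = 1.0  # flat gene
    study = make_study(values, 8, 8,
                       cohorts=["A"] * 4 + ["B"] * 4 + ["A"] * 4 + ["B"] * 4)
    corrected, model = combat_adjust(study)
    assert study.genes[0] in model.flagged_genes
    np.testing.assert_array_equal(corrected.values[0], values[0])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_rank_one_matrix_has_unit_variance_fraction():
    u = np.arange(1, 7, dtype=float)
    v = np.array([1.0, -2.0, 0.5, 3.0, 1.5, -1.0, 0.2, 2.0])
    study = make_study(np.outer(u, v), 4, 4)
    _, frac = pca_embed(study, k=1)
    assert frac[0] == pytest.approx(1.0, abs=1e-10)


def test_full_rank_projection_reconstructs_matrix(null_study):
    k = min(null_study.n_genes, null_study.n_samples)
    table, frac = pca_embed(null_study, k=k)
    assert frac.sum() <= 1.0 + 1e-12
    coords = table[[f"PC{i+1}" for i in range(k)]].to_numpy()
    Xc = null_study.values - null_study.values.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # reconstruct through the fitted loadings: loadings @ coords.T == Xc
    recon = np.linalg.lstsq(coords, Xc.T, rcond=None)[0]
    np.testing.assert_allclose(coords @ recon, Xc.T, atol=1e-8)


def test_sample_permutation_leaves_variance_fractions(null_study):
    _, frac = pca_embed(null_study, k=3)
    rng = np.random.default_rng(0)
    perm = rng.permutation(null_study.n_samples)
    permuted = ExpressionStudy(
        list(null_study.genes),
        [null_study.samples[i] for i in perm],
        null_study.values[:, perm],
        dict(null_study.cohort),
        dict(null_study.condition),
    )
    _, frac_p = pca_embed(permuted, k=3)
    np.testing.assert_allclose(frac, frac_p, atol=1e-10)


def test_invalid_k_rejected(null_study):
    with pytest.raises(HarmonizeError):
        pca_embed(null_study, k=0)


def test_correction_improves_cohort_mixing():
    """Cohort silhouette on PC1-2 drops after correction (the before/after
    PCA diagnostic)."""
    from sklearn.metrics import silhouette_score

    cfg = SyntheticConfig(n_cohorts=3, samples_per_cohort=((15, 15),) * 3,
                         n_genes=600, n_informative=5, effect_size=2.0,
                         batch_shift_sd=1.0, batch_scale_sd=0.25, seed=13)
    study, _ = generate_cohorts(cfg)

    def silhouette(st):
        table, _ = pca_embed(st, k=2)
        return silhouette_score(table[["PC1", "PC2"]], table["cohort"])

    corrected, _ = combat_adjust(study)
    assert silhouette(study) > silhouette(corrected)
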