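"""Shapley machinery: closed forms, a brute-force permutation oracle,
the axioms (efficiency, symmetry, dummy), sampling convergence and the
interaction index."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from flavotarget.shapley import (
    ShapError,
    kernel_shap,
    kernel_shap_table,
    mean_abs_shap,
    shap_interactions,
    single_gene_auc,
)

from conftest import make_study


def _permutation_oracle(predict, background, instance):
    """Exact Shapley values by averaging marginal contributions over all
    M! feature orderings (fully independent of the WLS solver)."""
    background = np.atleast_2d(background)
    x = np.asarray(instance, float)
    M = len(x)

    def value(members):
        data = background.copy()
        for j in members:
            data[:, j] = x[j]
        return float(np.mean(predict(data)))

    phi = np.zeros(M)
    count = 0
    for order in permutations(range(M)):
        count += 1
        members = []
        prev = value(members)
        for j in order:
            members.append(j)
            cur = value(members)
            phi[j] += cur - prev
            prev = cur
    return phi / count


class TestKernelShap:
    def test_constant_model_gets_zero_attributions(self):
        predict = lambda X: np.full(len(np.atleast_2d(X)), 0.7)
        exp = kernel_shap(predict, np.zeros((4, 3)), np.ones(3))
        np.testing.assert_allclose(exp.phi, 0.0, atol=1e-10)
        assert exp.base_value == pytest.approx(0.7)

    def test_linear_model_closed_form(self):
        """For f(x) = beta.x with an independent-column background,
        phi_j = beta_j (x_j - mean background_j)."""
        rng = np.random.default_rng(5)
        beta = np.array([0.5, -1.2, 2.0, 0.3])
        background = rng.normal(size=(40, 4))
        predict = lambda X: np.atleast_2d(X) @ beta
        x = rng.normal(size=4)
        exp = kernel_shap(predict, background, x)
        expected = beta * (x - background.mean(axis=0))
        np.testing.assert_allclose(exp.phi, expected, atol=1e-6)

    def test_three_feature_toy_matches_permutation_oracle(self):
        rng = np.random.default_rng(8)
        background = rng.uniform(size=(6, 3))
        x = rng.uniform(size=3)

        def predict(X):
            X = np.atleast_2d(X)
            return X[:, 0] * X[:, 1] + np.sin(X[:, 2]) + 0.5 * X[:, 0]

        exp = kernel_shap(predict, background, x)
        oracle = _permutation_oracle(predict, background, x)
        np.testing.assert_allclose(exp.phi, oracle, atol=1e-10)

    def test_efficiency_axiom(self):
        rng = np.random.default_rng(9)
        background = rng.normal(size=(10, 5))
        x = rng.normal(size=5)
        predict = lambda X: np.tanh(np.atleast_2d(X).sum(axis=1))
        exp = kernel_shap(predict, background, x)
        assert exp.phi.sum() == pytest.approx(exp.fx - exp.base_value, abs=1e-6)

    def test_symmetry_axiom(self):
        """Exchangeable features receive equal attributions."""
        background = np.zeros((5, 3))
        x = np.array([1.0, 1.0, 0.5])
        predict = lambda X: np.atleast_2d(X)[:, 0] + np.atleast_2d(X)[:, 1]
        exp = kernel_shap(predict, background, x)
        assert exp.phi[0] == pytest.approx(exp.phi[1], abs=1e-10)

    def test_dummy_axiom(self):
        background = np.random.default_rng(10).normal(size=(8, 3))
        x = np.array([2.0, -1.0, 5.0])
        predict = lambda X: np.atleast_2d(X)[:, 0] * 2.0  # feature 2 unused
        exp = kernel_shap(predict, background, x)
        assert exp.phi[2] == pytest.approx(0.0, abs=1e-10)

    def test_sampling_converges_to_exact(self):
        """Paired sampling at 2^M - 2 coalition coverage agrees with the
        exact enumeration to 0.01 on an 8-feature toy."""
        rng = np.random.default_rng(11)
        M = 8
        beta = rng.normal(size=M)
        background = rng.normal(size=(15, M))
        predict = lambda X: 1 / (1 + np.exp(-(np.atleast_2d(X) @ beta)))
        x = rng.normal(size=M)
        exact = kernel_shap(predict, background, x, method="exact")
        sampled = kernel_shap(predict, background, x, method="sampling",
                              n_coalitions=2**M - 2, seed=3)
        assert np.max(np.abs(sampled.phi - exact.phi)) < 0.01

    def test_zero_features_rejected(self):
        with pytest.raises(ShapError):
            kernel_shap(lambda X: np.zeros(len(X)), np.zeros((2, 0)), np.array([]))

    def test_table_matches_per_instance_solver(self):
        rng = np.random.default_rng(13)
        background = rng.normal(size=(10, 4))
        X = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        predict = lambda Z: np.tanh(np.atleast_2d(Z) @ np.array([1.0, -0.5, 0.2, 0.8]))
        table, base = kernel_shap_table(predict, background, X)
        for i in range(len(X)):
            exp = kernel_shap(predict, background, X.iloc[i].to_numpy())
            np.testing.assert_allclose(table.iloc[i].to_numpy(), exp.phi, atol=1e-8)
            assert base == pytest.approx(exp.base_value)


class TestMeanAbsShap:
    def test_cancellation_resistant_ranking(self):
        phi = pd.DataFrame({"g1": [1.0, -1.0], "g2": [0.5, 0.5]})
        ranking = mean_abs_shap(phi)
        assert list(ranking.index) == ["g1", "g2"]
        assert ranking["g1"] == pytest.approx(1.0)
        assert ranking["g2"] == pytest.approx(0.5)

    def test_identical_rows_rank_by_single_row(self):
        phi = pd.DataFrame([[0.2, -0.9, 0.5]] * 4, columns=["a", "b", "c"])
        ranking = mean_abs_shap(phi)
        assert list(ranking.index) == ["b", "c", "a"]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(14)
        phi = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        shuffled = phi.sample(frac=1.0, random_state=1)
        pd.testing.assert_series_equal(mean_abs_shap(phi), mean_abs_shap(shuffled))


class TestInteractions:
    def test_additive_model_has_zero_interactions(self):
        rng = np.random.default_rng(15)
        background = rng.normal(size=(8, 3))
        x = rng.normal(size=3)
        predict = lambda X: (np.atleast_2d(X)[:, 0] ** 2
                             + np.sin(np.atleast_2d(X)[:, 1])
                             + 0.3 * np.atleast_2d(X)[:, 2])
        inter = shap_interactions(predict, background, x)
        off = inter - np.diag(np.diag(inter))
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_product_model_matches_second_difference_oracle(self):
        background = np.zeros((4, 2))
        x = np.array([1.0, 1.0])
        predict = lambda X: np.atleast_2d(X)[:, 0] * np.atleast_2d(X)[:, 1]
        inter = shap_interactions(predict, background, x)
        # only S = {} contributes: weight 1/2, second difference = 1
        assert inter[0, 1] == pytest.approx(0.5, abs=1e-10)
        assert inter[1, 0] == pytest.approx(0.5, abs=1e-10)

    def test_rows_sum_to_shapley_values(self):
        rng = np.random.default_rng(16)
        background = rng.normal(size=(6, 4))
        x = rng.normal(size=4)
        predict = lambda X: np.tanh(np.atleast_2d(X)[:, 0]
                                    * np.atleast_2d(X)[:, 1]
                                    + np.atleast_2d(X)[:, 2])
        inter = shap_interactions(predict, background, x)
        exp = kernel_shap(predict, background, x)
        np.testing.assert_allclose(inter.sum(axis=1), exp.phi, atol=1e-8)
        np.testing.assert_allclose(inter, inter.T, atol=1e-12)

    def test_single_feature_equals_phi(self):
        background = np.zeros((3, 1))
        x = np.array([2.0])
        predict = lambda X: 3.0 * np.atleast_2d(X)[:, 0]
        inter = shap_interactions(predict, background, x)
        exp = kernel_shap(predict, background, x)
        assert inter[0, 0] == pytest.approx(exp.phi[0], abs=1e-10)

    def test_oversized_panel_rejected(self):
        with pytest.raises(ShapError):
            shap_interactions(lambda X: np.zeros(len(np.atleast_2d(X))),
                              np.zeros((2, 11)), np.zeros(11))


class TestSingleGeneAuc:
    def test_label_gene_is_perfect(self):
        values = np.zeros((2, 10))
        values[0, :5] = 1.0  # equals the disease indicator
        values[1] = np.random.default_rng(0).normal(size=10)
        study = make_study(values, 5, 5)
        aucs = single_gene_auc(study, [study.genes[0]])
        assert aucs.iloc[0] == pytest.approx(1.0)

    def test_independent_gene_scores_at_chance(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            study = make_study(rng.normal(size=(1, 40)), 20, 20)
            vals.append(single_gene_auc(study, [study.genes[0]]).iloc[0])
        assert 0.45 < np.mean(vals) < 0.55

    def test_negation_symmetry(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=(1, 20))
        study = make_study(values, 10, 10)
        neg = make_study(-values, 10, 10)
        a = single_gene_auc(study, [study.genes[0]]).iloc[0]
        b = single_gene_auc(neg, [neg.genes[0]]).iloc[0]
        assert b == pytest.approx(1.0 - a, abs=1e-12)

    def test_absent_gene_listed_in_error(self):
        study = make_study(np.zeros((2, 8)) + np.arange(8), 4, 4)
        with pytest.raises(ShapError, match="NOPE"):
            single_gene_auc(study, ["NOPE"])
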