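"""Population graphs, spectral filtering, attention fusion, and the masked
completion model's training contracts."""

import numpy as np
import pytest

from vestibench import gmc
from vestibench.gmc import (
    CompletionProblem,
    GmcConfig,
    GmcModel,
    PopulationGraph,
    build_similarity_graph,
    chebyshev_basis,
    fit_gmc,
    gmc_loss,
    predict_gmc,
    self_attention_fuse,
    spectral_convolve,
    sum_graphs,
)
from conftest import build_cohort


def age_cohort(schema, ages, y=None, **kw):
    n = len(ages)
    y = y if y is not None else np.arange(n) % 2
    return build_cohort(schema, n, {"age": ages}, y, **kw)


class TestGraphBuilders:
    def test_age_threshold_is_five_years_inclusive(self, schema):
        g = build_similarity_graph(age_cohort(schema, [60.0, 63.0, 66.0]), "age")
        assert g.weights[0, 1] == 1.0   # |60-63| <= 5
        assert g.weights[0, 2] == 0.0   # |60-66| > 5
        assert g.weights[1, 2] == 1.0

    def test_abcd2_threshold_is_one_point(self, schema):
        # scores: 3 (age+duration), 4 (+diabetes), 2 (duration only), via components
        over = {
            "age": [65.0, 65.0, 40.0],
            "symptom_duration_minutes": [70.0, 70.0, 70.0],
            "diabetes": [0.0, 1.0, 0.0],
            "sbp": [120.0, 120.0, 120.0], "dbp": [80.0, 80.0, 80.0],
        }
        c = build_cohort(schema, 3, over, [1, 1, 0])
        g = build_similarity_graph(c, "abcd2")
        assert g.weights[0, 1] == 1.0   # |3-4| = 1 connects
        assert g.weights[0, 2] == 1.0   # |3-2| = 1 connects
        assert g.weights[1, 2] == 0.0   # |4-2| = 2 does not

    def test_missing_meta_feature_leaves_patient_unconnected(self, schema):
        c = age_cohort(schema, [60.0, 61.0, 62.0], missing={"age": [False, True, False]})
        g = build_similarity_graph(c, "age")
        assert g.weights[1].sum() == 0 and g.weights[:, 1].sum() == 0
        assert g.weights[0, 2] == 1.0

    def test_unknown_criterion_rejected(self, schema):
        with pytest.raises(ValueError):
            build_similarity_graph(age_cohort(schema, [60.0, 61.0]), "sex")

    def test_exhaustive_pairwise_oracle_on_random_cohort(self, schema):
        rng = np.random.default_rng(5)
        ages = rng.uniform(20, 90, 80)
        g = build_similarity_graph(age_cohort(schema, ages), "age")
        for i in range(80):
            assert g.weights[i, i] == 0
            for j in range(i + 1, 80):
                expected = 1.0 if abs(ages[i] - ages[j]) <= 5.0 else 0.0
                assert g.weights[i, j] == expected == g.weights[j, i]

    def test_sum_graph_weights_in_0_1_2(self, schema):
        c = build_cohort(schema, 4, {"age": [60.0, 62.0, 80.0, 61.0]}, [0, 1, 0, 1])
        g_age = build_similarity_graph(c, "age")
        g_ab = build_similarity_graph(c, "abcd2")
        s = sum_graphs(g_age, g_ab)
        assert set(np.unique(s.weights)) <= {0.0, 1.0, 2.0}
        # zero graph is the identity element
        zero = PopulationGraph(g_age.patient_ids, np.zeros_like(g_age.weights))
        np.testing.assert_array_equal(sum_graphs(g_age, zero).weights, g_age.weights)

    def test_sum_graph_ordering_mismatch_rejected(self, schema):
        g1 = build_similarity_graph(age_cohort(schema, [60.0, 61.0]), "age")
        g2 = PopulationGraph(("X", "Y"), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            sum_graphs(g1, g2)

    def test_asymmetric_or_self_loop_adjacency_rejected(self):
        with pytest.raises(ValueError):
            PopulationGraph(("a", "b"), np.array([[0.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError):
            PopulationGraph(("a", "b"), np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestSpectralConvolution:
    def test_order_zero_is_a_graph_independent_linear_map(self, schema):
        x = np.random.default_rng(0).normal(size=(3, 2))
        theta = np.array([[1.0, -2.0], [0.5, 0.0]])
        g_line = build_similarity_graph(age_cohort(schema, [60.0, 63.0, 66.0]), "age")
        g_none = build_similarity_graph(age_cohort(schema, [20.0, 50.0, 80.0]), "age")
        out1 = spectral_convolve(g_line, x, [theta])
        out2 = spectral_convolve(g_none, x, [theta])
        np.testing.assert_allclose(out1, x @ theta)
        np.testing.assert_allclose(out1, out2)

    def test_edgeless_graph_collapses_to_a_linear_map(self, schema):
        g = build_similarity_graph(age_cohort(schema, [20.0, 50.0, 80.0]), "age")
        assert g.weights.sum() == 0
        x = np.random.default_rng(1).normal(size=(3, 2))
        thetas = [np.eye(2) * c for c in (0.7, -0.3, 0.2)]
        out = spectral_convolve(g, x, thetas)
        # T_0 = I, T_1 = L~ = 0, T_2 = -I on an edgeless graph
        np.testing.assert_allclose(out, x @ (thetas[0] - thetas[2]), atol=1e-12)

    def test_two_node_graph_matches_hand_computed_polynomial(self):
        g = PopulationGraph(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        # normalized Laplacian = I - A, scaled L~ = -A; T_0 = I, T_1 = -A,
        # T_2 = 2A^2 - I = I
        x = np.array([[1.0], [2.0]])
        c0, c1, c2 = 0.5, -1.0, 0.25
        out = spectral_convolve(g, x, [[[c0]], [[c1]], [[c2]]])
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        expected = c0 * x + c1 * (-a @ x) + c2 * x
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_chebyshev_recurrence_against_direct_polynomials(self, schema):
        g = build_similarity_graph(
            age_cohort(schema, [60.0, 62.0, 64.0, 90.0]), "age")
        lt = g.scaled_laplacian()
        x = np.random.default_rng(2).normal(size=(4, 3))
        t = chebyshev_basis(g, x, 3)
        np.testing.assert_allclose(t[2], 2 * lt @ (lt @ x) - x, atol=1e-10)
        np.testing.assert_allclose(
            t[3], 4 * lt @ lt @ lt @ x - 3 * lt @ x, atol=1e-10)


class TestSelfAttention:
    def test_single_graph_fuses_to_itself_with_weight_one(self):
        h = np.random.default_rng(0).normal(size=(5, 4))
        fused, alpha = self_attention_fuse([h])
        np.testing.assert_array_equal(fused, h)
        np.testing.assert_array_equal(alpha, np.ones((5, 1)))

    def test_identical_embeddings_fuse_to_the_input(self):
        h = np.random.default_rng(1).normal(size=(6, 3))
        fused, alpha = self_attention_fuse([h, h], attn_vector=np.ones(3))
        np.testing.assert_allclose(fused, h)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0)

    def test_hand_set_scores_give_expected_softmax_weights(self):
        h = np.zeros((4, 2))
        _, alpha = self_attention_fuse([h, h], attn_vector=np.zeros(2),
                                       attn_bias=np.array([np.log(3), np.log(1)]))
        np.testing.assert_allclose(alpha, np.tile([0.75, 0.25], (4, 1)))

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            self_attention_fuse([np.zeros((3, 2)), np.zeros((3, 4))])


@pytest.fixture
def component_problem(schema):
    """Two pure graph components (by age), one hidden label per component."""
    ids_test = ["P004", "P009"]
    c = age_cohort(schema, [30, 31, 32, 33, 34, 70, 71, 72, 73, 74],
                   y=[0] * 5 + [1] * 5)
    g = build_similarity_graph(c, "age")
    assert g.weights[:5, 5:].sum() == 0
    train = [p for p in c.patient_ids if p not in ids_test]
    return CompletionProblem(c, [g], train, test_ids=ids_test), ids_test


class TestCompletionModel:
    def test_masked_entries_have_exactly_zero_loss_gradient(self, schema):
        rng = np.random.default_rng(3)
        c = build_cohort(
            schema, 8,
            {"age": rng.uniform(40, 80, 8), "vhit_gain_right": rng.random(8)},
            np.arange(8) % 2,
            missing={"vhit_gain_right": [True, False] * 4,
                     "sbp": [True] * 8})
        g = build_similarity_graph(c, "age")
        prob = CompletionProblem(c, [g], c.patient_ids[:6], test_ids=c.patient_ids[6:])
        cfg = GmcConfig(seed=0)
        model = fit_gmc(prob, cfg)
        base = gmc_loss(model.params, prob, cfg)
        masked = np.argwhere(~prob.mask)
        for r, col in masked[:: max(1, len(masked) // 25)]:
            prob.X[r, col] = (0.0 if np.isnan(prob.X[r, col]) else prob.X[r, col]) + 123.0
            assert gmc_loss(model.params, prob, cfg) == base  # bitwise equal
            prob.X[r, col] -= 123.0

    def test_disconnected_components_recover_their_majority_label(self, component_problem):
        prob, ids_test = component_problem
        model = fit_gmc(prob, GmcConfig(seed=0, epochs=400, patience=0))
        post, dec = predict_gmc(model, prob, ids_test)
        assert list(dec) == [0, 1]

    def test_mu_zero_overfits_a_separable_toy(self, schema):
        y = np.arange(10) % 2
        c = build_cohort(schema, 10,
                         {"age": 50.0 + np.arange(10),
                          "vhit_gain_right": np.where(y == 1, 1.2, 0.4)}, y)
        g = build_similarity_graph(c, "age")
        prob = CompletionProblem(c, [g], c.patient_ids)
        model = fit_gmc(prob, GmcConfig(seed=0, mu=0.0, epochs=400, patience=0))
        _, dec = predict_gmc(model, prob)
        assert (dec == y).all()

    def test_fully_masked_feature_column_is_ignored(self, schema):
        c = build_cohort(schema, 6, {"age": [40, 41, 42, 70, 71, 72.0]},
                         [0, 0, 0, 1, 1, 1], missing={"sbp": [True] * 6})
        g = build_similarity_graph(c, "age")
        prob = CompletionProblem(c, [g], c.patient_ids)
        model = fit_gmc(prob, GmcConfig(seed=0, epochs=50, patience=0))
        assert np.isfinite(model.loss_history).all()

    def test_no_observed_labels_rejected(self, schema):
        c = build_cohort(schema, 4, {"age": [40, 41, 42, 43.0]}, [0, 1, 0, 1])
        g = build_similarity_graph(c, "age")
        with pytest.raises(ValueError):
            CompletionProblem(c, [g], [])

    def test_training_loss_non_increasing_under_plain_gradient_descent(
            self, component_problem):
        prob, _ = component_problem
        model = fit_gmc(prob, GmcConfig(seed=0, epochs=150, patience=0,
                                        optimizer="gd", learning_rate=1e-3))
        assert (np.diff(model.loss_history) <= 1e-10).all()

    def test_hidden_test_label_flip_changes_nothing_at_training_time(self, schema):
        """Transductive no-leak: a hidden label never influences the fit."""
        ages = np.linspace(40, 75, 12)
        y = np.arange(12) % 2
        trains, tests = [f"P{i:03d}" for i in range(10)], ["P010", "P011"]

        def fit_with(y_variant):
            c = build_cohort(schema, 12, {"age": ages}, y_variant)
            g = build_similarity_graph(c, "age")
            prob = CompletionProblem(c, [g], trains, test_ids=tests)
            return fit_gmc(prob, GmcConfig(seed=4, epochs=60, patience=0))

        y_flip = y.copy()
        y_flip[-1] = 1 - y_flip[-1]
        m1, m2 = fit_with(y), fit_with(y_flip)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_permuting_patients_permutes_posteriors(self, schema):
        rng = np.random.default_rng(8)
        ages = rng.uniform(40, 80, 10)
        y = np.arange(10) % 2
        c = build_cohort(schema, 10, {"age": ages}, y)
        perm = rng.permutation(10)
        ids = c.patient_ids
        train_ids, test_ids = ids[:8], ids[8:]

        def posteriors(cohort):
            g = build_similarity_graph(cohort, "age")
            prob = CompletionProblem(cohort, [g], train_ids, test_ids=test_ids)
            model = fit_gmc(prob, GmcConfig(seed=1, epochs=80, patience=0))
            p, _ = predict_gmc(model, prob)
            return dict(zip(cohort.patient_ids, p))

        p_orig = posteriors(c)
        p_perm = posteriors(c.subset([ids[i] for i in perm]))
        for pid in ids:
            assert p_perm[pid] == pytest.approx(p_orig[pid], abs=1e-6)

    def test_absent_patient_rejected_at_prediction(self, component_problem):
        prob, _ = component_problem
        model = fit_gmc(prob, GmcConfig(seed=0, epochs=20, patience=0))
        with pytest.raises(ValueError, match="absent"):
            predict_gmc(model, prob, ["GHOST"])

    def test_model_json_round_trip(self, component_problem):
        prob, ids_test = component_problem
        model = fit_gmc(prob, GmcConfig(seed=0, epochs=60, patience=0))
        back = GmcModel.from_json(model.to_json())
        p1, _ = predict_gmc(model, prob, ids_test)
        p2, _ = predict_gmc(back, prob, ids_test)
        np.testing.assert_allclose(p1, p2)


class TestMultiGraph:
    def test_attention_prefers_the_informative_graph(self, schema):
        rng = np.random.default_rng(0)
        n = 60
        y = np.array([0, 1] * (n // 2))
        over = {
            "age": np.where(y == 1, 70.0, 40.0) + rng.normal(0, 1.5, n),
            "symptom_duration_minutes": rng.choice([5.0, 30.0, 120.0], n),
            "diabetes": rng.integers(0, 2, n).astype(float),
            "unilateral_weakness": rng.integers(0, 2, n).astype(float),
            "sbp": rng.choice([120.0, 150.0], n), "dbp": np.full(n, 80.0),
        }
        c = build_cohort(schema, n, over, y)
        g_age = build_similarity_graph(c, "age")
        g_ab = build_similarity_graph(c, "abcd2")
        ids = c.patient_ids
        weights = []
        for seed in range(3):
            prob = CompletionProblem(c, [g_age, g_ab], ids[:40], ids[40:50], ids[50:])
            model = fit_gmc(prob, GmcConfig(seed=seed, epochs=800, patience=0))
            weights.append(model.attention[:, 0].mean())
        assert np.mean(weights) > 0.5

    def test_multigmc_not_inferior_to_singlegmc_on_synthetic_cohorts(self):
        """Scaled-down non-inferiority check (3 seeds, 5 folds)."""
        import vestibench as vb
        from vestibench.evaluate import run_benchmark

        diffs = []
        for seed in range(3):
            cohort = vb.generate_cohort(vb.GeneratorConfig(seed=200 + seed))
            rep = run_benchmark(cohort, methods=["SingleGMC", "MultiGMC"],
                                k=5, seed=seed)
            diffs.append(np.nanmean(rep.fold_metric("MultiGMC", "auc"))
                         - np.nanmean(rep.fold_metric("SingleGMC", "auc")))
        assert np.mean(diffs) >= -0.05
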