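"""Stratified folds, Wilcoxon comparison, MDI ranking, univariate tests,
and the benchmark orchestration."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

import vestibench as vb
from vestibench import baselines
from vestibench.evaluate import (
    compare_models,
    make_folds,
    mdi_ranking,
    run_benchmark,
    univariate_table,
    wilcoxon_signed_rank,
)
from conftest import build_cohort


class TestFolds:
    def test_stratified_partition_arithmetic_on_study_cohort(self, default_cohort):
        folds = make_folds(default_cohort, k=10, seed=0)
        y = dict(zip(default_cohort.patient_ids, default_cohort.y()))
        all_test = [p for f in folds for p in f.test_ids]
        assert sorted(all_test) == sorted(default_cohort.patient_ids)
        for f in folds:
            assert 10 <= len(f.test_ids) <= 11
            n_stroke = sum(y[p] for p in f.test_ids)
            assert 3 <= n_stroke <= 5  # 40/108 of 10-11, within one patient
            parts = set(f.train_ids) | set(f.val_ids) | set(f.test_ids)
            assert parts == set(default_cohort.patient_ids)
            # every part carries both classes
            for ids in (f.train_ids, f.val_ids, f.test_ids):
                classes = {y[p] for p in ids}
                assert classes == {0, 1}

    def test_validation_is_about_ten_percent_of_training(self, default_cohort):
        folds = make_folds(default_cohort, k=10, seed=3)
        for f in folds:
            pool = len(f.train_ids) + len(f.val_ids)
            assert abs(len(f.val_ids) - 0.1 * pool) <= 1

    def test_same_seed_reproduces_identical_splits(self, default_cohort):
        a = make_folds(default_cohort, k=10, seed=5)
        b = make_folds(default_cohort, k=10, seed=5)
        assert [f.test_ids for f in a] == [f.test_ids for f in b]
        assert [f.val_ids for f in a] == [f.val_ids for f in b]

    def test_leave_one_out_with_relaxed_stratification(self, schema):
        c = build_cohort(schema, 8, {}, [0, 1] * 4)
        folds = make_folds(c, k=8, seed=0, stratified=False)
        assert all(len(f.test_ids) == 1 for f in folds)

    def test_class_smaller_than_k_rejected(self, schema):
        c = build_cohort(schema, 12, {}, [1] * 3 + [0] * 9)
        with pytest.raises(ValueError):
            make_folds(c, k=5, seed=0)


class TestWilcoxon:
    def test_identical_lists_give_p_one_with_warning(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank([0.7] * 10, [0.7] * 10)
        assert p == 1.0

    def test_all_ones_vs_all_zeros_exact_p(self):
        _, p = wilcoxon_signed_rank([1.0] * 10, [0.0] * 10)
        assert p == pytest.approx(2 / 2 ** 10)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(10), rng.random(10)
        assert wilcoxon_signed_rank(a, b)[1] == pytest.approx(
            wilcoxon_signed_rank(b, a)[1])

    def test_exact_p_matches_brute_force_sign_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(8):
            n = int(rng.integers(4, 11))
            d = np.round(rng.normal(0, 1, n), 2)
            d[d == 0] = 0.11
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            dist = [sum(r for r, s in zip(ranks, signs) if s)
                    for signs in itertools.product([0, 1], repeat=n)]
            dist = np.array(dist)
            cdf = (dist <= w_obs + 1e-9).mean()
            sf = (dist >= w_obs - 1e-9).mean()
            expected = min(1.0, 2 * min(cdf, sf))
            _, p = wilcoxon_signed_rank(d, np.zeros(n))
            assert p == pytest.approx(expected, abs=1e-12)

    def test_large_sample_path_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0.3, 1, 40), rng.normal(0, 1, 40)
        _, p = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, zero_method="wilcox", correction=False,
                             alternative="two-sided", method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_nan_metrics_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([np.nan, 1.0], [0.0, 0.0])


class TestMdi:
    def test_single_split_stumps_put_all_importance_on_one_feature(self, schema):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 50)
        c = build_cohort(schema, 100, {"vhit_pathological": 1.0 - y}, y)
        est = RandomForestClassifier(n_estimators=5, max_depth=1, random_state=0)
        est.fit(c.values.fillna(0.0).to_numpy(), y)
        ranking = mdi_ranking(est, schema)
        assert ranking.iloc[0]["feature"] == "vhit_pathological"
        assert ranking.iloc[0]["importance"] == pytest.approx(1.0)
        assert ranking["importance"].sum() == pytest.approx(1.0)

    def test_duplicated_feature_splits_importance(self, schema):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 400)
        signal = y + rng.normal(0, 0.3, 400)
        noise = rng.normal(size=(400, 3))
        c1 = build_cohort(schema, 400, {
            "vhit_gain_right": signal,
            "vog_q001": noise[:, 0], "vog_q002": noise[:, 1]}, y)
        c2 = build_cohort(schema, 400, {
            "vhit_gain_right": signal, "vhit_gain_left": signal,
            "vog_q001": noise[:, 0], "vog_q002": noise[:, 2]}, y)
        imp = {}
        for tag, c in (("orig", c1), ("dup", c2)):
            model = baselines.fit(baselines.ModelSpec("rf", {"n_trees": 50}), c)
            r = mdi_ranking(model, schema).set_index("feature")["importance"]
            imp[tag] = r
        single = imp["orig"]["vhit_gain_right"]
        pair = imp["dup"]["vhit_gain_right"] + imp["dup"]["vhit_gain_left"]
        assert pair == pytest.approx(single, abs=0.15)
        assert imp["dup"]["vhit_gain_right"] < single

    def test_unfitted_forest_rejected(self, schema):
        with pytest.raises(ValueError):
            mdi_ranking(RandomForestClassifier(), schema)


class TestUnivariate:
    def test_perfect_association_chi2_forty(self, schema):
        y = np.array([0] * 20 + [1] * 20)
        c = build_cohort(schema, 40, {"diabetes": y.astype(float)}, y)
        t = univariate_table(c, ["diabetes"])
        assert t.loc["diabetes", "statistic"] == pytest.approx(40.0)
        assert t.loc["diabetes", "p_value"] < 1e-4

    def test_no_association_chi2_zero(self, schema):
        y = np.array([0] * 20 + [1] * 20)
        d = np.array(([0] * 10 + [1] * 10) * 2, float)
        c = build_cohort(schema, 40, {"diabetes": d}, y)
        t = univariate_table(c, ["diabetes"])
        assert t.loc["diabetes", "statistic"] == pytest.approx(0.0)
        assert t.loc["diabetes", "p_value"] == pytest.approx(1.0)

    def test_identical_class_distributions_give_p_one(self, schema):
        vals = np.concatenate([np.arange(20.0), np.arange(20.0)])
        y = np.array([0] * 20 + [1] * 20)
        c = build_cohort(schema, 40, {"age": vals}, y)
        t = univariate_table(c, ["age"])
        assert t.loc["age", "test"] == "mannwhitney"
        assert t.loc["age", "p_value"] == pytest.approx(1.0)

    def test_zero_variance_feature_noted(self, schema):
        c = build_cohort(schema, 10, {}, [0, 1] * 5)
        t = univariate_table(c, ["age"])
        assert t.loc["age", "p_value"] == 1.0
        assert "variance" in t.loc["age", "note"]


class TestBenchmark:
    def test_hints_perfect_cohort_scores_perfectly(self, schema):
        # neuritis: abnormal HIT (peripheral), no other central signs;
        # stroke: normal HIT -> one central point each
        y = np.array([0] * 6 + [1] * 6)
        c = build_cohort(schema, 12, {"vhit_pathological": 1.0 - y}, y)
        rep = run_benchmark(c, methods=["HINTS"], k=2, seed=0)
        assert rep.index_tests["HINTS"]["accuracy"] == 1.0
        assert rep.index_tests["HINTS"]["evaluated_on"] == "full_cohort"

    def test_unknown_method_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="unknown method"):
            run_benchmark(default_cohort, methods=["SVM"])

    def test_per_fold_table_complete_and_comparable(self, default_cohort):
        rep = run_benchmark(default_cohort, methods=["LR", "RF"], k=5, seed=1,
                            grids={"LR": [baselines.ModelSpec("lr", {"C": 1.0})],
                                   "RF": [baselines.ModelSpec("rf", {"n_trees": 15})]})
        assert len(rep.per_fold) == 10
        assert not rep.per_fold[["accuracy", "f1", "auc"]].isna().any().any()
        p = compare_models(rep, "LR", "RF")
        assert 0.0 <= p <= 1.0
        assert compare_models(rep, "RF", "RF") == 1.0

    def test_baseline_predictions_never_read_test_labels(self, default_cohort):
        folds = make_folds(default_cohort, k=5, seed=2)
        f = folds[0]
        train = default_cohort.subset(list(f.train_ids))
        test = default_cohort.subset(list(f.test_ids))
        model = baselines.fit(baselines.ModelSpec("rf", {"n_trees": 10}, seed=0), train)
        p1, _ = baselines.predict_posterior(model, test)
        import pandas as pd

        permuted = pd.Series(test.labels.sample(frac=1, random_state=0).to_numpy(),
                             index=test.values.index)
        shuffled = vb.Cohort(test.values, test.schema, permuted)
        p2, _ = baselines.predict_posterior(model, shuffled)
        np.testing.assert_array_equal(p1, p2)
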