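"""Folds, balancing, TPE, metrics, nested CV and reporting."""

import numpy as np
import pandas as pd
import pytest

import bicpred as bp
from bicpred.model_eval import fit_outer_fold, make_classifier
from bicpred.synthetic import null_cohort

from conftest import make_cohort, planted_cohort


class TestStratifiedFolds:
    def test_study_scale_positive_spread(self):
        y = np.array([1] * 21 + [0] * 82)
        folds = bp.stratified_folds(y, 10, seed=0)
        for f in range(10):
            pos = int(y[folds == f].sum())
            assert pos in (2, 3)  # 21 positives into 10 folds

    def test_deterministic(self):
        y = np.array([1] * 10 + [0] * 30)
        np.testing.assert_array_equal(
            bp.stratified_folds(y, 5, seed=3), bp.stratified_folds(y, 5, seed=3)
        )

    def test_partition(self):
        y = np.array([1] * 10 + [0] * 30)
        folds = bp.stratified_folds(y, 5, seed=1)
        assert sorted(np.unique(folds)) == list(range(5))
        assert len(folds) == 40

    @pytest.mark.parametrize("k", [1, 15])
    def test_bad_fold_counts(self, k):
        y = np.array([1] * 10 + [0] * 30)
        with pytest.raises(ValueError):
            bp.stratified_folds(y, k)


class TestSmoteSvm:
    def test_balances_to_majority_count(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((103, 6))
        y = np.array([1] * 21 + [0] * 82)
        Xb, yb = bp.smote_svm_balance(X, y, seed=1)
        assert np.bincount(yb).tolist() == [82, 82]
        np.testing.assert_array_equal(Xb[:103], X)  # originals verbatim

    def test_already_balanced_is_noop(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        y = np.array([0, 1] * 10)
        Xb, yb = bp.smote_svm_balance(X, y, seed=0)
        assert Xb.shape == X.shape

    def test_synthetic_samples_are_segments_between_minority_pairs(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 4))
        y = np.array([1] * 8 + [0] * 32)
        Xb, yb = bp.smote_svm_balance(X, y, seed=3)
        minority = X[:8]
        for s in Xb[40:]:
            on_segment = False
            for a in range(8):
                for b in range(8):
                    if a == b:
                        continue
                    d = minority[b] - minority[a]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    t = float((s - minority[a]) @ d) / denom
                    if -1e-9 <= t <= 1 + 1e-9 and np.allclose(
                        s, minority[a] + t * d, atol=1e-9
                    ):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_tiny_minority_error(self):
        X = np.zeros((5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            bp.smote_svm_balance(X, y)


class TestTpe:
    SPACE = {"x": ("uniform", 0.0, 1.0)}

    def test_budget_one_returns_single_sample(self):
        best, trials = bp.tpe_optimize(lambda p: p["x"], self.SPACE, budget=1, seed=0)
        assert len(trials) == 1 and best == trials[0][0]

    def test_monotone_objective_drifts_to_favorable_end(self):
        finals = []
        for seed in range(5):
            best, _ = bp.tpe_optimize(lambda p: p["x"], self.SPACE, budget=30, seed=seed)
            finals.append(best["x"])
        assert np.mean(finals) > 0.8

    def test_deterministic_trial_sequence(self):
        a = bp.tpe_optimize(lambda p: p["x"], self.SPACE, budget=15, seed=7)
        b = bp.tpe_optimize(lambda p: p["x"], self.SPACE, budget=15, seed=7)
        assert a == b

    def test_int_and_choice_dimensions(self):
        space = {"k": ("int", 1, 9), "kind": ("choice", ("a", "b"))}
        obj = lambda p: p["k"] + (5 if p["kind"] == "b" else 0)
        best, _ = bp.tpe_optimize(obj, space, budget=40, seed=0)
        assert best["k"] >= 7 and best["kind"] == "b"

    def test_all_failures_raise(self):
        with pytest.raises(RuntimeError, match="failed"):
            bp.tpe_optimize(lambda p: -np.inf, self.SPACE, budget=3, seed=0)

    def test_search_over_separable_data(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 1, (30, 2)), rng.normal(2, 1, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        best = bp.tpe_search(X, y, "decision_tree", budget=5, seed=0, inner_folds=3)
        assert set(best) == {"max_depth", "min_samples_leaf"}


class TestClassificationMetrics:
    def test_perfect_ranking(self):
        r = bp.classification_metrics(
            np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1])
        )
        assert (r.auc, r.precision, r.recall) == (1.0, 1.0, 1.0)

    def test_three_of_four_concordant(self):
        r = bp.classification_metrics(
            np.array([1, 0, 1, 0]), np.array([0.2, 0.8, 0.9, 0.1])
        )
        assert r.auc == pytest.approx(0.75)

    def test_degenerate_all_negative_predictions(self):
        y = np.array([1] * 21 + [0] * 82)
        r = bp.classification_metrics(y, np.zeros(103))
        assert r.recall == 0.0 and r.specificity == 1.0
        assert "precision" in r.undefined

    def test_single_class_auc_flagged(self):
        r = bp.classification_metrics(np.ones(4), np.array([0.1, 0.2, 0.3, 0.4]))
        assert np.isnan(r.auc) and "auc" in r.undefined

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_brute_force_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        y = (rng.random(n) < 0.4).astype(int)
        if y.sum() in (0, n):
            y[0], y[1] = 0, 1
        s = np.round(rng.random(n), 1)  # coarse scores force ties
        pairs = conc = 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                pairs += 1
                conc += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
        r = bp.classification_metrics(y, s)
        assert r.auc == pytest.approx(conc / pairs)

    def test_confusion_identity(self):
        y = np.array([1, 0, 1, 0, 0])
        s = np.array([0.9, 0.6, 0.1, 0.2, 0.7])
        r = bp.classification_metrics(y, s)
        assert r.confusion == {"tp": 1, "fp": 2, "tn": 1, "fn": 1}


class TestPrCurve:
    def test_perfect_scores_reach_top_right(self):
        pts = bp.pr_curve(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1]))
        assert (1.0, 1.0) in pts

    def test_recall_monotone(self):
        rng = np.random.default_rng(0)
        y = (rng.random(60) < 0.3).astype(int)
        pts = bp.pr_curve(y, rng.random(60))
        recalls = [r for r, _ in pts]
        assert recalls == sorted(recalls)

    def test_random_scores_precision_near_prevalence(self):
        rng = np.random.default_rng(1)
        precisions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.array([1] * 30 + [0] * 70)
            pts = bp.pr_curve(y, rng.random(100))
            mid = [p for r, p in pts if 0.3 < r < 0.9]
            precisions.append(np.mean(mid))
        assert np.mean(precisions) == pytest.approx(0.3, abs=0.08)

    def test_requires_a_positive(self):
        with pytest.raises(ValueError):
            bp.pr_curve(np.zeros(5), np.random.default_rng(0).random(5))


class TestRandomBaseline:
    def test_precision_converges_to_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        r = bp.random_baseline(y, n_iter=400, seed=0)
        se = np.sqrt(0.3 * 0.7 / (400 * 50))  # ~50 positive predictions/iter
        assert abs(r.precision - 0.3) < 3 * max(se, 0.01)

    def test_balanced_outcome(self):
        y = np.array([1, 0] * 40)
        r = bp.random_baseline(y, n_iter=100, seed=1)
        assert r.precision == pytest.approx(0.5, abs=0.05)
        assert r.auc == pytest.approx(0.5, abs=0.05)


class TestNestedCV:
    CFG = dict(model_family="naive_bayes", inner_folds=3, search_budget=3)

    def test_default_outer_folds_is_ten(self):
        assert bp.PipelineConfig().outer_folds == 10

    def test_each_sample_predicted_exactly_once(self):
        c = null_cohort(40, 10, prevalence=0.3, seed=0)
        res = bp.nested_cv(c, bp.PipelineConfig(outer_folds=4, seed=0, **self.CFG))
        ids = [s for fr in res.folds for s in fr.test_ids]
        assert sorted(ids) == sorted(c.sample_ids)

    def test_setting_mismatch_rejected(self):
        c = null_cohort(40, 10, prevalence=0.3, seed=0)
        with pytest.raises(ValueError):
            bp.nested_cv(c, bp.PipelineConfig(setting="I", outer_folds=4, **self.CFG))

    def test_leakage_guard_fitted_objects_ignore_test_data(self):
        c = null_cohort(50, 15, prevalence=0.3, seed=5)
        cfg = bp.PipelineConfig(
            outer_folds=5,
            seed=5,
            selection=bp.SelectionParams(alpha=0.3, use_mi=False),
            **self.CFG,
        )
        train_idx = np.arange(35)
        f1 = fit_outer_fold(c, train_idx, cfg)
        trashed = c.subset_samples(np.arange(50))
        trashed.expr[35:] = np.random.default_rng(0).normal(50, 10, (15, 15))
        f2 = fit_outer_fold(trashed, train_idx, cfg)
        assert f1.pipeline.fingerprint() == f2.pipeline.fingerprint()
        assert f1.best_params == f2.best_params

    def test_pattern_space_leakage_guard(self):
        c, _ = planted_cohort(seed=6, n_samples=50, n_genes=15, noise_sd=0.05)
        cfg = bp.PipelineConfig(
            space="pattern",
            mining=bp.MiningParams(n_iterations=1, n_labels=4, min_genes=2),
            outer_folds=5,
            seed=6,
            **self.CFG,
        )
        train_idx = np.arange(35)
        f1 = fit_outer_fold(c, train_idx, cfg)
        trashed = c.subset_samples(np.arange(50))
        trashed.expr[35:] = 999.0
        f2 = fit_outer_fold(trashed, train_idx, cfg)
        assert f1.pipeline.fingerprint() == f2.pipeline.fingerprint()

    def test_planted_signal_detected(self):
        c, _ = planted_cohort(seed=7, n_samples=60, n_genes=20, noise_sd=0.05)
        res = bp.nested_cv(c, bp.PipelineConfig(outer_folds=5, seed=7, **self.CFG))
        assert res.aggregate["auc"][0] > 0.8

    def test_smote_inside_cv_runs(self):
        c, _ = planted_cohort(seed=8, n_samples=60, n_genes=15)
        cfg = bp.PipelineConfig(
            outer_folds=4, seed=8, balancing="smote-svm", **self.CFG
        )
        res = bp.nested_cv(c, cfg)
        assert np.isfinite(res.aggregate["f1"][0])


class TestBootstrapSetting1:
    def test_flagged_optimistic_and_reproducible(self):
        c = null_cohort(40, 12, prevalence=0.3, seed=1)
        cfg = bp.PipelineConfig(
            setting="I",
            model_family="naive_bayes",
            inner_folds=3,
            search_budget=2,
            bootstrap_resamples=10,
            seed=1,
        )
        r1 = bp.bootstrap_eval_setting1(c, cfg)
        r2 = bp.bootstrap_eval_setting1(c, cfg)
        assert r1.optimistic is True
        assert len(r1.reports) + r1.n_skipped == 10
        assert r1.aggregate == r2.aggregate

    def test_oob_is_nonempty_in_practice(self):
        # P(empty OOB) is (1 - 1/n)^n ~ e^-n/... astronomically small
        c = null_cohort(40, 12, prevalence=0.3, seed=2)
        cfg = bp.PipelineConfig(
            setting="I",
            model_family="naive_bayes",
            inner_folds=3,
            search_budget=2,
            bootstrap_resamples=5,
            seed=2,
        )
        r = bp.bootstrap_eval_setting1(c, cfg)
        assert len(r.reports) >= 4


class TestStratifiedErrorReport:
    def _result(self, seed=0):
        c = null_cohort(60, 10, prevalence=0.3, seed=seed)
        cfg = bp.PipelineConfig(
            model_family="naive_bayes",
            outer_folds=4,
            inner_folds=3,
            search_budget=2,
            seed=seed,
        )
        return c, bp.nested_cv(c, cfg)

    def test_stratum_counts_partition_global_confusion(self):
        c, res = self._result()
        rep = bp.stratified_error_report(res, c.clinical, min_count=0)
        for var, table in rep.items():
            totals = table.sum(axis=0)
            assert int(totals.sum()) == c.n_samples
            for k in ("tp", "fp", "tn", "fn"):
                assert int(totals[k]) == res.pooled.confusion[k]

    def test_small_strata_suppressed(self):
        c, res = self._result(seed=1)
        rep = bp.stratified_error_report(res, c.clinical, min_count=10)
        table = rep["stage_code"]
        assert all(table.sum(axis=1) >= 10)
        assert isinstance(table.attrs["suppressed"], list)

    def test_age_bins_are_decades(self):
        c, res = self._result(seed=2)
        rep = bp.stratified_error_report(res, c.clinical, min_count=0)
        for label in rep["age_bin"].index:
            lo, hi = map(int, label.split("-"))
            assert hi - lo == 9 and lo % 10 == 0

    def test_all_correct_means_no_errors(self):
        c, res = self._result(seed=3)
        # overwrite predictions with the truth
        for fr in res.folds:
            fr.labels = fr.y_true.copy()
        rep = bp.stratified_error_report(res, c.clinical, min_count=0)
        for table in rep.values():
            assert int(table["fp"].sum()) == 0 and int(table["fn"].sum()) == 0


class TestMakeClassifier:
    @pytest.mark.parametrize(
        "family",
        ["svm", "knn", "random_forest", "xgboost", "decision_tree", "naive_bayes"],
    )
    def test_uniform_fit_predict_contract(self, family):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-1, 1, (20, 3)), rng.normal(1, 1, (20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        clf = make_classifier(family, {}, seed=0)
        clf.fit(X, y)
        proba = clf.predict_proba(X)[:, 1]
        assert proba.shape == (40,) and np.all((proba >= 0) & (proba <= 1))

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            make_classifier("mystery", {})
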