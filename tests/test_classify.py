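"""Classification metrics against enumeration oracles, lasso behavior,
comparator construction, transfer-study hygiene."""

import numpy as np
import pytest

import atnfuse as af
from atnfuse.classify import DIAGNOSIS_TASKS


def auroc_pair_count(scores, labels):
    """Exhaustive pair-counting AUROC oracle: P(pos > neg), ties half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def auprc_step_integration(scores, labels):
    """Step-integrated precision-recall area: sum (R_i - R_{i-1}) * P_i."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    n_pos = y.sum()
    area = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:  # process tied block at once
            tp += y_sorted[j]
            fp += 1 - y_sorted[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestEvaluateBinary:
    def test_worked_example(self):
        m = af.evaluate_binary([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert m["auroc"] == pytest.approx(0.75)

    def test_perfect_separation(self):
        m = af.evaluate_binary([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m["auroc"] == 1.0
        assert m["auprc"] == 1.0

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        a = af.evaluate_binary(s, y)["auroc"]
        b = af.evaluate_binary(s, 1 - y)["auroc"]
        assert a + b == pytest.approx(1.0)

    def test_matches_pair_count_oracle_small_n(self):
        """Full agreement with exhaustive pair counting for all n <= 12."""
        rng = np.random.default_rng(1)
        for n in range(2, 13):
            for _ in range(40):
                s = rng.choice([0.1, 0.2, 0.2, 0.5, 0.7, 0.9], size=n)
                y = rng.integers(0, 2, n)
                if y.min() == y.max():
                    y[0] = 1 - y[0]
                m = af.evaluate_binary(s, y)
                assert m["auroc"] == pytest.approx(auroc_pair_count(s, y), abs=1e-12)
                assert m["auprc"] == pytest.approx(auprc_step_integration(s, y), abs=1e-9)

    def test_thresholded_metrics_from_confusion_counts(self):
        s = np.array([0.9, 0.8, 0.3, 0.2, 0.6, 0.1])
        y = np.array([1, 1, 1, 0, 0, 0])
        m = af.evaluate_binary(s, y)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(4 / 6)
        assert m["balanced_accuracy"] == pytest.approx(2 / 3)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            af.evaluate_binary([0.1, 0.9], [1, 1])


class TestMacroAverage:
    def test_identical_reports(self):
        rep = {"auroc": 0.8, "f1": 0.5}
        out = af.macro_average([rep, rep, rep])
        assert out == pytest.approx(rep)

    def test_arithmetic_mean(self):
        reports = [{"auroc": 1.0}, {"auroc": 0.5}, {"auroc": 0.75}]
        assert af.macro_average(reports)["auroc"] == pytest.approx(0.75)

    def test_inconsistent_keys_rejected(self):
        with pytest.raises(ValueError):
            af.macro_average([{"a": 1.0}, {"b": 1.0}])


class TestBootstrapCI:
    def test_perfect_classifier_degenerate_interval(self):
        s = np.array([0.9, 0.8, 0.1, 0.2] * 5)
        y = np.array([1, 1, 0, 0] * 5)
        lo, hi = af.bootstrap_ci(lambda a, b: af.evaluate_binary(a, b)["auroc"],
                                 s, y, B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        metric = lambda a, b: af.evaluate_binary(a, b)["auroc"]
        hits = 0
        for rep in range(20):
            y = rng.integers(0, 2, 80)
            y[:2] = [0, 1]
            s = y + rng.standard_normal(80)
            point = metric(s, y)
            lo, hi = af.bootstrap_ci(metric, s, y, B=300, seed=rep)
            hits += lo - 1e-12 <= point <= hi + 1e-12
        assert hits >= 19

    def test_width_halves_as_n_quadruples(self):
        rng = np.random.default_rng(3)
        metric = lambda a, b: af.evaluate_binary(a, b)["auroc"]
        widths = []
        for n in (100, 400):
            ws = []
            for rep in range(5):
                y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
                s = y + rng.standard_normal(n)
                lo, hi = af.bootstrap_ci(metric, s, y, B=400, seed=rep)
                ws.append(hi - lo)
            widths.append(np.mean(ws))
        ratio = widths[1] / widths[0]
        assert 0.3 <= ratio <= 0.75

    def test_seed_reproducible_and_b_floor(self):
        s = np.array([0.2, 0.8, 0.4, 0.6] * 10)
        y = np.array([0, 1, 0, 1] * 10)
        metric = lambda a, b: af.evaluate_binary(a, b)["auroc"]
        assert af.bootstrap_ci(metric, s, y, B=150, seed=4) == \
            af.bootstrap_ci(metric, s, y, B=150, seed=4)
        with pytest.raises(ValueError):
            af.bootstrap_ci(metric, s, y, B=50)


class TestLassoLogistic:
    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 10))
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        m = af.fit_lasso_logistic(X, y, lambda_grid=[1e6])
        np.testing.assert_allclose(m.coef, 0.0, atol=1e-8)
        base = y.mean()
        assert m.intercept == pytest.approx(np.log(base / (1 - base)), abs=1e-6)

    def test_separating_feature_selected(self):
        rng = np.random.default_rng(6)
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 20))
        X[:, 7] = y * 4 + rng.standard_normal(n) * 0.3
        tr, te = np.arange(0, 200), np.arange(200, n)
        m = af.fit_lasso_logistic(X[tr], y[tr], seed=0)
        assert 7 in m.selected
        auc = af.evaluate_binary(m.predict_proba(X[te]), y[te])["auroc"]
        assert auc >= 0.95

    def test_support_recovery_rate(self):
        """3 informative of 50 features recovered in >= 80% of replicates."""
        rng = np.random.default_rng(7)
        grid = np.logspace(-3, -0.5, 8)
        hits = 0
        reps = 50
        for rep in range(reps):
            n = 400
            X = rng.standard_normal((n, 50))
            logit = 1.5 * X[:, 3] - 1.5 * X[:, 17] + 1.0 * X[:, 41]
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            if y.min() == y.max():
                continue
            m = af.fit_lasso_logistic(X, y, lambda_grid=grid, inner_folds=3, seed=rep)
            hits += {3, 17, 41} <= set(m.selected)
        assert hits / reps >= 0.8

    def test_single_class_and_empty_grid_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            af.fit_lasso_logistic(X, np.ones(10, int))
        with pytest.raises(ValueError):
            af.fit_lasso_logistic(X, np.r_[np.zeros(5, int), np.ones(5, int)],
                                  lambda_grid=[])


class TestComparators:
    def test_pca_matches_eigendecomposition_oracle(self, small_dataset, small_split):
        sets = af.build_comparators(small_dataset, small_split, n_components=4,
                                    seed=0, include_ica=False)
        fs = next(s for s in sets if s.name == "GM_pcs")
        tr = small_split.train
        x = small_dataset.X[0]
        mu, sd = x[tr].mean(0), x[tr].std(0)
        xs = (x - mu) / np.where(sd < 1e-12, 1, sd)
        xc = xs[tr] - xs[tr].mean(0)
        cov = xc.T @ xc / (tr.size - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for j in range(4):
            proj = (xs[tr] - xs[tr].mean(0)) @ v[:, order[j]]
            r = np.corrcoef(proj, fs.matrix[tr][:, j])[0, 1]
            assert abs(r) > 1 - 1e-8  # equal up to sign

    def test_rank_limited_pca(self, small_split):
        from conftest import make_single_modality_dataset, all_train_split
        rng = np.random.default_rng(8)
        base = rng.standard_normal((50, 2)) @ rng.standard_normal((2, 30))
        ds = make_single_modality_dataset(base)
        sp = all_train_split(50)
        sets = af.build_comparators(ds, sp, n_components=10, seed=0, include_ica=False)
        fs = next(s for s in sets if s.name == "GM_pcs")
        assert fs.matrix.shape[1] == 2  # components beyond the rank carry no variance

    def test_top10_combo_finds_target_correlated_directions(self, small_dataset,
                                                            small_split):
        sets = af.build_comparators(small_dataset, small_split, n_components=6,
                                    seed=0, include_ica=False)
        combo = next(s for s in sets if s.name == "top10_pcs_combo")
        assert combo.matrix.shape[1] == 10
        tr = small_split.train
        y = small_dataset.target[tr]
        rs = [abs(np.corrcoef(combo.matrix[tr][:, j], y)[0, 1]) for j in range(10)]
        # the selected directions really do correlate with the training target
        assert np.mean(rs) > 0.1
        assert max(rs) > 0.3

    def test_demographics_columns(self, small_dataset, small_split):
        sets = af.build_comparators(small_dataset, small_split, seed=0,
                                    include_ica=False)
        demo = next(s for s in sets if s.name == "demographics")
        assert demo.matrix.shape[1] == 2
        assert demo.provenance["columns"] == ["age", "sex_female"]


@pytest.fixture(scope="module")
def study(small_dataset, small_split, small_fit):
    Z = small_fit.loadings_all()
    cb = af.fit_combat(Z[small_split.train], small_dataset.scanner[small_split.train])
    Zh = cb.transform(Z, small_dataset.scanner)
    fs = af.FeatureSet("fused_loadings", Zh)
    return af.run_transfer_study(small_dataset, [fs], small_split,
                                 boot_B=120, seed=0)


class TestTransferStudy:
    def test_all_tasks_reported(self, study):
        tasks = study.results["fused_loadings"]
        expected = {f"{a}_vs_{b}" for a, b in DIAGNOSIS_TASKS} | {"carrier"}
        assert set(tasks) == expected
        for t in tasks.values():
            assert t.status == "ok" or t.status.startswith("skipped")

    def test_macro_equals_external_recomputation(self, study):
        tasks = study.results["fused_loadings"]
        ok = [t for name, t in tasks.items() if name != "carrier" and t.status == "ok"]
        if not ok:
            pytest.skip("no complete diagnosis task in this draw")
        mac = study.macro["fused_loadings"]
        expect = np.mean([t.test_metrics["auroc"] for t in ok])
        assert mac["auroc"] == pytest.approx(expect)

    def test_metrics_bounded(self, study):
        for tasks in study.results.values():
            for t in tasks.values():
                for v in t.test_metrics.values():
                    assert 0.0 <= v <= 1.0

    def test_report_serializes(self, study):
        import json
        json.dumps(study.to_dict())


class TestLeakageSentinel:
    def test_test_split_corruption_leaves_training_artifacts_unchanged(
            self, small_dataset, small_split):
        """No test-split information may enter any training-side fit."""
        import copy
        ds2 = copy.deepcopy(small_dataset)
        te = small_split.test
        rng = np.random.default_rng(0)
        ds2.pheno.iloc[te, ds2.pheno.columns.get_loc("target")] = \
            rng.permutation(ds2.pheno["target"].to_numpy()[te])
        ds2.pheno.iloc[te, ds2.pheno.columns.get_loc("carrier")] = \
            rng.integers(0, 2, te.size)
        sets1 = af.build_comparators(small_dataset, small_split, n_components=3,
                                     seed=1, include_ica=False)
        sets2 = af.build_comparators(ds2, small_split, n_components=3,
                                     seed=1, include_ica=False)
        for a, b in zip(sets1, sets2):
            np.testing.assert_array_equal(a.matrix[small_split.train],
                                          b.matrix[small_split.train])
        tr = small_split.train
        y = small_dataset.pheno["carrier"].to_numpy()
        m1 = af.fit_lasso_logistic(sets1[1].matrix[tr], y[tr], seed=2)
        m2 = af.fit_lasso_logistic(sets2[1].matrix[tr], y[tr], seed=2)
        np.testing.assert_array_equal(m1.coef, m2.coef)
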