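import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from preprotac.modeling import (
    THRESHOLD_LATTICE,
    CalibrationError,
    CVReport,
    EnsembleModel,
    MetricUndefinedError,
    calibrate_threshold,
    consensus_vote,
    fpr_at_threshold,
    fpr_curve,
    grid_search,
    load_model,
    pr_curve,
    repeated_stratified_cv,
    roc_auc,
    save_model,
    sensitivity_at_fpr,
    soft_vote,
)


class _FixedModel:
    """Stand-in member returning preset probabilities."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, features):
        return self.probs


def _separable(n=60, p=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 3.0, -3.0)
    return X, y


class TestMetrics:
    def test_perfect_separation_auc_one(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_auc_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_toy_set_matches_pairwise_concordance(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2]
        labels = [0, 1, 0, 1, 0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            oracles.brute_roc_auc(scores, labels), abs=1e-12
        )

    def test_single_class_undefined(self):
        with pytest.raises(MetricUndefinedError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_perfect_ap(self):
        *_, ap = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ap == 1.0

    def test_toy_ap_matches_direct_formula(self):
        scores = [0.9, 0.7, 0.7, 0.4, 0.2]
        labels = [1, 0, 1, 1, 0]
        *_, ap = pr_curve(scores, labels)
        assert ap == pytest.approx(oracles.brute_average_precision(scores, labels), abs=1e-12)

    def test_fpr_at_reference_operating_points(self):
        # 241 negatives, exactly one scoring above the 0.85 cutoff
        neg = np.full(241, 0.2)
        neg[0] = 0.9
        scores = np.concatenate([neg, [0.95, 0.99]])
        labels = np.array([0] * 241 + [1, 1])
        fpr85 = fpr_at_threshold(scores, labels, 0.85)
        assert fpr85 == pytest.approx(1 / 241)
        assert round(fpr85, 3) == 0.004
        assert fpr_at_threshold(scores, labels, 0.91) == 0.0

    def test_fpr_threshold_above_max_score_is_zero(self):
        assert fpr_at_threshold([0.3, 0.5], [0, 0], 0.6) == 0.0

    def test_fpr_needs_negatives(self):
        with pytest.raises(MetricUndefinedError):
            fpr_at_threshold([0.3], [1], 0.5)

    def test_boundary_score_counts_as_positive(self):
        assert fpr_at_threshold([0.9], [0], 0.9) == 1.0

    def test_sensitivity_perfect_classifier(self):
        assert sensitivity_at_fpr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.05) == 1.0

    def test_sensitivity_toy_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(4)
        scores = rng.random(8)
        labels = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        for cap in (0.0, 0.25, 0.5, 1.0):
            assert sensitivity_at_fpr(scores, labels, cap) == pytest.approx(
                oracles.brute_sensitivity_at_fpr(scores, labels, cap)
            )

    def test_sensitivity_monotone_in_cap(self):
        rng = np.random.default_rng(5)
        scores, labels = rng.random(30), rng.integers(0, 2, 30)
        vals = [sensitivity_at_fpr(scores, labels, c) for c in (0.0, 0.1, 0.3, 1.0)]
        assert vals == sorted(vals)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=30))
    def test_fpr_curve_non_increasing_in_threshold(self, scores):
        labels = [0, 1] * (len(scores) // 2) + [0] * (len(scores) % 2)
        curve = fpr_curve(scores, labels)
        assert (np.diff(curve) <= 1e-12).all()


class TestVoting:
    def test_soft_vote_is_member_mean(self):
        members = [_FixedModel([0.8]), _FixedModel([0.6])]
        assert soft_vote(members, None)[0] == pytest.approx(0.7)

    def test_soft_vote_invariant_to_member_order(self):
        rng = np.random.default_rng(0)
        members = [_FixedModel(rng.random(5)) for _ in range(4)]
        a = soft_vote(members, None)
        b = soft_vote(members[::-1], None)
        np.testing.assert_allclose(a, b)

    @pytest.mark.parametrize(
        "probs,expected",
        [((0.95, 0.92), 1), ((0.95, 0.2), 0), ((0.2, 0.1), 0)],
    )
    def test_consensus_requires_all_members_positive(self, probs, expected):
        members = [_FixedModel([p]) for p in probs]
        out = consensus_vote(members, None, [0.9, 0.9])
        assert out[0] == expected

    def test_single_member_consensus_is_thresholding(self):
        out = consensus_vote([_FixedModel([0.91, 0.5])], None, [0.9])
        np.testing.assert_array_equal(out, [1, 0])

    def test_ensemble_needs_two_members(self):
        with pytest.raises(ValueError):
            EnsembleModel(members=[_FixedModel([0.5])])


class TestGridSearch:
    def test_grid_of_size_one_returned(self):
        X, y = _separable()
        best, results = grid_search(X, y, "rf", {"n_estimators": [20]}, seed=0)
        assert best == {"n_estimators": 20} and len(results) == 1

    def test_separable_data_reaches_auc_one(self):
        X, y = _separable()
        _, results = grid_search(X, y, "rf", {"n_estimators": [20]}, seed=0)
        assert results[0]["mean_roc_auc"] == 1.0

    def test_enumeration_order_only_affects_tie_break(self):
        X, y = _separable()
        g1 = {"n_estimators": [10, 20], "max_depth": [2, 4]}
        g2 = {"max_depth": [4, 2], "n_estimators": [20, 10]}
        _, r1 = grid_search(X, y, "rf", g1, seed=0)
        _, r2 = grid_search(X, y, "rf", g2, seed=0)
        key = lambda e: tuple(sorted(e["hyperparameters"].items()))
        assert {key(e): e["mean_roc_auc"] for e in r1} == {key(e): e["mean_roc_auc"] for e in r2}

    def test_too_few_samples_per_class(self):
        X = np.zeros((6, 2))
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="stratified"):
            grid_search(X, y, "rf", {"n_estimators": [5]}, n_splits=5)


class TestRepeatedCV:
    def test_defaults_give_ten_fold_models(self):
        X, y = _separable()
        report, folds = repeated_stratified_cv(X, y, "rf", {"n_estimators": 10}, seed=0)
        assert len(folds) == 10 and len(report.folds) == 10

    def test_each_sample_held_out_once_per_repeat(self):
        X, y = _separable(n=40)
        _, folds = repeated_stratified_cv(X, y, "rf", {"n_estimators": 5}, seed=0)
        all_ids = set(str(i) for i in range(40))
        for repeat in range(2):
            held_out = []
            for fm in folds[repeat * 5 : (repeat + 1) * 5]:
                held_out.extend(all_ids - set(fm.train_ids))
            assert sorted(held_out) == sorted(all_ids)

    def test_fold_class_proportions_near_global(self):
        X, y = _separable(n=50)
        _, folds = repeated_stratified_cv(X, y, "rf", {"n_estimators": 5}, seed=0)
        global_pos = y.sum() / len(y)
        for fm in folds:
            test_idx = [i for i in range(50) if str(i) not in set(fm.train_ids)]
            n_pos = y[test_idx].sum()
            assert abs(n_pos - global_pos * len(test_idx)) <= 1.0

    def test_fixed_seed_reproduces_report(self):
        X, y = _separable()
        r1, _ = repeated_stratified_cv(X, y, "rf", {"n_estimators": 10}, seed=3)
        r2, _ = repeated_stratified_cv(X, y, "rf", {"n_estimators": 10}, seed=3)
        assert [f["roc_auc"] for f in r1.folds] == [f["roc_auc"] for f in r2.folds]
        assert r1.mean_roc_auc == r2.mean_roc_auc

    def test_gbt_also_supported(self):
        X, y = _separable()
        report, folds = repeated_stratified_cv(
            X, y, "gbt", {"n_estimators": 10, "max_depth": 2}, seed=0
        )
        assert len(folds) == 10 and 0.0 <= report.mean_roc_auc <= 1.0


class TestCalibration:
    def _report_with_curves(self, curves):
        rep = CVReport(scheme={})
        for c in curves:
            rep.folds.append(
                {"roc_auc": 1.0, "average_precision": 1.0, "roc_curve": (None, None),
                 "pr_curve": (None, None), "fpr_curve": np.asarray(c)}
            )
        return rep

    def test_hand_computed_curve(self):
        # mean FPR drops to 0.05 at lattice index 60 and 0.0 at 80
        curve = np.ones(101)
        curve[60:] = 0.05
        curve[80:] = 0.0
        rep = self._report_with_curves([curve])
        assert calibrate_threshold(rep, 0.05) == pytest.approx(THRESHOLD_LATTICE[60])
        assert calibrate_threshold(rep, 0.0) == pytest.approx(THRESHOLD_LATTICE[80])

    def test_mean_over_folds(self):
        c1, c2 = np.zeros(101), np.zeros(101)
        c1[:50] = 1.0
        c2[:70] = 1.0  # mean is 0.5 on [50, 70)
        rep = self._report_with_curves([c1, c2])
        assert calibrate_threshold(rep, 0.4) == pytest.approx(THRESHOLD_LATTICE[70])

    def test_achieved_fpr_meets_target(self):
        rng = np.random.default_rng(0)
        curves = [np.sort(rng.random(101))[::-1] for _ in range(3)]
        rep = self._report_with_curves(curves)
        for target in (0.1, 0.5):
            thr = calibrate_threshold(rep, target)
            i = int(np.argmin(np.abs(THRESHOLD_LATTICE - thr)))
            assert rep.mean_fpr_curve()[i] <= target

    def test_unreachable_target(self):
        rep = self._report_with_curves([np.full(101, 0.3)])
        with pytest.raises(CalibrationError):
            calibrate_threshold(rep, 0.1)


class TestPersistence:
    def test_round_trip_identical_predictions(self, tmp_path):
        X, y = _separable()
        _, folds = repeated_stratified_cv(X, y, "rf", {"n_estimators": 10}, seed=0)
        ens = EnsembleModel(members=folds, threshold=0.9)
        path = tmp_path / "m.joblib"
        save_model(ens, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.predict_proba(X), ens.predict_proba(X))
        assert back.threshold == ens.threshold

    def test_bad_container_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "m.joblib"
        joblib.dump({"something": 1}, path)
        with pytest.raises(ValueError):
            load_model(path)
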