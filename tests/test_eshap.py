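import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from preprotac.descriptors import FeatureMatrix
from preprotac.eshap import (
    MutScanResult,
    ShapSelection,
    difference_score,
    eshap_scan,
    report_key_positions,
    select_top_features,
)

vec20 = st.lists(st.floats(-5, 5, allow_nan=False), min_size=25, max_size=25)


def _selection(indices=range(20)):
    k = len(list(indices))
    return ShapSelection(
        feature_indices=list(indices), importances=[1.0] * k, source_model="t", k=k
    )


class TestSelectTopFeatures:
    def test_requires_embedding_provenance(self, small_rf, small_cohort):
        _, _, _, fm, _ = small_cohort
        bad = FeatureMatrix(fm.sample_ids, fm.feature_names, fm.values, provenance="descriptor:tpc")
        with pytest.raises(ValueError, match="embedding"):
            select_top_features(small_rf, bad, k=5)
        sel = select_top_features(small_rf, bad, k=5, require_embedding=False)
        assert len(sel.feature_indices) == 5

    def test_importances_sorted_and_unique_indices(self, small_rf, small_cohort):
        _, _, _, fm, _ = small_cohort
        sel = select_top_features(small_rf, fm, k=20)
        assert len(set(sel.feature_indices)) == 20
        assert all(a >= b for a, b in zip(sel.importances, sel.importances[1:]))

    def test_k_equal_to_feature_count_returns_all_sorted(self, small_rf, small_cohort):
        _, _, _, fm, _ = small_cohort
        sel = select_top_features(small_rf, fm, k=fm.shape[1])
        assert sorted(sel.feature_indices) == list(range(fm.shape[1]))

    def test_k_beyond_feature_count_rejected(self, small_rf, small_cohort):
        _, _, _, fm, _ = small_cohort
        with pytest.raises(ValueError):
            select_top_features(small_rf, fm, k=fm.shape[1] + 1)

    def test_ensemble_attribution_is_member_mean(self, small_cohort):
        from preprotac.modeling import EnsembleModel, repeated_stratified_cv
        from preprotac.treeshap import shap_values

        _, _, _, fm, y = small_cohort
        _, folds = repeated_stratified_cv(fm, y, "rf", {"n_estimators": 10}, seed=2)
        ens = EnsembleModel(members=folds)
        sel = select_top_features(ens, fm, k=10)
        phi = np.mean([shap_values(m.estimator, fm.values)[0] for m in folds], axis=0)
        expected = np.abs(phi).mean(axis=0)
        order = np.lexsort((np.arange(len(expected)), -expected))[:10]
        assert sel.feature_indices == [int(i) for i in order]


class TestDifferenceScore:
    def test_identical_vectors_zero(self):
        v = np.arange(25.0)
        assert difference_score(v, v, _selection()) == 0.0

    def test_pythagorean_example(self):
        ref = np.zeros(25)
        mut = np.zeros(25)
        mut[0], mut[1] = 3.0, 4.0
        assert difference_score(ref, mut, _selection()) == pytest.approx(5.0)

    def test_only_selected_features_count(self):
        ref = np.zeros(25)
        mut = np.zeros(25)
        mut[24] = 100.0  # outside the selected first 20
        assert difference_score(ref, mut, _selection()) == 0.0

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(0)
        sel = _selection(rng.choice(25, size=20, replace=False).tolist())
        # reconstruct with sorted importances to satisfy the invariant
        for _ in range(10):
            ref, mut = rng.normal(size=25), rng.normal(size=25)
            expected = oracles.brute_difference_score(ref, mut, sel.feature_indices)
            assert difference_score(ref, mut, sel) == pytest.approx(expected, abs=1e-12)

    def test_index_out_of_range(self):
        sel = _selection([30])
        with pytest.raises(ValueError, match="range"):
            difference_score(np.zeros(25), np.zeros(25), sel)

    @settings(max_examples=50, deadline=None)
    @given(vec20, vec20, vec20)
    def test_metric_axioms_on_selected_subspace(self, a, b, c):
        a, b, c = np.array(a), np.array(b), np.array(c)
        sel = _selection()
        dab = difference_score(a, b, sel)
        dba = difference_score(b, a, sel)
        assert dab == pytest.approx(dba)  # symmetry
        assert dab >= 0.0
        idx = sel.feature_indices
        if np.array_equal(a[idx], b[idx]):
            assert dab == 0.0
        dac = difference_score(a, c, sel)
        dcb = difference_score(c, b, sel)
        assert dab <= dac + dcb + 1e-9  # triangle inequality


class TestScan:
    def test_scan_has_one_score_per_position_and_max_first(self, small_cohort, small_rf):
        dataset, truth, emb, fm, _ = small_cohort
        rec = dataset.records[0]
        res = eshap_scan(rec, emb, small_rf, training_features=fm, k=20)
        assert len(res.position_scores) == len(rec.sequence)
        scores = {p: s for p, _, _, s in res.position_scores}
        top = res.ranked_positions[0]
        assert scores[top] == max(scores.values())
        assert sorted(res.ranked_positions) == list(range(1, len(rec.sequence) + 1))

    def test_rank_ties_broken_by_lower_position(self, small_cohort, small_rf):
        dataset, _, emb, fm, _ = small_cohort
        res = eshap_scan(dataset.records[1], emb, small_rf, training_features=fm, k=20)
        pairs = sorted(
            ((s, p) for p, _, _, s in res.position_scores), key=lambda t: (-t[0], t[1])
        )
        assert res.ranked_positions == [p for _, p in pairs]

    def test_deterministic(self, small_cohort, small_rf):
        dataset, _, emb, fm, _ = small_cohort
        r1 = eshap_scan(dataset.records[2], emb, small_rf, training_features=fm, k=20)
        r2 = eshap_scan(dataset.records[2], emb, small_rf, training_features=fm, k=20)
        assert r1.position_scores == r2.position_scores
        assert r1.ranked_positions == r2.ranked_positions

    def test_needs_selection_or_training_features(self, small_cohort, small_rf):
        dataset, _, emb, _, _ = small_cohort
        with pytest.raises(ValueError, match="Selection|training"):
            eshap_scan(dataset.records[0], emb, small_rf)


class TestReport:
    def _result(self):
        scores = [(1, "K", "E", 0.5), (2, "D", "K", 0.9), (3, "A", "S", 0.1)]
        return MutScanResult(
            protein_id="p", position_scores=scores, ranked_positions=[2, 1, 3], params={}
        )

    def test_top_n_rows_sorted_descending(self):
        df = report_key_positions(self._result(), top_n=2)
        assert list(df["position"]) == [2, 1]
        assert list(df["rank"]) == [1, 2]
        assert df["score"].is_monotonic_decreasing

    def test_top_n_full_table(self):
        df = report_key_positions(self._result(), top_n=3)
        assert len(df) == 3 and list(df.columns) == [
            "protein_id", "position", "ref_aa", "alt_aa", "score", "rank",
        ]

    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "scan.tsv"
        self._result().to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 3 and df.loc[df["position"] == 2, "rank"].item() == 1
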