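import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import precision_recall_fscore_support

from segbeat import (HeartbeatClassifier, LeakageError, PipelineConfig,
                     aami_group, balanced_weights, evaluate_predictions,
                     gini, lopo_tune, m_prime, run_pipeline, train_forest)
from segbeat.classify import AAMI_MAP, DS1_RECORDS, DS2_RECORDS, ForestConfig
from segbeat import OracleSegmentClassifier, SynthConfig, generate_record


class TestGini:
    @pytest.mark.parametrize("p, expected", [
        ([1, 0], 0.0),
        ([0.5, 0.5], 0.5),
        ([0.25] * 4, 0.75),
    ])
    def test_known_values(self, p, expected):
        assert gini(p) == pytest.approx(expected)

    def test_requires_distribution(self):
        with pytest.raises(ValueError):
            gini([0.5, 0.2])


class TestBalancedWeights:
    def test_balanced_input_all_ones(self):
        np.testing.assert_allclose(balanced_weights(list("AABB")), 1.0)

    def test_imbalanced_example(self):
        # N_total/(C*N_c): A -> 4/(2*3), B -> 4/(2*1); sums to N_total
        w = balanced_weights(list("AAAB"))
        np.testing.assert_allclose(w, [2 / 3, 2 / 3, 2 / 3, 2.0])
        assert w.sum() == pytest.approx(4.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from("abc"), min_size=1, max_size=50))
    def test_class_masses_equalized(self, labels):
        w = balanced_weights(labels)
        y = np.asarray(labels)
        masses = {c: w[y == c].sum() for c in set(labels)}
        first = next(iter(masses.values()))
        assert all(abs(m - first) < 1e-9 for m in masses.values())
        assert w.sum() == pytest.approx(len(labels))


class TestAamiGrouping:
    def test_known_symbols(self):
        assert aami_group(["V"])[0] == "VEB"
        assert aami_group(["A"])[0] == "SVEB"
        assert aami_group(["N"])[0] == "N"

    def test_fifteen_symbols_give_five_classes(self):
        symbols = list(AAMI_MAP)
        assert len(symbols) == 15
        assert set(aami_group(symbols)) == {"N", "SVEB", "VEB", "F", "Q"}

    def test_unknown_symbol_is_named_in_error(self):
        with pytest.raises(ValueError, match="'x'"):
            aami_group(["N", "x"])

    def test_interpatient_division_is_disjoint(self):
        assert len(DS1_RECORDS) == len(DS2_RECORDS) == 22
        assert not set(DS1_RECORDS) & set(DS2_RECORDS)


class TestForest:
    def test_m_prime_floor_sqrt(self):
        assert m_prime(7) == 2
        assert m_prime(79) == 8
        assert m_prime(1) == 1

    def test_separable_classes_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (200, 3)), rng.normal(8, 1, (200, 3))])
        y = np.array(["a"] * 200 + ["b"] * 200)
        model = train_forest(X, y, ForestConfig(50, 0))
        assert (model.predict(X) == y).mean() == 1.0

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 4))
        y = np.array(["a", "b"] * 60)
        Xt = rng.normal(size=(40, 4))
        a = train_forest(X, y, ForestConfig(30, 7)).predict(Xt)
        b = train_forest(X, y, ForestConfig(30, 7)).predict(Xt)
        np.testing.assert_array_equal(a, b)


class TestMetrics:
    def test_perfect_predictions(self):
        rep = evaluate_predictions(list("aabb"), list("aabb"))
        assert rep.macro_f1 == 1.0
        assert rep.accuracy == 1.0

    def test_hand_checked_two_class_matrix(self):
        y_true = ["a"] * 10 + ["b"] * 10
        y_pred = (["a"] * 8 + ["b"] * 2) + (["a"] * 3 + ["b"] * 7)
        rep = evaluate_predictions(y_true, y_pred)
        assert rep.precision["a"] == pytest.approx(8 / 11)
        assert rep.precision["b"] == pytest.approx(7 / 9)
        assert rep.recall["a"] == pytest.approx(0.8)
        assert rep.recall["b"] == pytest.approx(0.7)
        f1a = 2 * (8 / 11) * 0.8 / (8 / 11 + 0.8)
        f1b = 2 * (7 / 9) * 0.7 / (7 / 9 + 0.7)
        assert rep.macro_f1 == pytest.approx((f1a + f1b) / 2)
        assert rep.accuracy == pytest.approx(0.75)

    def test_prediction_only_class_excluded_from_macro(self):
        rep = evaluate_predictions(["a", "a", "b", "b"], ["a", "a", "b", "c"])
        assert "c" in rep.labels
        # macro over {a, b} only
        assert rep.macro_f1 == pytest.approx((rep.f1["a"] + rep.f1["b"]) / 2)
        assert rep.f1["c"] == 0.0

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_reference_implementation(self, trial):
        rng = np.random.default_rng(trial)
        labels = np.array(list("abcd"))
        y_true = labels[rng.integers(0, 4, 200)]
        y_pred = labels[rng.integers(0, 4, 200)]
        rep = evaluate_predictions(y_true, y_pred)
        present = sorted(set(y_true))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=sorted(set(y_true) | set(y_pred)),
            zero_division=0)
        for i, c in enumerate(sorted(set(y_true) | set(y_pred))):
            assert rep.precision[c] == pytest.approx(p[i])
            assert rep.recall[c] == pytest.approx(r[i])
            assert rep.f1[c] == pytest.approx(f[i])
        f_macro = precision_recall_fscore_support(
            y_true, y_pred, labels=present, zero_division=0)[2].mean()
        assert rep.macro_f1 == pytest.approx(f_macro)
        assert rep.accuracy == pytest.approx((y_true == y_pred).mean())

    def test_empty_evaluation_rejected(self):
        with pytest.raises(ValueError):
            evaluate_predictions([], [])


def _small_dataset(n_records, seed=0, **cfg_kw):
    cfg = SynthConfig(seed=seed, rhythm_blocks=(("NSR", 30.0),
                                                ("AFIB_LIKE", 30.0)), **cfg_kw)
    return [generate_record(cfg, f"t{seed}-{i}") for i in range(n_records)]


def _frames(pairs, seg_len=30.0, with_oracle=False):
    from segbeat.pipeline import record_design_frame
    cfg = PipelineConfig(n_trees=30, segment_length_s=seg_len)
    clf = None
    if with_oracle:
        truths = {rec.record_id: t for rec, t in pairs}
        clf = OracleSegmentClassifier(truths, segment_length_s=seg_len)
    return [record_design_frame(rec, cfg, clf) for rec, _ in pairs], cfg


class TestHeartbeatClassifier:
    def test_selects_n_features_plus_segment_columns(self):
        pairs = _small_dataset(4)
        frames, _ = _frames(pairs, with_oracle=True)
        X = pd.concat([f for f, _ in frames], ignore_index=True)
        y = np.concatenate([y for _, y in frames])
        clf = HeartbeatClassifier(n_features=6, n_trees=20).fit(X, y)
        assert len(clf.selected_features_) == 6
        assert clf.feature_columns_ == clf.selected_features_ + \
            ["seg_AFIB_LIKE", "seg_NSR"]
        assert len(clf.ranking_) == 79

    def test_without_segment_label_uses_exactly_n_features(self):
        pairs = _small_dataset(4)
        frames, _ = _frames(pairs, with_oracle=False)
        X = pd.concat([f for f, _ in frames], ignore_index=True)
        y = np.concatenate([y for _, y in frames])
        clf = HeartbeatClassifier(n_features=6, n_trees=20).fit(X, y)
        assert len(clf.feature_columns_) == 6

    def test_requires_dataframe(self):
        with pytest.raises(TypeError):
            HeartbeatClassifier().fit(np.zeros((10, 5)), np.zeros(10))

    def test_sklearn_params_round_trip(self):
        clf = HeartbeatClassifier(n_features=4, n_trees=10, seed=3)
        params = clf.get_params()
        assert params["n_features"] == 4
        clone = HeartbeatClassifier(**params)
        assert clone.get_params() == params


class TestPipeline:
    def test_leakage_guard_rejects_shared_records(self):
        pairs = _small_dataset(2)
        recs = [rec for rec, _ in pairs]
        with pytest.raises(LeakageError):
            run_pipeline(recs, recs, PipelineConfig(n_trees=10,
                                                    use_segment_label=False))

    def test_end_to_end_report_is_deterministic(self):
        pairs = _small_dataset(6, seed=2)
        recs = [rec for rec, _ in pairs]
        truths = {rec.record_id: t for rec, t in pairs}
        cfg = PipelineConfig(n_trees=20, segment_length_s=30.0)
        clf = OracleSegmentClassifier(truths, segment_length_s=30.0)
        rep1, art1 = run_pipeline(recs[:3], recs[3:], cfg, clf)
        rep2, art2 = run_pipeline(recs[:3], recs[3:], cfg, clf)
        assert rep1.to_dict() == rep2.to_dict()
        assert art1["selected_features"] == art2["selected_features"]
        assert 0.0 <= rep1.macro_f1 <= 1.0

    def test_segment_id_is_single_column_before_expansion(self):
        pairs = _small_dataset(2)
        rec, truth = pairs[0]
        clf = OracleSegmentClassifier({rec.record_id: truth},
                                      segment_length_s=30.0)
        from segbeat import assign_segment_labels
        labeling = assign_segment_labels(rec, clf, "none")
        assert labeling.beat_ids.ndim == 1  # one categorical column
        assert labeling.feature_frame().shape[1] == 2  # one-hot expansion


class TestLopoTune:
    def _record_frames(self, n=3):
        pairs = _small_dataset(n, seed=5)
        frames, _ = _frames(pairs)
        return frames

    def test_single_grid_value_returned(self):
        frames = self._record_frames()
        best, scores = lopo_tune(frames, grid=[10], n_features=4)
        assert best == 10
        assert set(scores) == {10}

    def test_fold_count_equals_record_count(self):
        frames = self._record_frames(3)
        _, scores = lopo_tune(frames, grid=[10], n_features=4)
        assert len(scores[10]) == 3

    def test_deterministic_and_ties_prefer_fewer_trees(self):
        frames = self._record_frames(3)
        best1, s1 = lopo_tune(frames, grid=[10, 20], n_features=4)
        best2, s2 = lopo_tune(frames, grid=[10, 20], n_features=4)
        assert best1 == best2 and s1 == s2
        if np.isclose(np.mean(s1[10]), np.mean(s1[20])):
            assert best1 == 10

    def test_requires_two_records(self):
        frames = self._record_frames(1)
        with pytest.raises(ValueError):
            lopo_tune(frames, grid=[10])
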