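import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.datasets import make_blobs

from fogait.data_io import AnnotatedEpisode, FogaitError
from fogait.feature_extraction import build_design_matrix
from fogait.fog_classification import (
    ClassifierSpec,
    FIXED_TOP5_FEATURES,
    auc_score,
    compare_models_ttest,
    default_spec,
    evaluate_metrics,
    label_motion_phases,
    lopo_cross_validate,
    preakinesia_fraction,
    rater_agreement,
    select_best_foot,
    train_classifier,
    tune_hyperparameters,
)
from fogait.gait_segmentation import MotionPhase
from fogait.synthetic_gait import simulate_cohort


def _phase(t_end):
    return MotionPhase(t_start=t_end - 0.5, t_end=t_end,
                       start_rule="pitch_max", end_rule="pitch_min")


def auc_bruteforce(scores, labels):
    """Independent oracle: exhaustive positive-negative pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


class TestLabeling:
    def test_no_episodes_all_normal(self):
        labels = label_motion_phases([_phase(1.0), _phase(2.0)], [], "OR")
        np.testing.assert_array_equal(labels, [0, 0])

    def test_or_vs_and_combination(self):
        episodes = [AnnotatedEpisode(1.5, 2.5, "shuffling", "expert1"),
                    AnnotatedEpisode(5.0, 6.0, "trembling", "expert2")]
        phases = [_phase(2.0)]
        assert label_motion_phases(phases, episodes, "OR")[0] == 1
        assert label_motion_phases(phases, episodes, "AND")[0] == 0

    def test_half_open_boundary(self):
        episodes = [AnnotatedEpisode(1.5, 2.5, "shuffling", "expert1")]
        assert label_motion_phases([_phase(2.5)], episodes, "OR")[0] == 0
        assert label_motion_phases([_phase(1.5)], episodes, "OR")[0] == 1

    def test_invalid_combination(self):
        with pytest.raises(FogaitError):
            label_motion_phases([_phase(1.0)], [], "XOR")


class TestRaterAgreement:
    def test_identical(self):
        assert rater_agreement([1, 0, 1], [1, 0, 1]) == 1.0

    def test_disjoint(self):
        a = [1] * 5 + [0] * 5
        b = [0] * 5 + [1] * 5
        assert rater_agreement(a, b) == 0.0

    def test_partial_overlap(self):
        # e1 marks {1,2,3}, e2 marks {2,3,4} out of 5 phases -> 2/4
        a = [1, 1, 1, 0, 0]
        b = [0, 1, 1, 1, 0]
        assert rater_agreement(a, b) == 0.5

    def test_empty_or_set(self):
        assert rater_agreement([0, 0], [0, 0]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(FogaitError):
            rater_agreement([1], [1, 0])


class TestSpecs:
    def test_shipped_svm_defaults(self):
        assert default_spec("C210", "SVM_10").hyperparams == {
            "kernel": "rbf", "C": 2.37, "gamma": 0.026}
        assert default_spec("C0", "SVM_10").hyperparams == {
            "kernel": "rbf", "C": 5.9, "gamma": 0.005}
        assert default_spec("C0", "SVM_5").hyperparams == {
            "kernel": "rbf", "C": 0.032, "gamma": 0.33}
        assert default_spec("C21", "SVM_5").hyperparams == {
            "kernel": "rbf", "C": 10.0, "gamma": 0.081}

    def test_shipped_adaboost_defaults(self):
        hp = default_spec("C0", "AdaBoost").hyperparams
        assert hp == {"criterion": "entropy", "max_depth": 3,
                      "n_estimators": 20, "learning_rate": 0.318}
        hp210 = default_spec("C210", "AdaBoost").hyperparams
        assert hp210["criterion"] == "gini" and hp210["max_depth"] == 2
        assert hp210["learning_rate"] == 0.447

    @pytest.mark.parametrize("hp", [{"C": -1.0}, {"gamma": 0.0}, {"n_estimators": 0}])
    def test_invalid_hyperparams(self, hp):
        with pytest.raises(FogaitError):
            ClassifierSpec(hyperparams=hp)

    def test_unknown_variant_or_model(self):
        with pytest.raises(FogaitError):
            ClassifierSpec(variant="C99")
        with pytest.raises(FogaitError):
            ClassifierSpec(model="RandomForest")


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(n_samples=200, centers=2, cluster_std=0.5, random_state=0)
    return X, y


class TestTrainClassifier:

    def test_svm_separable_blobs(self, blobs):
        X, y = blobs
        model = train_classifier(X, y, default_spec("C210", "SVM_10"), seed=0)
        assert (model.predict(X) == y).mean() >= 0.99

    def test_adaboost_separable_blobs(self, blobs):
        X, y = blobs
        model = train_classifier(X, y, default_spec("C0", "AdaBoost"), seed=0)
        assert (model.predict(X) == y).mean() >= 0.99

    def test_single_class_rejected(self, blobs):
        X, _ = blobs
        with pytest.raises(FogaitError):
            train_classifier(X, np.ones(len(X), dtype=int), default_spec("C0", "SVM_10"))

    def test_decision_function_available(self, blobs):
        X, y = blobs
        for model_name in ("SVM_10", "AdaBoost"):
            model = train_classifier(X, y, default_spec("C0", model_name), seed=0)
            scores = model.decision_function(X)
            assert scores.shape == (len(X),)


class TestTuneHyperparameters:
    def test_deterministic(self, blobs):
        X, y = blobs
        spec = default_spec("C0", "SVM_10")
        a = tune_hyperparameters(X, y, spec, budget=5, seed=3)
        b = tune_hyperparameters(X, y, spec, budget=5, seed=3)
        assert a == b

    def test_budget_one_returns_single_point(self, blobs):
        X, y = blobs
        hp = tune_hyperparameters(X, y, default_spec("C0", "SVM_10"), budget=1, seed=0)
        assert set(hp) == {"kernel", "C", "gamma"}

    def test_zero_budget_rejected(self, blobs):
        X, y = blobs
        with pytest.raises(FogaitError):
            tune_hyperparameters(X, y, default_spec("C0", "SVM_10"), budget=0)

    def test_tuned_not_much_worse_than_default(self, blobs):
        X, y = blobs
        spec = default_spec("C0", "SVM_10")
        hp = tune_hyperparameters(X, y, spec, budget=10, seed=0)
        tuned = train_classifier(X, y, spec.with_hyperparams(**hp), seed=0)
        default = train_classifier(X, y, spec, seed=0)
        auc_t = auc_score(tuned.decision_function(X), y)
        auc_d = auc_score(default.decision_function(X), y)
        assert auc_t >= auc_d - 0.02


class TestMetrics:
    def test_perfectly_ordered_auc(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert evaluate_metrics(scores, labels)["auc"] == 1.0

    def test_all_ties_auc_half(self):
        assert auc_score(np.ones(10), np.array([0, 1] * 5)) == 0.5

    def test_pairwise_example(self):
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auc_score(scores, labels) == pytest.approx(0.75)

    def test_single_class_auc_nan(self):
        assert np.isnan(auc_score(np.array([1.0, 2.0]), np.array([1, 1])))

    def test_duplication_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        m1 = evaluate_metrics(scores, labels)
        m2 = evaluate_metrics(np.tile(scores, 2), np.tile(labels, 2))
        assert m1["sensitivity"] == m2["sensitivity"]
        assert m1["specificity"] == m2["specificity"]
        assert m1["auc"] == pytest.approx(m2["auc"])

    @given(st.integers(0, 2**32 - 1), st.integers(4, 50))
    @settings(max_examples=60, deadline=None)
    def test_auc_matches_bruteforce(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n), 1)  # rounding provokes ties
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        assert auc_score(scores, labels) == pytest.approx(
            auc_bruteforce(scores, labels), abs=1e-12)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(n_subjects=8, fog_prevalence=0.6,
                           effect_size=2.0, seed=7, n_phases=25)


class TestLopoCrossValidation:

    def test_two_subject_cohort_counts(self):
        frame = simulate_cohort(n_subjects=2, fog_prevalence=0.5, seed=0,
                                n_phases=30, label_persistence=0.3)
        result = lopo_cross_validate(frame, default_spec("C0", "SVM_10"), seed=0)
        assert len(result.frame) == 4  # 2 subjects x 2 feet
        assert set(result.frame["subject_id"]) == {"P01", "P02"}

    def test_strong_separation_high_auc(self, cohort):
        result = lopo_cross_validate(cohort, default_spec("C0", "SVM_10"), seed=7)
        assert result.mean("auc") >= 0.95

    def test_shuffled_labels_chance_auc(self, cohort):
        rng = np.random.default_rng(0)
        shuffled = cohort.copy()
        for _, idx in shuffled.groupby("subject_id").groups.items():
            shuffled.loc[idx, "label"] = rng.permutation(shuffled.loc[idx, "label"].values)
        result = lopo_cross_validate(shuffled, default_spec("C0", "SVM_10"), seed=0)
        assert 0.4 <= result.mean("auc") <= 0.6

    def test_svm5_runs_with_per_fold_selection(self, cohort):
        result = lopo_cross_validate(cohort, default_spec("C0", "SVM_5"), seed=7)
        assert result.mean("auc") >= 0.9

    def test_svm5_fixed_subset(self, cohort):
        spec = default_spec("C0", "SVM_5")
        spec = ClassifierSpec(variant=spec.variant, model=spec.model,
                              hyperparams=spec.hyperparams,
                              feature_subset=FIXED_TOP5_FEATURES)
        result = lopo_cross_validate(cohort, spec, seed=7)
        assert result.mean("auc") >= 0.9

    def test_detection_beats_prediction(self, cohort):
        det = lopo_cross_validate(cohort, default_spec("C210", "SVM_10"), seed=7)
        pred = lopo_cross_validate(cohort, default_spec("C21", "SVM_10"), seed=7)
        assert det.mean("auc") >= pred.mean("auc")

    def test_single_subject_rejected(self):
        frame = simulate_cohort(n_subjects=2, seed=0, n_phases=10)
        with pytest.raises(FogaitError):
            lopo_cross_validate(frame[frame["subject_id"] == "P01"],
                                default_spec("C0", "SVM_10"))

    def test_no_leakage_from_held_out_labels(self, cohort):
        # the fold model must be bitwise independent of the held-out subject
        spec = default_spec("C0", "SVM_10")
        held_out = "P01"
        X, y, meta = build_design_matrix(cohort, spec.variant)
        train = (meta["subject_id"] != held_out).to_numpy()
        test = ~train
        model_a = train_classifier(X[train], y[train], spec, seed=0)
        corrupted = y.copy()
        corrupted[test] = 1 - corrupted[test]
        model_b = train_classifier(X[train], corrupted[train], spec, seed=0)
        np.testing.assert_array_equal(model_a.decision_function(X[test]),
                                      model_b.decision_function(X[test]))


class TestTTest:
    def test_identical_vectors(self):
        a = np.array([0.9, 0.8, 0.85])
        assert compare_models_ttest(a, a) == 1.0

    def test_constant_difference_degenerates(self):
        a = np.full(16, 0.9)
        b = np.full(16, 0.8)
        with pytest.warns(UserWarning):
            assert compare_models_ttest(a, b) == 0.0

    def test_matches_closed_form(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.9, 0.05, 16)
        b = a - rng.normal(0.05, 0.02, 16)
        p = compare_models_ttest(a, b)
        # hand-rolled paired t statistic
        d = a - b
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        from scipy import stats as sps
        expected = 2 * sps.t.sf(abs(t_stat), d.size - 1)
        assert p == pytest.approx(expected, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(FogaitError):
            compare_models_ttest([0.9], [0.8, 0.7])


class TestBestFoot:
    def _result(self, rows):
        from fogait.fog_classification import EvalResult
        return EvalResult(spec=default_spec("C0", "SVM_10"),
                          frame=pd.DataFrame(rows))

    def test_higher_auc_wins(self):
        res = self._result([
            {"subject_id": "S1", "foot": "left", "auc": 0.9},
            {"subject_id": "S1", "foot": "right", "auc": 0.8},
        ])
        assert select_best_foot(res) == {"S1": "left"}

    def test_tie_resolves_left(self):
        res = self._result([
            {"subject_id": "S1", "foot": "left", "auc": 0.8},
            {"subject_id": "S1", "foot": "right", "auc": 0.8},
        ])
        assert select_best_foot(res) == {"S1": "left"}

    def test_missing_foot_uses_available(self):
        res = self._result([{"subject_id": "S1", "foot": "right", "auc": 0.7}])
        assert select_best_foot(res) == {"S1": "right"}

    def test_best_foot_mean_dominates(self):
        frame = simulate_cohort(n_subjects=6, fog_prevalence=0.5, seed=3,
                                n_phases=20, label_persistence=0.3)
        result = lopo_cross_validate(frame, default_spec("C0", "SVM_10"), seed=3)
        best = select_best_foot(result)
        best_aucs = [
            result.frame[(result.frame["subject_id"] == s)
                         & (result.frame["foot"] == f)]["auc"].iloc[0]
            for s, f in best.items()
        ]
        per_foot = result.frame.groupby("foot")["auc"].mean()
        assert np.mean(best_aucs) >= per_foot.max() - 1e-12


class TestPreakinesiaFraction:
    def _setup(self, labels_for_qualifying):
        episodes = [AnnotatedEpisode(10.0, 12.0, "akinesia", "expert1")]
        # 4 phases ending within [7, 10): qualifying
        phases = [_phase(t) for t in (7.5, 8.2, 9.0, 9.8, 15.0)]
        # mark some qualifying phases as inside a shuffling episode
        for i, flag in enumerate(labels_for_qualifying):
            if flag:
                t = phases[i].t_end
                episodes.append(AnnotatedEpisode(t - 0.1, t + 0.1, "shuffling", "expert1"))
        labels = label_motion_phases(phases, episodes, "OR")
        return labels, phases, episodes

    def test_all_labeled(self):
        labels, phases, episodes = self._setup([1, 1, 1, 1])
        assert preakinesia_fraction(labels, phases, episodes) == 1.0

    def test_none_labeled(self):
        labels, phases, episodes = self._setup([0, 0, 0, 0])
        assert preakinesia_fraction(labels, phases, episodes) == 0.0

    def test_three_of_four(self):
        labels, phases, episodes = self._setup([1, 1, 1, 0])
        assert preakinesia_fraction(labels, phases, episodes) == 0.75

    def test_no_akinesia_returns_none(self):
        episodes = [AnnotatedEpisode(1.0, 2.0, "shuffling", "expert1")]
        assert preakinesia_fraction([1], [_phase(1.5)], episodes) is None
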