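"""Metrics, the stacked ensemble, and pooled out-of-fold evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.datasets import make_classification
from sklearn.ensemble import StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from mpestack.markers import ALL_MARKERS
from mpestack.models import (
    BASE_LEARNER_NAMES,
    StackingDiagnosticClassifier,
    compute_auc,
    cross_validated_evaluate,
    evaluate_panels,
    feature_matrix,
    make_base_learner,
    pooled_oof_scores,
    sens_spec,
    youden_threshold,
)


def pair_count_auc(scores, labels):
    """O(n^2) oracle: (concordant + 0.5 * tied) / (n1 * n0)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert compute_auc([0.3] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_small_example_against_pair_counting(self):
        # both positive-negative pairs (3 vs 1) and (2 vs 1) are concordant
        scores, labels = [3, 1, 2], [1, 0, 1]
        assert compute_auc(scores, labels) == 1.0
        assert pair_count_auc(scores, labels) == 1.0

    def test_matches_pair_count_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.25, 0.5, rng.random()], size=n)
            assert compute_auc(scores, labels) == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_increasing_transform(self, data):
        n = data.draw(st.integers(4, 30))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert compute_auc(scores, labels) == pytest.approx(
            compute_auc(np.exp(scores), labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc([0.1, 0.2], [1, 1])


class TestSensSpec:
    def test_threshold_zero_calls_everything_positive(self):
        se, sp = sens_spec([0.2, 0.9, 0.4], [1, 1, 0], 0.0)
        assert (se, sp) == (1.0, 0.0)

    def test_threshold_above_max_calls_everything_negative(self):
        se, sp = sens_spec([0.2, 0.9, 0.4], [1, 1, 0], 2.0)
        assert (se, sp) == (0.0, 1.0)

    def test_half_half_confusion(self):
        se, sp = sens_spec([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0], 0.5)
        assert (se, sp) == (0.5, 0.5)

    def test_youden_picks_separating_threshold(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        t = youden_threshold(scores, labels)
        assert sens_spec(scores, labels, t) == (1.0, 1.0)


@pytest.fixture(scope="module")
def separable_xy():
    x, y = make_classification(
        n_samples=60,
        n_features=4,
        n_informative=4,
        n_redundant=0,
        class_sep=5.0,
        random_state=0,
    )
    return x, y


class TestStackingEstimator:
    def test_separable_training_auc_is_one(self, separable_xy):
        x, y = separable_xy
        est = StackingDiagnosticClassifier(random_state=0).fit(x, y)
        assert compute_auc(est.predict_proba(x)[:, 1], y) == 1.0
        assert set(est.base_estimators_) == set(BASE_LEARNER_NAMES)
        assert est.oof_meta_features_.shape == (60, 5)
        assert ((est.predict_proba(x) >= 0) & (est.predict_proba(x) <= 1)).all()

    def test_sklearn_estimator_contract(self):
        est = StackingDiagnosticClassifier(inner_folds=4, random_state=3)
        params = est.get_params()
        assert params["inner_folds"] == 4
        est.set_params(inner_folds=2)
        assert est.inner_folds == 2

    def test_matches_sklearn_stacking_cross_check(self, separable_xy):
        """Independent oracle: sklearn's StackingClassifier with the same
        base pipelines, folds and meta-learner gives a near-identical AUC."""
        x, y = make_classification(
            n_samples=240, n_features=6, n_informative=3, flip_y=0.2, random_state=1
        )
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=5)
        ours = StackingDiagnosticClassifier(random_state=5)
        ref = StackingClassifier(
            estimators=[
                (name, make_base_learner(name, random_state=5))
                for name in BASE_LEARNER_NAMES
            ],
            final_estimator=LogisticRegression(max_iter=2000),
            cv=StratifiedKFold(n_splits=3, shuffle=True, random_state=5),
            stack_method="predict_proba",
        )
        auc_ours = compute_auc(
            cross_val_predict(ours, x, y, cv=cv, method="predict_proba")[:, 1], y
        )
        auc_ref = compute_auc(
            cross_val_predict(ref, x, y, cv=cv, method="predict_proba")[:, 1], y
        )
        assert auc_ours == pytest.approx(auc_ref, abs=0.03)

    def test_permuted_labels_give_chance_auc(self, cohort):
        rng = np.random.default_rng(2)
        y = (cohort["group"] == "MPE").astype(int).to_numpy()
        aucs = []
        for _ in range(4):
            scores, yp = pooled_oof_scores(
                cohort,
                ALL_MARKERS,
                model="stacking",
                seed=int(rng.integers(0, 1000)),
                labels=rng.permutation(y),
            )
            aucs.append(compute_auc(scores, yp))
        assert 0.35 <= float(np.mean(aucs)) <= 0.65

    def test_class_starved_inner_fold_fails_loudly(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        y = np.array([1, 1] + [0] * 18)
        with pytest.raises(ValueError, match="stratify"):
            StackingDiagnosticClassifier(inner_folds=3).fit(x, y)


class TestCrossValidatedEvaluate:
    def test_determinism(self, cohort):
        a = cross_validated_evaluate(cohort, ["PE.CEA"], model="logistic", seed=3)
        b = cross_validated_evaluate(cohort, ["PE.CEA"], model="logistic", seed=3)
        assert a == b

    def test_record_fields(self, cohort):
        rec = cross_validated_evaluate(cohort, ["PE.CEA", "PB.CEA"], model="naive_bayes", seed=1)
        assert rec.panel == "PB.CEA+PE.CEA"
        assert rec.n_folds == 3 and rec.seed == 1
        assert 0 <= rec.auc <= 1

    def test_empty_panel_rejected(self, cohort):
        with pytest.raises(ValueError, match="non-empty"):
            cross_validated_evaluate(cohort, [], model="logistic")

    def test_unknown_model_rejected(self, cohort):
        with pytest.raises(ValueError, match="unknown model"):
            cross_validated_evaluate(cohort, ["PE.CEA"], model="gbm")

    def test_leave_one_out_matches_manual_loop(self, toy_cohort):
        panel = ["PE.CEA", "PB.CA19-9"]
        scores, y = pooled_oof_scores(
            toy_cohort, panel, model="logistic", k=len(toy_cohort), seed=0
        )
        x, y2 = feature_matrix(toy_cohort, panel)
        np.testing.assert_array_equal(y, y2)
        manual = np.empty(len(y))
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            est = make_base_learner("logistic")
            est.fit(x.to_numpy()[mask], y[mask])
            manual[i] = est.predict_proba(x.to_numpy()[[i]])[0, 1]
        np.testing.assert_allclose(scores, manual, atol=1e-10)

    def test_oof_scores_never_leak_test_labels(self, toy_cohort):
        """Flipping one held-out label must not move that sample's score."""
        panel = ["PE.CEA"]
        x, y = feature_matrix(toy_cohort, panel)
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        folds = list(cv.split(x, y))
        train_idx, test_idx = folds[0]
        target = test_idx[0]

        def score_of(labels):
            est = make_base_learner("logistic")
            est.fit(x.to_numpy()[train_idx], labels[train_idx])
            return est.predict_proba(x.to_numpy()[[target]])[0, 1]

        flipped = y.copy()
        flipped[target] = 1 - flipped[target]
        assert score_of(y) == pytest.approx(score_of(flipped), abs=1e-12)


class TestEvaluatePanels:
    def test_resume_equals_uninterrupted(self, toy_cohort):
        panels = [("PE.CEA",), ("PB.CEA",), ("PE.CEA", "PB.CEA")]
        full = evaluate_panels(toy_cohort, panels, models=("logistic",), seed=4)
        partial = full.iloc[:1]
        resumed = evaluate_panels(
            toy_cohort, panels, models=("logistic",), seed=4, existing=partial
        )
        pd.testing.assert_frame_equal(full, resumed, check_dtype=False)

    def test_record_count_panels_times_models(self, toy_cohort):
        panels = [("PE.CEA",), ("PB.CEA",)]
        recs = evaluate_panels(
            toy_cohort, panels, models=("logistic", "naive_bayes"), seed=0
        )
        assert len(recs) == 4
        assert recs.loc[recs.panel == "PE.CEA", "cost"].unique().tolist() == [56.5]
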