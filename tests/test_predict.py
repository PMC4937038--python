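"""Prediction routes: metric identities, pipeline contracts, LOOCV mechanics."""

import numpy as np
import pytest

from metaboselect.predict import (
    confusion_metrics,
    logistic_pipeline,
    loocv_probabilities,
    rf_predict_nested,
    varsel_rf,
    _stratified_split,
)
from metaboselect.rankers import ConfusionMatrix
from tests.conftest import make_table


class TestConfusionMetrics:
    def test_identities_on_random_matrices(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 40, size=4))
            report = confusion_metrics(ConfusionMatrix(tp, fp, tn, fn))
            n = tp + fp + tn + fn
            assert report.sensitivity == pytest.approx(tp / (tp + fn))
            assert report.specificity == pytest.approx(tn / (tn + fp))
            assert report.accuracy == pytest.approx((tp + tn) / n)
            assert report.precision == pytest.approx(tp / (tp + fp))
            assert report.misclassification == pytest.approx(1 - (tp + tn) / n)

    def test_balanced_errors_give_half_sensitivity(self):
        report = confusion_metrics(ConfusionMatrix(tp=7, fp=3, tn=5, fn=7))
        assert report.sensitivity == pytest.approx(0.5)

    def test_all_correct(self):
        report = confusion_metrics(ConfusionMatrix(tp=10, fp=0, tn=10, fn=0))
        assert report.accuracy == 1.0
        assert report.misclassification == 0.0

    def test_zero_denominator_is_explicit_none(self):
        report = confusion_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert report.sensitivity is None
        assert report.precision is None
        assert report.specificity == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, tn=0, fn=1)


class TestRfPredictNested:
    def _separable_table(self, rng, n=40, p=8):
        labels = np.where(np.arange(n) < n // 2, 1, -1)
        x = rng.normal(size=(n, p))
        x[:, 0] = labels * 4.0
        return make_table(x, labels=labels)

    def test_perfectly_separable_toy(self, rng):
        table = self._separable_table(rng)
        reports = rf_predict_nested(
            table, table.feature_ids, subset_sizes=[8, 4, 2],
            replications=3, n_trees=50, seed=0,
        )
        assert [r.n_features for r in reports] == [8, 4, 2]
        for r in reports:
            assert r.accuracy == 1.0

    def test_fixed_seed_reproducible(self, rng):
        table = self._separable_table(rng, n=30)
        a = rf_predict_nested(table, table.feature_ids, subset_sizes=[4],
                              replications=1, n_trees=30, seed=9)
        b = rf_predict_nested(table, table.feature_ids, subset_sizes=[4],
                              replications=1, n_trees=30, seed=9)
        assert a[0].confusion == b[0].confusion
        assert a[0].oob_error == b[0].oob_error

    def test_oversize_subset_skipped_with_warning(self, rng):
        table = self._separable_table(rng)
        with pytest.warns(UserWarning, match="skipped"):
            reports = rf_predict_nested(
                table, table.feature_ids[:4], subset_sizes=[48, 2],
                replications=1, n_trees=20, seed=0,
            )
        assert [r.n_features for r in reports] == [2]

    def test_stratified_split_proportions(self, rng):
        labels = np.where(np.arange(111) < 55, 1, -1)
        train = _stratified_split(labels, 0.75, rng)
        assert int(np.sum(train & (labels == 1))) == 41  # round(0.75·55)
        assert int(np.sum(train & (labels == -1))) == 42  # round(0.75·56)


class TestVarselRf:
    def test_recovers_planted_features(self):
        successes = 0
        n_seeds = 4
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n, p = 111, 48
            labels = np.where(np.arange(n) < 55, 1, -1)
            x = r.normal(size=(n, p))
            planted = [0, 1, 2, 3, 4]
            for j in planted:
                x[:, j] += labels * 1.0
            table = make_table(x, labels=labels)
            stable, per_rep = varsel_rf(
                table, table.feature_ids, replications=8, n_trees=100, seed=seed
            )
            planted_ids = {f"f{j}" for j in planted}
            if len(set(stable) & planted_ids) >= 3 and set(stable) <= planted_ids:
                successes += 1
            assert len(per_rep) == 8
        assert successes >= 3

    def test_drop_one_backward_path_on_graded_instance(self):
        """One variable dropped per round: the weakest features fall first and
        the minimum-OOB set keeps the strong pair."""
        r = np.random.default_rng(1)
        n = 60
        labels = np.where(np.arange(n) < n // 2, 1, -1)
        x = r.normal(size=(n, 4)) * 0.3
        x[:, 2] += labels * 2.0
        x[:, 3] += labels * 2.0
        table = make_table(x, labels=labels)
        stable, per_rep = varsel_rf(
            table, table.feature_ids, drop_frac=0.26, replications=2,
            n_trees=80, seed=0,
        )
        assert set(stable) <= {"f2", "f3"}
        assert len(stable) >= 1

    def test_requires_two_features(self, rng):
        table = make_table(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            varsel_rf(table, table.feature_ids[:1])


class TestLogisticPipeline:
    def test_duplicated_informative_columns_pruned_to_one(self, rng):
        n = 60
        labels = np.where(np.arange(n) < n // 2, 1, -1)
        x = rng.normal(size=(n, 6))
        x[:, 0] += labels * 1.5
        x[:, 1] = x[:, 0]  # exact duplicate, r = 1
        table = make_table(x, labels=labels)
        trace = logistic_pipeline(table, table.feature_ids, shortlist=4)
        survivors_dup = {"f0", "f1"} & set(trace.shortlist)
        assert len(survivors_dup) == 1
        # stage-2 postcondition
        if len(trace.shortlist) >= 2:
            cols = [table.feature_ids.index(f) for f in trace.shortlist]
            r = np.abs(np.corrcoef(x[:, cols], rowvar=False))
            np.fill_diagonal(r, 0)
            assert r.max() <= 0.5 + 1e-12

    def test_informative_feature_reaches_final_model(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 80
            labels = np.where(np.arange(n) < n // 2, 1, -1)
            x = r.normal(size=(n, 11))
            x[:, 5] += labels * 1.5
            table = make_table(x, labels=labels)
            trace = logistic_pipeline(table, table.feature_ids, shortlist=5)
            if "f5" in trace.final_terms:
                hits += 1
        assert hits >= n_seeds - 1

    def test_column_order_invariance(self, rng):
        n = 50
        labels = np.where(np.arange(n) < n // 2, 1, -1)
        x = rng.normal(size=(n, 8))
        x[:, 2] += labels * 1.2
        ids = [f"f{j}" for j in range(8)]
        table = make_table(x, labels=labels, feature_ids=ids)
        perm = [5, 2, 7, 0, 1, 6, 3, 4]
        permuted = make_table(x[:, perm], labels=labels, feature_ids=[ids[j] for j in perm])
        a = logistic_pipeline(table, ids, shortlist=4)
        b = logistic_pipeline(permuted, [ids[j] for j in perm], shortlist=4)
        assert set(a.final_terms) == set(b.final_terms)
        assert set(a.shortlist) == set(b.shortlist)

    def test_trace_is_complete(self, rng):
        n = 40
        labels = np.where(np.arange(n) < n // 2, 1, -1)
        x = rng.normal(size=(n, 6))
        x[:, 0] += labels
        table = make_table(x, labels=labels)
        trace = logistic_pipeline(table, table.feature_ids, shortlist=3)
        assert set(trace.univariable_p) == set(table.feature_ids)
        assert set(trace.final_terms) <= set(trace.shortlist)
        assert len(trace.shortlist) <= 3
        assert trace.aic_path[0][0] == "start"


class TestLoocvProbabilities:
    def test_constant_model_gives_equal_probabilities(self, rng):
        table = make_table(rng.normal(size=(10, 3)))

        def const_model(Xtr, ytr):
            return lambda Xte: np.full(len(Xte), 0.3)

        probs = loocv_probabilities(const_model, table, table.feature_ids)
        assert np.allclose(probs, 0.3)

    def test_separable_logistic_probabilities_on_correct_side(self, rng):
        n = 20
        labels = np.where(np.arange(n) < n // 2, 1, -1)
        x = rng.normal(size=(n, 2)) * 0.2
        x[:, 0] += labels * 3.0
        table = make_table(x, labels=labels)
        probs = loocv_probabilities("logistic", table, table.feature_ids)
        assert np.all(probs[labels == 1] > 0.5)
        assert np.all(probs[labels == -1] < 0.5)

    def test_fold_mechanics_match_hand_computation(self):
        """Class-prior model at n=4 (2 pos / 2 neg): leaving out a positive
        leaves a 1/3 positive training prior, and symmetrically 2/3."""
        table = make_table(np.arange(8, dtype=float).reshape(4, 2),
                           labels=np.array([1, 1, -1, -1]))

        def prior_model(Xtr, ytr):
            p = float(np.mean(ytr == 1))
            return lambda Xte: np.full(len(Xte), p)

        probs = loocv_probabilities(prior_model, table, table.feature_ids)
        assert np.allclose(probs, [1 / 3, 1 / 3, 2 / 3, 2 / 3])

    def test_requires_two_per_class(self):
        table = make_table(np.arange(6, dtype=float).reshape(3, 2),
                           labels=np.array([1, -1, -1]))
        with pytest.raises(ValueError):
            loocv_probabilities("logistic", table, table.feature_ids)
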