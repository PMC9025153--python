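"""Splitting, Ward HCA, the four classifiers, CV and report arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from imsferm.classify import (
    ClassifierReport,
    cross_validate,
    evaluate_test,
    format_accuracy,
    format_error_rate,
    hca,
    stratified_split,
    train_classifier,
)


class TestReportArithmetic:
    @pytest.mark.parametrize(
        "m, n, expected",
        [(2, 61, 3.3), (0, 61, 0.0), (1, 61, 1.6), (5, 61, 8.2),
         (3, 61, 4.9), (4, 61, 6.6), (6, 61, 9.8)],
    )
    def test_error_rate_one_decimal(self, m, n, expected):
        assert format_error_rate(m, n) == expected

    @pytest.mark.parametrize(
        "c, n, expected", [(13, 15, 87), (15, 15, 100), (14, 15, 93)]
    )
    def test_accuracy_integer_percent(self, c, n, expected):
        assert format_accuracy(c, n) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            format_error_rate(0, 0)
        with pytest.raises(ValueError):
            format_accuracy(0, 0)

    def test_rounding_identity_exhaustive_small_n(self):
        # half-away-from-zero at one decimal: 10 * rate is within 0.5 of the
        # exact rational 1000*m/n, rounding up at exact halves — checked for
        # every (m, n) with n <= 300 against integer arithmetic
        from fractions import Fraction

        for n in range(1, 301):
            for m in range(n + 1):
                tenths = Fraction(1000 * m, n)
                got = round(format_error_rate(m, n) * 10)
                floor, rem = divmod(1000 * m, n)
                expected = floor + (1 if 2 * rem >= n else 0)
                assert got == expected, (m, n, tenths)

    @settings(derandomize=True, deadline=None, max_examples=300)
    @given(st.integers(1, 10_000), st.data())
    def test_rounding_identity_random_pairs(self, n, data):
        from decimal import ROUND_HALF_UP, Decimal

        m = data.draw(st.integers(0, n))
        expected = float(
            (Decimal(100 * m) / Decimal(n)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        assert format_error_rate(m, n) == expected


class TestStratifiedSplit:
    def test_printed_class_totals_give_61_and_15(self):
        labels = (
            ["yogurt"] * 18 + ["commercial"] * 16 + ["mild"] * 20
            + ["tangy"] * 22
        )
        plan = stratified_split(labels, 0.8, seed=0)
        assert plan.train_indices.size == 61
        assert plan.test_indices.size == 15
        assert sorted(plan.per_class_train.values()) == [13, 14, 16, 18]

    def test_disjoint_and_exhaustive(self):
        labels = ["a"] * 9 + ["b"] * 7
        plan = stratified_split(labels, 0.8, seed=3)
        union = np.union1d(plan.train_indices, plan.test_indices)
        assert np.array_equal(union, np.arange(16))
        assert np.intersect1d(
            plan.train_indices, plan.test_indices
        ).size == 0

    def test_same_seed_same_plan(self):
        labels = ["a"] * 10 + ["b"] * 10
        p1 = stratified_split(labels, 0.8, seed=5)
        p2 = stratified_split(labels, 0.8, seed=5)
        assert np.array_equal(p1.train_indices, p2.train_indices)

    def test_full_fraction_rejected(self):
        with pytest.raises(ValueError, match="empty test"):
            stratified_split(["a"] * 4 + ["b"] * 4, 1.0, seed=0)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(["a", "a", "b"], 0.8, seed=0)


class TestHCA:
    def test_two_points_merge_at_their_distance(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        dg = hca(pts)
        assert dg.heights[0] == pytest.approx(5.0)

    def test_duplicated_point_merges_at_zero(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        dg = hca(pts)
        assert dg.heights[0] == pytest.approx(0.0)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        dg = hca(rng.normal(size=(20, 3)))
        assert (np.diff(dg.heights) >= -1e-12).all()

    def test_four_separated_clusters_recovered(self):
        rng = np.random.default_rng(1)
        centers = np.array(
            [[0.0, 0.0], [50.0, 0.0], [0.0, 50.0], [50.0, 50.0]]
        )
        labels = np.repeat(np.arange(4), 10)
        pts = centers[labels] + rng.normal(scale=0.5, size=(40, 2))
        dg = hca(pts)
        cut = fcluster(dg.merges, t=4, criterion="maxclust")
        assert adjusted_rand_score(labels, cut) == 1.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            hca(np.array([[0.0, np.nan], [1.0, 2.0]]))

    def test_newick_export_contains_all_leaves(self):
        pts = np.array([[0.0], [1.0], [5.0]])
        dg = hca(pts, labels=["x", "y", "z"])
        nwk = dg.to_newick()
        assert nwk.endswith(";")
        for leaf in ("x", "y", "z"):
            assert leaf in nwk


@pytest.fixture()
def separable_scores():
    rng = np.random.default_rng(2)
    centers = np.array(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0],
         [0.0, 0.0, 10.0]]
    )
    labels = np.repeat(["a", "b", "c", "d"], 12)
    X = centers[np.repeat(np.arange(4), 12)] + rng.normal(
        scale=0.3, size=(48, 3)
    )
    return X, labels


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["lda", "knn5", "svm", "plsda"])
    def test_zero_training_errors_when_separable(
        self, kind, separable_scores
    ):
        X, labels = separable_scores
        model = train_classifier(kind, X, labels, n_components=3)
        assert (model.predict(X) == labels).all()

    def test_knn_single_point_per_class(self):
        X = np.array([[0.0], [10.0], [20.0]])
        y = np.array(["a", "b", "c"])
        model = train_classifier("knn5", X, y)  # k clipped to 3 available
        assert (model.predict(X) == y).all()

    def test_knn_tie_broken_by_decrementing_k(self):
        # with k=4 the vote is 2-2; at k=3 class 'a' wins 2-1
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array(["a", "b", "a", "b"])
        model = train_classifier("knn5", X, y, k=4)
        assert model.predict(np.array([[0.0]]))[0] == "a"

    def test_plsda_exact_on_one_hot_recoverable_data(self):
        X = np.eye(4)[np.repeat(np.arange(4), 3)][:, :3]
        y = np.repeat(["a", "b", "c", "d"], 3)
        model = train_classifier("plsda", X, y, n_components=3)
        assert (model.predict(X) == y).all()

    def test_fewer_rows_than_classes_rejected(self):
        with pytest.raises(ValueError, match="fewer training rows"):
            train_classifier(
                "knn5", np.zeros((2, 2)), np.array(["a", "b", "c"])
            )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            train_classifier("forest", np.zeros((4, 2)), ["a", "a", "b", "b"])


class TestCrossValidate:
    def test_perfectly_separable_scores_give_zero_error(
        self, separable_scores
    ):
        X, labels = separable_scores
        for kind in ("lda", "knn5", "svm", "plsda"):
            mis, fields = cross_validate(
                kind, X, labels, folds=8, seed=1, n_components=3
            )
            assert mis == 0
            assert fields["cv_error_pct"] == 0.0

    def test_permutation_null_error_near_three_quarters(self):
        # 4 balanced classes with shuffled labels: expect ~75% CV error
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        rates = []
        for seed in range(20):
            labels = np.repeat(["a", "b", "c", "d"], 10)
            rng.shuffle(labels)
            mis, _ = cross_validate("lda", X, labels, folds=5, seed=seed)
            rates.append(100.0 * mis / 40)
        assert np.mean(rates) == pytest.approx(75.0, abs=10.0)

    def test_same_seed_identical_outcome(self, separable_scores):
        X, labels = separable_scores
        a = cross_validate("knn5", X, labels, folds=6, seed=4)
        b = cross_validate("knn5", X, labels, folds=6, seed=4)
        assert a == b

    def test_too_few_folds_rejected(self, separable_scores):
        X, labels = separable_scores
        with pytest.raises(ValueError, match="folds"):
            cross_validate("lda", X, labels, folds=1, seed=0)

    def test_relaxed_stratification_warns(self, caplog):
        import logging

        X = np.arange(10.0).reshape(-1, 1)
        labels = np.array(["a"] * 8 + ["b"] * 2)
        with caplog.at_level(logging.WARNING, logger="imsferm.classify"):
            cross_validate("knn5", X, labels, folds=4, seed=0)
        assert "stratification relaxed" in caplog.text


class TestReports:
    def test_report_enforces_rounding_identities(self):
        report = ClassifierReport(
            method="lda", feature_source="pca", n_components=4,
            cv_folds=10, cv_misclassified=2, cv_total=61, cv_error_pct=3.3,
            test_correct=13, test_total=15, test_accuracy_pct=87,
        )
        assert report.to_dict()["cv_error_pct"] == 3.3
        with pytest.raises(AssertionError):
            ClassifierReport(
                method="lda", feature_source="pca", n_components=4,
                cv_folds=10, cv_misclassified=2, cv_total=61,
                cv_error_pct=3.2,  # inconsistent with 2/61
                test_correct=13, test_total=15, test_accuracy_pct=87,
            )

    def test_evaluate_test_counts(self, separable_scores):
        X, labels = separable_scores
        model = train_classifier("lda", X, labels)
        fields = evaluate_test(model, X, labels)
        assert fields["test_correct"] == fields["test_total"]
        assert fields["test_accuracy_pct"] == 100
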