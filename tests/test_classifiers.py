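import numpy as np
import pytest
from scipy import stats

from enosemi import (
    ClassifierSpec,
    FeatureMatrix,
    PredictionSet,
    accuracy,
    bayes_net_classify,
    classify,
    compute_rbf_gamma,
    cost_series,
    knn_classify,
    margin_classify,
    mi_ml_classify,
    mlp_classify,
)
from enosemi.classifiers import (
    DegenerateDistancesError,
    InvalidKError,
    InvalidParametersError,
    LengthMismatchError,
    UnknownStructureError,
    default_knn_k,
)
from enosemi.mi_estimation import preprocess_for_mi


def gaussian_blobs(n_per_class, centers, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for c, center in enumerate(centers):
        xs.append(rng.normal(center, sd, size=(n_per_class, len(center))))
        ys.append(np.full(n_per_class, c))
    return FeatureMatrix(values=np.vstack(xs), labels=np.concatenate(ys))


class TestAccuracy:
    @pytest.mark.parametrize("correct,total,expected", [(20, 20, 1.0), (0, 20, 0.0), (18, 20, 0.9)])
    def test_fraction_correct(self, correct, total, expected):
        truth = np.zeros(total, dtype=int)
        preds = np.concatenate([np.zeros(correct, dtype=int), np.ones(total - correct, dtype=int)])
        assert accuracy(PredictionSet(predictions=preds), truth) == expected

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            accuracy(PredictionSet(predictions=np.zeros(3)), np.zeros(4))


class TestCostSeries:
    def test_nine_fourfold_values_ending_at_65536(self):
        series = cost_series()
        assert len(series) == 9
        assert series[:3] == [1, 4, 16]
        assert series[-1] == 65536
        assert all(b / a == 4 for a, b in zip(series, series[1:]))


class TestKnn:
    def test_default_k_is_per_class_training_count(self):
        labels = np.repeat(np.arange(20), 9)  # 180 train rows, 20 classes
        assert default_knn_k(labels) == 9

    def test_exact_training_point_with_k1(self):
        train = gaussian_blobs(10, [(0, 0), (5, 5)], seed=1)
        test = FeatureMatrix(values=train.values[[3, 15]])
        pred = knn_classify(train, test, k=1)
        np.testing.assert_array_equal(pred.predictions, train.labels[[3, 15]])

    def test_majority_vote_hand_case(self):
        # 5 x class A at distance ~2, 4 x class B at distance ~1: with k=9 the
        # majority (A) wins even though B members are nearer
        values = np.concatenate([np.full(5, 2.0), np.full(4, 1.0)])[:, None]
        labels = np.array(["A"] * 5 + ["B"] * 4)
        train = FeatureMatrix(values=values, labels=labels)
        pred = knn_classify(train, FeatureMatrix(values=np.array([[0.0]])), k=9)
        assert pred.predictions[0] == "A"

    def test_vote_tie_broken_by_nearest_member(self):
        values = np.array([[1.0], [3.0], [2.0], [4.0]])
        labels = np.array(["A", "A", "B", "B"])
        train = FeatureMatrix(values=values, labels=labels)
        pred = knn_classify(train, FeatureMatrix(values=np.array([[0.0]])), k=4)
        assert pred.predictions[0] == "A"  # nearest single member is A at 1.0

    def test_invalid_k(self):
        train = gaussian_blobs(5, [(0,), (3,)])
        with pytest.raises(InvalidKError):
            knn_classify(train, train, k=11)


class TestMiMl:
    def test_matches_gaussian_bayes_rule_on_separated_classes(self):
        train = preprocess_for_mi(gaussian_blobs(500, [(0.0,), (3.0,)], seed=2), seed=0)
        rng = np.random.default_rng(3)
        q_labels = rng.integers(0, 2, 400)
        q = np.where(q_labels == 0, rng.normal(0, 1, 400), rng.normal(3, 1, 400))[:, None]
        # queries standardised with the training statistics
        raw = gaussian_blobs(500, [(0.0,), (3.0,)], seed=2).values
        qs = (q - raw.mean()) / raw.std()
        pred = mi_ml_classify(train, FeatureMatrix(values=qs), k=4)
        bayes = (qs.ravel() > (0 + 3) / 2 / raw.std() - raw.mean() / raw.std()).astype(int)
        agreement = np.mean(pred.predictions == bayes)
        assert agreement >= 0.95

    def test_single_class_training_predicts_that_class(self):
        train = FeatureMatrix(values=np.random.default_rng(0).normal(size=(20, 2)),
                              labels=np.full(20, "only"))
        pred = mi_ml_classify(train, FeatureMatrix(values=np.zeros((5, 2))), k=3)
        assert all(p == "only" for p in pred.predictions)

    def test_chance_level_on_uninformative_features(self):
        rng = np.random.default_rng(4)
        n_classes, n = 20, 1000
        train = FeatureMatrix(values=rng.normal(size=(n, 2)),
                              labels=rng.permutation(np.repeat(np.arange(n_classes), n // n_classes)))
        test_vals = rng.normal(size=(800, 2))
        truth = rng.integers(0, n_classes, 800)
        pred = mi_ml_classify(preprocess_for_mi(train, 0), FeatureMatrix(values=test_vals), k=4)
        acc = np.mean(pred.predictions == truth)
        lo, hi = stats.binom.interval(0.99, 800, 1 / n_classes)
        assert lo / 800 <= acc <= hi / 800


class TestBayesNet:
    def test_separated_gaussians_classified_accurately(self):
        train = gaussian_blobs(50, [(0, 0), (6, 0), (0, 6)], seed=5)
        test = gaussian_blobs(50, [(0, 0), (6, 0), (0, 6)], seed=6)
        for structure in ("naive", "time_chain"):
            pred = bayes_net_classify(train, test, structure=structure)
            assert accuracy(pred, test.labels) > 0.95

    def test_symmetric_classes_tie_break_to_smallest(self):
        values = np.array([[0.0], [1.0], [0.0], [1.0]])
        train = FeatureMatrix(values=values, labels=np.array([0, 0, 1, 1]))
        pred = bayes_net_classify(train, FeatureMatrix(values=np.array([[0.5]])), "naive")
        assert pred.predictions[0] == 0

    def test_time_chain_matches_naive_without_cross_time_dependence(self):
        rng = np.random.default_rng(7)
        n = 400
        labels = rng.integers(0, 4, n)
        # two sensors x two times, independent given the class
        values = rng.normal(size=(n, 4)) + 2.5 * labels[:, None]
        cols = [(1, 1), (1, 2), (2, 1), (2, 2)]
        train = FeatureMatrix(values=values[:300], column_index=cols, labels=labels[:300])
        test = FeatureMatrix(values=values[300:], column_index=cols, labels=labels[300:])
        naive = bayes_net_classify(train, test, "naive").predictions
        chain = bayes_net_classify(train, test, "time_chain").predictions
        assert np.mean(naive == chain) >= 0.99

    def test_unknown_structure_rejected(self):
        train = gaussian_blobs(5, [(0,), (3,)])
        with pytest.raises(UnknownStructureError):
            bayes_net_classify(train, train, structure="loopy")


class TestMargin:
    def test_separable_data_fit_perfectly_at_large_cost(self):
        train = gaussian_blobs(20, [(0, 0), (10, 10)], seed=8, sd=0.5)
        pred = margin_classify(train, train, cost=65536.0, kernel="linear")
        assert accuracy(pred, train.labels) == 1.0

    def test_conflicting_duplicate_rows_do_not_crash(self):
        values = np.zeros((10, 2))
        labels = np.array([0, 1] * 5)
        train = FeatureMatrix(values=values, labels=labels)
        pred = margin_classify(train, train)
        assert len(pred.predictions) == 10

    @pytest.mark.parametrize(
        "mode,expected", [("inv_n_features", 1 / 12)]
    )
    def test_gamma_inverse_feature_count(self, mode, expected):
        train = FeatureMatrix(values=np.random.default_rng(0).normal(size=(30, 12)))
        assert compute_rbf_gamma(train, mode) == expected

    def test_gamma_inverse_median_distance(self):
        # three collinear equidistant points: all pairwise distances 2 except one
        train = FeatureMatrix(values=np.array([[0.0], [2.0]]))
        assert compute_rbf_gamma(train, "inv_median") == 0.5

    def test_gamma_degenerate_distances(self):
        train = FeatureMatrix(values=np.zeros((3, 2)))
        with pytest.raises(DegenerateDistancesError):
            compute_rbf_gamma(train, "inv_q90")

    def test_rbf_kernel_runs(self):
        train = gaussian_blobs(20, [(0, 0), (4, 4)], seed=9)
        pred = margin_classify(train, train, kernel="rbf", gamma_mode="inv_median")
        assert accuracy(pred, train.labels) > 0.9


class TestMlp:
    def test_xor_capacity(self):
        rng = np.random.default_rng(10)
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        values = np.repeat(base, 40, axis=0) + rng.normal(0, 0.05, size=(160, 2))
        labels = np.repeat([0, 1, 1, 0], 40)
        train = FeatureMatrix(values=values, labels=labels)
        pred = mlp_classify(train, train, hidden_units=12, seed=0)
        assert accuracy(pred, labels) > 0.9

    def test_same_seed_identical_predictions(self):
        train = gaussian_blobs(30, [(0, 0), (2, 2), (4, 0)], seed=11)
        test = gaussian_blobs(10, [(0, 0), (2, 2), (4, 0)], seed=12)
        a = mlp_classify(train, test, seed=3).predictions
        b = mlp_classify(train, test, seed=3).predictions
        np.testing.assert_array_equal(a, b)

    def test_zero_iterations_rejected(self):
        train = gaussian_blobs(10, [(0,), (3,)])
        with pytest.raises(InvalidParametersError):
            mlp_classify(train, train, max_iter=0)


class TestSuiteProperties:
    @pytest.mark.parametrize(
        "spec",
        [
            ClassifierSpec.make("mi_ml", k=3),
            ClassifierSpec.make("knn"),
            ClassifierSpec.make("bayes_net", structure="naive"),
            ClassifierSpec.make("margin"),
            ClassifierSpec.make("mlp", max_iter=50),
        ],
        ids=lambda s: s.kind,
    )
    def test_chance_level_on_permuted_labels(self, spec):
        rng = np.random.default_rng(20)
        n_classes, n_train, n_test = 4, 200, 400
        train = FeatureMatrix(
            values=rng.normal(size=(n_train, 3)),
            column_index=[(1, 1), (1, 2), (2, 1)],
            labels=rng.permutation(np.repeat(np.arange(n_classes), n_train // n_classes)),
        )
        test = FeatureMatrix(values=rng.normal(size=(n_test, 3)),
                             column_index=train.column_index)
        truth = rng.integers(0, n_classes, n_test)
        pred = classify(spec, train, test)
        acc = np.mean(pred.predictions == truth)
        lo, hi = stats.binom.interval(0.995, n_test, 1 / n_classes)
        assert lo / n_test <= acc <= hi / n_test

    def test_dispatch_rejects_unknown_kind(self):
        with pytest.raises(InvalidParametersError):
            ClassifierSpec.make("forest")
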