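"""The five classifier families used to evaluate selected feature sets.

* ``mi_ml_classify`` — the bespoke pointwise-MI maximum-likelihood
  classifier: predict the class maximising the nearest-neighbour estimate
  of i(x; c) = log p(x|c)/p(x), which under equiprobable class priors is a
  maximum-likelihood rule.
* ``knn_classify`` — majority vote among the k Euclidean-nearest training
  points, with k conventionally set to the per-class training count (the
  most any single class can contribute to a neighbourhood).
* ``bayes_net_classify`` — Gaussian Bayes networks: the naive structure
  (class is parent to every feature) and a ``time_chain`` modification in
  which each feature additionally has as parent the same sensor's feature
  at the previous selected time point, with linear-Gaussian conditionals.
* ``margin_classify`` — a soft-margin max-margin classifier (adapter over
  sklearn's SVC); the conventional reporting cost is 65536, the last of
  nine cost values starting at 1 and increasing fourfold.
* ``mlp_classify`` — a multilayer perceptron (adapter over sklearn's
  MLPClassifier): 12 hidden units, quasi-Newton (L-BFGS) optimisation,
  at most 100 iterations.

All classifiers are deterministic given (data, parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .dataset_io import FeatureMatrix
from .mi_estimation import DEFAULT_K, local_mi_scores

VARIANCE_FLOOR = 1e-9

#: The nine soft-margin cost values tested: 1, 4, 16, ..., 65536.
def cost_series(start: float = 1.0, factor: float = 4.0, n: int = 9) -> list[float]:
    return [start * factor**i for i in range(n)]


DEFAULT_COST = cost_series()[-1]  # 65536


class ClassifierError(RuntimeError):
    pass


class InvalidKError(ValueError):
    pass


class InvalidParametersError(ValueError):
    pass


class UnknownStructureError(ValueError):
    pass


class DegenerateDistancesError(ValueError):
    pass


class LengthMismatchError(ValueError):
    pass


@dataclass
class PredictionSet:
    """Predicted class per test sample, with optional per-class scores."""

    predictions: np.ndarray
    classes: np.ndarray | None = None
    scores: np.ndarray | None = None  # (n_test, n_classes)


@dataclass(frozen=True)
class ClassifierSpec:
    """A serialisable description of one classifier configuration."""

    kind: str  # mi_ml | knn | bayes_net | margin | mlp
    parameters: tuple = field(default_factory=tuple)  # sorted (key, value) pairs
    seed: int = 0

    def __post_init__(self):
        valid = {"mi_ml", "knn", "bayes_net", "margin", "mlp"}
        if self.kind not in valid:
            raise InvalidParametersError(f"unknown classifier kind {self.kind!r}")
        object.__setattr__(self, "parameters", tuple(sorted(dict(self.parameters).items())))

    @property
    def params(self) -> dict:
        return dict(self.parameters)

    @classmethod
    def make(cls, kind: str, seed: int = 0, **params) -> "ClassifierSpec":
        return cls(kind=kind, parameters=tuple(params.items()), seed=seed)


def _check_matrix(fm: FeatureMatrix, need_labels: bool):
    values = np.asarray(fm.values, dtype=float)
    labels = fm.labels
    if need_labels and labels is None:
        raise InvalidParametersError("training matrix must carry labels")
    return values, (np.asarray(labels) if labels is not None else None)


def accuracy(pred: PredictionSet, truth) -> float:
    """Fraction of correct predictions."""
    predictions = np.asarray(pred.predictions)
    truth = np.asarray(truth)
    if predictions.shape[0] != truth.shape[0]:
        raise LengthMismatchError(
            f"{predictions.shape[0]} predictions vs {truth.shape[0]} labels"
        )
    return float(np.mean(predictions == truth))


# ---------------------------------------------------------------------------
# pointwise-MI maximum likelihood


def mi_ml_classify(train: FeatureMatrix, test: FeatureMatrix, k: int = DEFAULT_K) -> PredictionSet:
    """Predict the class with maximal pointwise mutual information.

    Equiprobable class priors are assumed (the pointwise-MI argmax is then
    the maximum-likelihood class).  Ties break to the smallest class index.
    """
    scores = local_mi_scores(train, test, k=k)
    return PredictionSet(
        predictions=scores.argmax_class(),
        classes=scores.classes,
        scores=scores.scores,
    )


# ---------------------------------------------------------------------------
# k nearest neighbours


def default_knn_k(train_labels) -> int:
    """The per-class training count: the most any class can contribute to a
    neighbourhood (e.g. 180 training samples / 20 classes -> k = 9)."""
    _, counts = np.unique(np.asarray(train_labels), return_counts=True)
    return int(counts.min())


def knn_classify(train: FeatureMatrix, test: FeatureMatrix, k: int | None = None) -> PredictionSet:
    """Majority class among the k Euclidean-nearest training points.

    Vote ties break to the tied class owning the single nearest neighbour.
    """
    X, y = _check_matrix(train, need_labels=True)
    Q, _ = _check_matrix(test, need_labels=False)
    if k is None:
        k = default_knn_k(y)
    if not 1 <= k <= X.shape[0]:
        raise InvalidKError(f"k={k} outside 1..{X.shape[0]}")
    classes = np.unique(y)
    # (n_test, n_train) squared Euclidean distances
    d2 = ((Q[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    preds = np.empty(Q.shape[0], dtype=y.dtype)
    for i in range(Q.shape[0]):
        order = np.argsort(d2[i], kind="stable")[:k]
        votes = y[order]
        cls, counts = np.unique(votes, return_counts=True)
        top = cls[counts == counts.max()]
        if top.size == 1:
            preds[i] = top[0]
        else:
            # nearest single member among the tied classes
            for j in order:
                if y[j] in top:
                    preds[i] = y[j]
                    break
    return PredictionSet(predictions=preds, classes=classes)


# ---------------------------------------------------------------------------
# Gaussian Bayes networks


def bayes_net_classify(
    train: FeatureMatrix, test: FeatureMatrix, structure: str = "time_chain"
) -> PredictionSet:
    """Gaussian Bayes-network classification.

    ``naive``: class is parent to every feature; features are
    conditionally independent Gaussians given the class.  ``time_chain``:
    each feature whose sensor has an earlier selected time point
    additionally has that earlier feature as a parent, with a per-class
    linear-Gaussian conditional.  Prediction is the posterior argmax with
    empirical class priors; a variance floor of 1e-9 guards against
    degenerate fits.  Ties break to the smallest class index.
    """
    if structure not in ("naive", "time_chain"):
        raise UnknownStructureError(f"unknown structure {structure!r}")
    X, y = _check_matrix(train, need_labels=True)
    Q, _ = _check_matrix(test, need_labels=False)
    classes = np.unique(y)
    n, f = X.shape

    # parent column per feature (time_chain): previous time point, same sensor
    parents = [None] * f
    if structure == "time_chain" and train.column_index:
        pos = {col: j for j, col in enumerate(train.column_index)}
        by_sensor: dict[int, list] = {}
        for s, t in train.column_index:
            by_sensor.setdefault(s, []).append(t)
        for s, times in by_sensor.items():
            times = sorted(times)
            for prev_t, t in zip(times[:-1], times[1:]):
                parents[pos[(s, t)]] = pos[(s, prev_t)]

    log_post = np.zeros((Q.shape[0], classes.size))
    for ci, c in enumerate(classes):
        rows = X[y == c]
        if rows.shape[0] < 2:
            raise InvalidParametersError(f"class {c!r} needs >= 2 training samples")
        ll = np.log(rows.shape[0] / n)  # empirical prior
        total = np.full(Q.shape[0], ll)
        for j in range(f):
            xj = rows[:, j]
            if parents[j] is None:
                mu = xj.mean()
                var = max(xj.var(), VARIANCE_FLOOR)
                total += -0.5 * (np.log(2 * np.pi * var) + (Q[:, j] - mu) ** 2 / var)
            else:
                xp = rows[:, parents[j]]
                vp = xp.var()
                if vp <= VARIANCE_FLOOR:
                    slope = 0.0
                else:
                    slope = np.cov(xp, xj, bias=True)[0, 1] / vp
                intercept = xj.mean() - slope * xp.mean()
                resid = xj - (slope * xp + intercept)
                var = max(resid.var(), VARIANCE_FLOOR)
                mu_q = slope * Q[:, parents[j]] + intercept
                total += -0.5 * (np.log(2 * np.pi * var) + (Q[:, j] - mu_q) ** 2 / var)
        log_post[:, ci] = total
    preds = classes[np.argmax(log_post, axis=1)]
    return PredictionSet(predictions=preds, classes=classes, scores=log_post)


# ---------------------------------------------------------------------------
# max-margin and MLP adapters


def compute_rbf_gamma(train: FeatureMatrix, mode: str) -> float:
    """Gaussian-kernel width by rule: inverse feature count, or the inverse
    of the 0.1/0.5/0.9 quantile of pairwise training distances."""
    X, _ = _check_matrix(train, need_labels=False)
    if mode == "inv_n_features":
        return 1.0 / X.shape[1]
    quantiles = {"inv_q10": 0.1, "inv_median": 0.5, "inv_q90": 0.9}
    if mode not in quantiles:
        raise InvalidParametersError(f"unknown gamma mode {mode!r}")
    d = pdist(X)
    q = float(np.quantile(d, quantiles[mode])) if d.size else 0.0
    if q == 0.0:
        raise DegenerateDistancesError("pairwise distance quantile is zero")
    return 1.0 / q


def margin_classify(
    train: FeatureMatrix,
    test: FeatureMatrix,
    cost: float = DEFAULT_COST,
    kernel: str = "linear",
    gamma_mode: str = "inv_n_features",
) -> PredictionSet:
    """Multiclass soft-margin classification (SVC adapter)."""
    X, y = _check_matrix(train, need_labels=True)
    Q, _ = _check_matrix(test, need_labels=False)
    if kernel not in ("linear", "rbf"):
        raise InvalidParametersError(f"unknown kernel {kernel!r}")
    kwargs = {"C": cost, "kernel": kernel}
    if kernel == "rbf":
        kwargs["gamma"] = compute_rbf_gamma(train, gamma_mode)
    try:
        model = SVC(**kwargs)
        model.fit(X, y)
        preds = model.predict(Q)
    except Exception as exc:  # adapter failures surfaced uniformly
        raise ClassifierError(f"margin classifier failed: {exc}") from exc
    return PredictionSet(predictions=preds, classes=np.unique(y))


def mlp_classify(
    train: FeatureMatrix,
    test: FeatureMatrix,
    hidden_units: int = 12,
    max_iter: int = 100,
    optimiser: str = "lbfgs",
    seed: int = 0,
) -> PredictionSet:
    """Multilayer-perceptron classification (MLPClassifier adapter).

    Defaults follow the conventional e-nose configuration: one hidden layer
    of 12 units trained by quasi-Newton (L-BFGS) optimisation for at most
    100 iterations, with seeded initialisation.
    """
    if max_iter < 1 or hidden_units < 1:
        raise InvalidParametersError("hidden_units and max_iter must be >= 1")
    X, y = _check_matrix(train, need_labels=True)
    Q, _ = _check_matrix(test, need_labels=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = MLPClassifier(
                hidden_layer_sizes=(hidden_units,),
                solver=optimiser,
                max_iter=max_iter,
                random_state=seed,
            )
            model.fit(X, y)
            preds = model.predict(Q)
    except Exception as exc:
        raise ClassifierError(f"mlp classifier failed: {exc}") from exc
    return PredictionSet(predictions=preds, classes=np.unique(y))


# ---------------------------------------------------------------------------
# dispatch


def classify(spec: ClassifierSpec, train: FeatureMatrix, test: FeatureMatrix) -> PredictionSet:
    """Run the classifier described by ``spec`` on a train/test pair."""
    p = spec.params
    if spec.kind == "mi_ml":
        return mi_ml_classify(train, test, k=p.get("k", DEFAULT_K))
    if spec.kind == "knn":
        return knn_classify(train, test, k=p.get("k"))
    if spec.kind == "bayes_net":
        return bayes_net_classify(train, test, structure=p.get("structure", "time_chain"))
    if spec.kind == "margin":
        return margin_classify(
            train,
            test,
            cost=p.get("cost", DEFAULT_COST),
            kernel=p.get("kernel", "linear"),
            gamma_mode=p.get("gamma_mode", "inv_n_features"),
        )
    if spec.kind == "mlp":
        return mlp_classify(
            train,
            test,
            hidden_units=p.get("hidden_units", 12),
            max_iter=p.get("max_iter", 100),
            optimiser=p.get("optimiser", "lbfgs"),
            seed=spec.seed,
        )
    raise InvalidParametersError(f"unknown classifier kind {spec.kind!r}")


def default_classifier_suite(seed: int = 0) -> list[ClassifierSpec]:
    """One spec per family, at the conventional reporting configuration."""
    return [
        ClassifierSpec.make("margin", seed=seed, cost=DEFAULT_COST, kernel="linear"),
        ClassifierSpec.make("knn", seed=seed),
        ClassifierSpec.make("bayes_net", seed=seed, structure="time_chain"),
        ClassifierSpec.make("mlp", seed=seed, hidden_units=12, max_iter=100),
        ClassifierSpec.make("mi_ml", seed=seed, k=DEFAULT_K),
    ]
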