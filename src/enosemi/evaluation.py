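"""The experimental protocol: repeated balanced cross-validation with
per-split feature selection, random-feature baselines, the repeats t-test
and weighted performance reports.

Protocol, per split of a repeated balanced k-fold CV: the max-MI feature
set is selected on the *training* folds only, the selected features are
extracted from both folds, each classifier is fit on the training features
and scored on the test features.  The random baseline draws feature sets
uniformly from the same constrained candidate space and evaluates them on
the same CV splits (the j-th random set is assigned to split j mod
n_splits), so the MI-vs-random contrast is measured under identical
partitions.

The significance test is the two-sample statistic

    t = (m1 - m2) / sqrt((s1^2 + s2^2) / n),    df = 2n - 2

with n the number of CV *repetitions*: per-split accuracies are averaged
within each repetition before testing, so each group contributes n
(approximately independent) values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import ClassifierSpec, accuracy, classify
from .dataset_io import FeatureSet, SensorArrayDataset, extract_features
from .feature_selection import (
    EstimatorSettings,
    SelectionResult,
    SizeConstraint,
    enumerate_feature_sets,
    select_max_mi,
)


class UnbalancedClassesError(ValueError):
    pass


class MissingPerformanceForSetError(KeyError):
    pass


@dataclass(frozen=True)
class CVSplit:
    """One train/test partition of a repeated balanced k-fold CV."""

    repetition: int  # 1-based
    fold: int  # 1-based
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]

    @property
    def split_id(self) -> str:
        return f"r{self.repetition:02d}f{self.fold:02d}"


def make_cv_splits(labels, n_folds: int = 10, n_repeats: int = 10, seed: int = 0):
    """Balanced repeated k-fold splits.

    Within each repetition every class's samples are shuffled and dealt
    evenly into the folds, so each fold's test set holds the same number of
    samples of every class and the folds of one repetition partition the
    dataset.  Every class count must be divisible by ``n_folds``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for c, cnt in zip(classes, counts):
        if cnt < n_folds or cnt % n_folds != 0:
            raise UnbalancedClassesError(
                f"class {c!r} has {cnt} samples; needs a positive multiple of "
                f"{n_folds} for balanced {n_folds}-fold CV"
            )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCF]))
    splits = []
    all_idx = np.arange(labels.shape[0])
    for rep in range(1, n_repeats + 1):
        fold_members: list[list[int]] = [[] for _ in range(n_folds)]
        for c in classes:
            idx = all_idx[labels == c]
            perm = rng.permutation(idx)
            for f, chunk in enumerate(np.array_split(perm, n_folds)):
                fold_members[f].extend(int(i) for i in chunk)
        for f in range(n_folds):
            test = np.array(sorted(fold_members[f]), dtype=int)
            mask = np.ones(labels.shape[0], dtype=bool)
            mask[test] = False
            splits.append(
                CVSplit(
                    repetition=rep,
                    fold=f + 1,
                    train_indices=tuple(all_idx[mask]),
                    test_indices=tuple(test),
                )
            )
    return splits


def random_baseline(
    constraint: SizeConstraint,
    n_sensors_total: int,
    n_times_total: int,
    n_random: int = 100,
    seed: int = 0,
) -> list[FeatureSet]:
    """Draw feature sets uniformly from the constrained candidate space.

    Drawn without replacement when enough candidates exist, with
    replacement otherwise.
    """
    if not isinstance(constraint, SizeConstraint):
        constraint = SizeConstraint(*constraint)
    candidates = list(enumerate_feature_sets(constraint, n_sensors_total, n_times_total))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA5E]))
    replace = len(candidates) < n_random
    picks = rng.choice(len(candidates), size=n_random, replace=replace)
    return [candidates[i] for i in picks]


@dataclass
class EvaluationResult:
    """Long-format accuracy table plus the per-split selections."""

    performance: pd.DataFrame  # constraint, classifier, repetition, fold, mode, accuracy
    selections: list[SelectionResult] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean/sd/count per (constraint, classifier), MI arm vs pooled random arm."""
        perf = self.performance
        group = "mode_group" if "mode_group" in perf.columns else "mode"
        return (
            perf.groupby(["constraint", "classifier", group])["accuracy"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


def run_selection_evaluation(
    dataset: SensorArrayDataset,
    constraints,
    classifier_specs: list[ClassifierSpec],
    settings: EstimatorSettings | None = None,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    n_random: int = 100,
    splits=None,
) -> EvaluationResult:
    """Per-split max-MI selection and classification, plus random baselines.

    For each CV split and constraint: select the max-MI feature set on the
    training folds, fit every classifier on the selected training features
    and record its test accuracy (mode ``mi``).  Each of ``n_random``
    uniformly drawn feature sets per constraint is evaluated on one split,
    round-robin (mode ``random``).  Set ``n_random=0`` to skip the
    baseline arm.
    """
    settings = settings or EstimatorSettings(seed=seed)
    if splits is None:
        splits = make_cv_splits(dataset.class_labels, n_folds, n_repeats, seed=seed)
    constraints = [
        c if isinstance(c, SizeConstraint) else SizeConstraint(*c) for c in constraints
    ]

    records = []
    selections: list[SelectionResult] = []
    for constraint in constraints:
        # MI arm: select on training folds only, then classify
        for split in splits:
            train_ds = dataset.subset(list(split.train_indices))
            test_ds = dataset.subset(list(split.test_indices))
            sel = select_max_mi(train_ds, constraint, settings, split_id=split.split_id)
            selections.append(sel)
            train_fm = extract_features(train_ds, sel.feature_set)
            test_fm = extract_features(test_ds, sel.feature_set)
            for spec in classifier_specs:
                pred = classify(spec, train_fm, test_fm)
                records.append(
                    {
                        "constraint": str(constraint),
                        "classifier": spec.kind,
                        "repetition": split.repetition,
                        "fold": split.fold,
                        "mode": "mi",
                        "feature_set": _fs_key(sel.feature_set),
                        "n_ties": sel.n_ties,
                        "accuracy": accuracy(pred, test_fm.labels),
                    }
                )
        # random arm: same splits, uniformly drawn sets, round-robin
        if n_random > 0:
            random_sets = random_baseline(
                constraint, dataset.n_sensors, dataset.n_times, n_random, seed=seed
            )
            for j, fs in enumerate(random_sets):
                split = splits[j % len(splits)]
                train_ds = dataset.subset(list(split.train_indices))
                test_ds = dataset.subset(list(split.test_indices))
                train_fm = extract_features(train_ds, fs)
                test_fm = extract_features(test_ds, fs)
                for spec in classifier_specs:
                    pred = classify(spec, train_fm, test_fm)
                    records.append(
                        {
                            "constraint": str(constraint),
                            "classifier": spec.kind,
                            "repetition": split.repetition,
                            "fold": split.fold,
                            "mode": f"random:{j}",
                            "feature_set": _fs_key(fs),
                            "n_ties": 0,
                            "accuracy": accuracy(pred, test_fm.labels),
                        }
                    )
    performance = pd.DataFrame.from_records(records)
    if not performance.empty:
        performance["mode_group"] = np.where(
            performance["mode"] == "mi", "mi", "random"
        )
    return EvaluationResult(performance=performance, selections=selections)


def _fs_key(fs: FeatureSet) -> str:
    return "s" + ",".join(map(str, fs.sensors)) + "|t" + ",".join(map(str, fs.time_indices))


# ---------------------------------------------------------------------------
# hypothesis test


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    m1: float
    s1: float
    m2: float
    s2: float
    n: int


def t_test_two_sided(perf_a, perf_b, n: int | None = None, welch: bool = False) -> TTestResult:
    """Two-sided t-test for a difference in mean classification performance.

    ``t = (m1 - m2) / sqrt((s1^2 + s2^2) / n)`` with ``df = 2n - 2``, where
    ``n`` is the number of values per group (here: CV repetitions).  With
    ``welch=True`` the Welch-Satterthwaite df is used instead.  If both
    groups have zero variance, p is 1 when the means agree and 0 otherwise.
    """
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n is None:
        n = a.size
    if n < 2 or a.size != n or b.size != n:
        raise ValueError("both groups must hold n >= 2 values")
    m1, m2 = float(a.mean()), float(b.mean())
    s1, s2 = float(a.std(ddof=1)), float(b.std(ddof=1))
    denom = math.sqrt((s1**2 + s2**2) / n)
    if denom == 0.0:
        t = 0.0 if m1 == m2 else math.inf * np.sign(m1 - m2)
        p = 1.0 if m1 == m2 else 0.0
        df = 2 * n - 2
        return TTestResult(t=t, df=df, p_value=p, m1=m1, s1=s1, m2=m2, s2=s2, n=n)
    t = (m1 - m2) / denom
    if welch:
        v1, v2 = s1**2 / n, s2**2 / n
        df = (v1 + v2) ** 2 / (v1**2 / (n - 1) + v2**2 / (n - 1))
    else:
        df = 2 * n - 2
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p_value=p, m1=m1, s1=s1, m2=m2, s2=s2, n=n)


def per_repetition_means(performance: pd.DataFrame, constraint: str, classifier: str):
    """Aggregate per-split accuracies into per-repetition means for the MI
    and random arms (the groups the t-test compares)."""
    sub = performance[
        (performance["constraint"] == constraint)
        & (performance["classifier"] == classifier)
    ]
    mi = sub[sub["mode"] == "mi"].groupby("repetition")["accuracy"].mean()
    rnd = sub[sub["mode"] != "mi"].groupby("repetition")["accuracy"].mean()
    return mi.to_numpy(), rnd.to_numpy()


def mi_vs_random_tests(result: EvaluationResult) -> pd.DataFrame:
    """The MI-selected vs random-features t-test for every
    (constraint, classifier) cell with both arms present."""
    perf = result.performance
    rows = []
    for (constraint, classifier), _ in perf.groupby(["constraint", "classifier"]):
        mi, rnd = per_repetition_means(perf, constraint, classifier)
        if mi.size < 2 or rnd.size < 2 or mi.size != rnd.size:
            continue
        tt = t_test_two_sided(mi, rnd, n=mi.size)
        rows.append(
            {
                "constraint": constraint,
                "classifier": classifier,
                "mi_mean": tt.m1,
                "random_mean": tt.m2,
                "t": tt.t,
                "df": tt.df,
                "p_value": tt.p_value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# weighted performance


def weighted_performance_report(
    selections: list[SelectionResult], performance: pd.DataFrame
) -> pd.DataFrame:
    """Mean accuracy per constraint over the distinct chosen feature sets,
    weighted by each set's selection frequency.

    Expects the MI arm of a performance table; weights per constraint sum
    to one before averaging.
    """
    perf = performance[performance["mode"] == "mi"]
    rows = []
    by_constraint: dict = {}
    for sel in selections:
        by_constraint.setdefault(str(sel.constraint), []).append(sel)
    for constraint, group in sorted(by_constraint.items()):
        counts: dict[str, int] = {}
        for sel in group:
            key = _fs_key(sel.feature_set)
            counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        sub = perf[perf["constraint"] == constraint]
        for classifier in sorted(sub["classifier"].unique()):
            csub = sub[sub["classifier"] == classifier]
            weighted = 0.0
            for key, cnt in counts.items():
                acc = csub.loc[csub["feature_set"] == key, "accuracy"]
                if acc.empty:
                    raise MissingPerformanceForSetError(
                        f"no accuracy recorded for {key} at {constraint}"
                    )
                weighted += (cnt / total) * float(acc.mean())
            rows.append(
                {
                    "constraint": constraint,
                    "classifier": classifier,
                    "weighted_accuracy": weighted,
                }
            )
    return pd.DataFrame(rows)
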