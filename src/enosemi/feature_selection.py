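"""Exhaustive max-MI feature-set selection under joint size constraints.

The candidate space is constrained: a feature set consists of ``s`` sensors
and ``t`` time points, with the *same* ``t`` time points shared by every
chosen sensor.  For an array of S sensors and T candidate time points this
gives C(S, s) * C(T, t) candidate sets per constraint — small enough to
evaluate the mutual information of every candidate exhaustively, which is
the point of the filter approach: the score is computed once per candidate,
independently of any downstream classifier.

Selection is always performed on training data only.  Ties (within
1e-12 nats) break to the lexicographically smallest candidate so that
repeated runs are reproducible; the number of tied candidates is recorded
rather than guessed away.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .dataset_io import (
    FeatureSet,
    SensorArrayDataset,
    extract_features,
)
from .mi_estimation import (
    DEFAULT_K,
    MIEstimate,
    _class_indices,
    _knn_cd_from_distances,
    mi_plugin,
    preprocess_for_mi,
)

TIE_TOLERANCE_NATS = 1e-12


class InvalidConstraintError(ValueError):
    pass


class EmptyResultsError(ValueError):
    pass


class UnknownSensorInResultError(KeyError):
    pass


@dataclass(frozen=True)
class SizeConstraint:
    """Joint size constraint: choose ``n_sensors`` sensors and ``n_times``
    shared time points."""

    n_sensors: int
    n_times: int

    def __post_init__(self):
        if self.n_sensors < 1 or self.n_times < 1:
            raise InvalidConstraintError(f"constraint must be >= 1:1, got {self}")

    def validate_against(self, n_sensors_total: int, n_times_total: int) -> None:
        if self.n_sensors > n_sensors_total or self.n_times > n_times_total:
            raise InvalidConstraintError(
                f"{self} exceeds totals ({n_sensors_total} sensors, "
                f"{n_times_total} time points)"
            )

    def n_candidates(self, n_sensors_total: int, n_times_total: int) -> int:
        self.validate_against(n_sensors_total, n_times_total)
        return comb(n_sensors_total, self.n_sensors) * comb(n_times_total, self.n_times)

    def __str__(self):
        return f"{self.n_sensors}:{self.n_times}"


@dataclass
class SelectionResult:
    """The argmax feature set for one training split and constraint."""

    constraint: SizeConstraint
    feature_set: FeatureSet
    mi: MIEstimate
    n_ties: int = 1
    split_id: int | None = None


@dataclass
class EstimatorSettings:
    """How selection scores candidates: 'knn' (nearest-neighbour, continuous
    responses) or 'plugin' (exact plug-in; integer-valued responses only)."""

    estimator: str = "knn"
    k: int = DEFAULT_K
    seed: int = 0

    def __post_init__(self):
        if self.estimator not in ("knn", "plugin"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


def enumerate_feature_sets(
    constraint: SizeConstraint, n_sensors_total: int, n_times_total: int
):
    """Yield every candidate feature set in lexicographic order of
    (sorted sensors, sorted times)."""
    if not isinstance(constraint, SizeConstraint):
        constraint = SizeConstraint(*constraint)
    constraint.validate_against(n_sensors_total, n_times_total)
    for sensors in itertools.combinations(range(1, n_sensors_total + 1), constraint.n_sensors):
        for times in itertools.combinations(range(1, n_times_total + 1), constraint.n_times):
            yield FeatureSet(sensors=sensors, time_indices=times)


class _KnnSelectionWorkspace:
    """Shared state for scoring many candidate subsets of one training matrix.

    The full feature matrix is standardised and jittered once (both are
    column-wise operations, so the result on any column subset equals
    preprocessing that subset directly, up to the jitter draw).  Per-column
    absolute-difference matrices are cached; a candidate's Chebyshev
    distance matrix is their elementwise maximum over its columns.
    """

    def __init__(self, dataset: SensorArrayDataset, k: int, seed: int):
        self.k = k
        full = extract_features(dataset, dataset.full_feature_set())
        self.matrix = preprocess_for_mi(full, seed=seed)
        self.column_pos = {col: j for j, col in enumerate(self.matrix.column_index)}
        self.class_groups = _class_indices(self.matrix.labels)
        n = self.matrix.n_samples
        vals = self.matrix.values
        self._col_diffs = [
            np.abs(vals[:, j][:, None] - vals[:, j][None, :]) for j in range(vals.shape[1])
        ]
        self._dist = np.empty((n, n))

    def score(self, fs: FeatureSet) -> MIEstimate:
        cols = [self.column_pos[c] for c in fs.columns()]
        dist = self._dist
        np.copyto(dist, self._col_diffs[cols[0]])
        for j in cols[1:]:
            np.maximum(dist, self._col_diffs[j], out=dist)
        value = _knn_cd_from_distances(dist, self.class_groups, self.k)
        return MIEstimate(value=value, estimator="knn_cd", n=dist.shape[0], k=self.k)


class _PluginSelectionWorkspace:
    """Plug-in scoring for integer-valued training data (test oracle path)."""

    def __init__(self, dataset: SensorArrayDataset, seed: int):
        self.dataset = dataset

    def score(self, fs: FeatureSet) -> MIEstimate:
        fm = extract_features(self.dataset, fs)
        return mi_plugin(fm.values, fm.labels)


def select_max_mi(
    train: SensorArrayDataset,
    constraint: SizeConstraint,
    settings: EstimatorSettings | None = None,
    split_id: int | None = None,
) -> SelectionResult:
    """Exhaustively score every candidate set on the training data and
    return the MI maximiser.

    Ties within 1e-12 nats break to the lexicographically smallest
    candidate; ``n_ties`` counts how many candidates reached the maximum
    within that tolerance.
    """
    settings = settings or EstimatorSettings()
    if not isinstance(constraint, SizeConstraint):
        constraint = SizeConstraint(*constraint)
    constraint.validate_against(train.n_sensors, train.n_times)
    if settings.estimator == "knn":
        ws = _KnnSelectionWorkspace(train, k=settings.k, seed=settings.seed)
    else:
        ws = _PluginSelectionWorkspace(train, seed=settings.seed)

    best_fs = None
    best_mi = None
    n_ties = 0
    for fs in enumerate_feature_sets(constraint, train.n_sensors, train.n_times):
        est = ws.score(fs)
        if best_mi is None or est.value > best_mi.value + TIE_TOLERANCE_NATS:
            best_fs, best_mi, n_ties = fs, est, 1
        elif abs(est.value - best_mi.value) <= TIE_TOLERANCE_NATS:
            n_ties += 1
    return SelectionResult(
        constraint=constraint,
        feature_set=best_fs,
        mi=best_mi,
        n_ties=n_ties,
        split_id=split_id,
    )


# ---------------------------------------------------------------------------
# aggregation reports


@dataclass
class FrequencyReport:
    """Aggregation of per-split selections into frequency tables.

    ``set_frequencies``: per constraint, % of splits choosing each distinct
    feature set.  ``sensor_frequencies``: constraint x sensor matrix of
    appearance percentages (each selection contributes its s sensors, so a
    row sums to s * 100).  ``feature_frequencies``: the same at
    (sensor, time) resolution.
    """

    set_frequencies: dict = field(default_factory=dict)
    sensor_frequencies: pd.DataFrame | None = None
    feature_frequencies: pd.DataFrame | None = None


def selection_frequencies(results) -> FrequencyReport:
    """Pool per-split selections into percentage-frequency tables."""
    results = list(results)
    if not results:
        raise EmptyResultsError("no selection results")
    sensors = sorted({s for r in results for s in r.feature_set.sensors})
    features = sorted({c for r in results for c in r.feature_set.columns()})

    set_freq: dict = {}
    sensor_rows = {}
    feature_rows = {}
    by_constraint: dict = {}
    for r in results:
        by_constraint.setdefault(r.constraint, []).append(r)
    for constraint, group in sorted(
        by_constraint.items(), key=lambda kv: (kv[0].n_sensors, kv[0].n_times)
    ):
        n = len(group)
        counts: dict = {}
        for r in group:
            counts[r.feature_set] = counts.get(r.feature_set, 0) + 1
        set_freq[constraint] = {fs: 100.0 * c / n for fs, c in counts.items()}
        srow = {s: 0.0 for s in sensors}
        frow = {f: 0.0 for f in features}
        for fs, c in counts.items():
            for s in fs.sensors:
                srow[s] += 100.0 * c / n
            for f in fs.columns():
                frow[f] += 100.0 * c / n
        sensor_rows[str(constraint)] = srow
        feature_rows[str(constraint)] = frow

    return FrequencyReport(
        set_frequencies=set_freq,
        sensor_frequencies=pd.DataFrame.from_dict(sensor_rows, orient="index")[sensors],
        feature_frequencies=pd.DataFrame.from_dict(feature_rows, orient="index")[features],
    )


COMPOSITION_COLUMNS = ["% CTO only", "% SnO2 only", "% CTO>SnO2", "% SnO2>CTO", "% CTO=SnO2"]


def composition_table(results, families: dict[int, str]) -> pd.DataFrame:
    """Family balance of selected sets, one row per sensor-count constraint.

    Columns give the percentage of selected sets that are CTO-only,
    SnO2-only, CTO-majority, SnO2-majority and balanced; each row is a
    partition and sums to 100.
    """
    results = list(results)
    if not results:
        raise EmptyResultsError("no selection results")
    buckets: dict[int, list] = {}
    for r in results:
        buckets.setdefault(r.constraint.n_sensors, []).append(r)

    rows = {}
    for n_sensors, group in sorted(buckets.items()):
        tally = dict.fromkeys(COMPOSITION_COLUMNS, 0)
        for r in group:
            fams = []
            for s in r.feature_set.sensors:
                if s not in families:
                    raise UnknownSensorInResultError(f"sensor {s} has no family tag")
                fams.append(families[s])
            n_cto = sum(f == "CTO" for f in fams)
            n_sno = len(fams) - n_cto
            if n_sno == 0:
                key = "% CTO only"
            elif n_cto == 0:
                key = "% SnO2 only"
            elif n_cto > n_sno:
                key = "% CTO>SnO2"
            elif n_sno > n_cto:
                key = "% SnO2>CTO"
            else:
                key = "% CTO=SnO2"
            tally[key] += 1
        rows[n_sensors] = {k: 100.0 * v / len(group) for k, v in tally.items()}
    table = pd.DataFrame.from_dict(rows, orient="index")[COMPOSITION_COLUMNS]
    table.index.name = "No. Sensors"
    return table
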