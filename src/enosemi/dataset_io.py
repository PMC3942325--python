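"""Reading, writing, validating and slicing sensor-array datasets.

A dataset is a dense 3-way array of sensor responses indexed by
(sample, sensor, time point), together with a chemical class label and a
replicate id per sample, and a chemistry-family tag per sensor.  The
canonical on-disk representation is a long (tidy) CSV with one row per
(sample, sensor, time point) cell::

    sample_id,class,replicate,sensor,time_s,response[,family]

Sensor ids and time indices are 1-based throughout, matching the usual
"sensor 1..12" / "time point 1..6" naming for a 12-sensor, 6-time-point
metal-oxide array.  Responses are dimensionless fractional resistance
changes and are stored as given (no baseline correction or unit change).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CTO = "CTO"
SNO2 = "SnO2"

#: Default family map for the 12-sensor array: sensors 1-6 are chromium
#: titanium oxide (CTO), sensors 7-12 are doped tin oxide (SnO2).
DEFAULT_FAMILIES = (CTO,) * 6 + (SNO2,) * 6

#: Default candidate extraction times (seconds) for the 12 x 6 feature grid.
DEFAULT_TIME_POINTS_S = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)

CSV_COLUMNS = ["sample_id", "class", "replicate", "sensor", "time_s", "response"]

# float format used by write_dataset; 17 significant digits round-trip IEEE
# doubles exactly, and the fixed format makes write -> load -> write
# byte-identical.
_FLOAT_FMT = "%.17g"


class DatasetError(ValueError):
    """Base class for dataset validation failures."""


class MissingCellError(DatasetError):
    pass


class DuplicateCellError(DatasetError):
    pass


class NonNumericResponseError(DatasetError):
    pass


class InvalidDatasetError(DatasetError):
    pass


class UnwritablePathError(OSError):
    pass


class UnknownSensorError(KeyError):
    pass


class UnknownTimeIndexError(KeyError):
    pass


class EmptyFeatureSetError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSet:
    """A choice of sensors and shared time points.

    ``sensors`` are 1-based sensor ids, ``time_indices`` are 1-based indices
    into the dataset's time-point axis.  The same time points apply to every
    chosen sensor, so the feature count is ``len(sensors) * len(time_indices)``.
    """

    sensors: tuple[int, ...]
    time_indices: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "sensors", tuple(sorted(int(s) for s in self.sensors)))
        object.__setattr__(
            self, "time_indices", tuple(sorted(int(t) for t in self.time_indices))
        )
        if not self.sensors or not self.time_indices:
            raise EmptyFeatureSetError("a feature set needs >=1 sensor and >=1 time point")
        if len(set(self.sensors)) != len(self.sensors):
            raise InvalidDatasetError(f"duplicate sensors in {self.sensors}")
        if len(set(self.time_indices)) != len(self.time_indices):
            raise InvalidDatasetError(f"duplicate time indices in {self.time_indices}")

    @property
    def n_features(self) -> int:
        return len(self.sensors) * len(self.time_indices)

    def columns(self) -> list[tuple[int, int]]:
        """Ordered (sensor id, time index) pairs, sensor-major."""
        return [(s, t) for s in self.sensors for t in self.time_indices]


@dataclass
class SensorArrayDataset:
    """Dense sensor-array responses plus per-sample and per-sensor metadata."""

    responses: np.ndarray  # (n_samples, n_sensors, n_times)
    class_labels: np.ndarray  # (n_samples,) str
    replicate_ids: np.ndarray  # (n_samples,) int
    sensor_families: tuple[str, ...] = DEFAULT_FAMILIES
    time_points_s: tuple[float, ...] = DEFAULT_TIME_POINTS_S
    sample_ids: np.ndarray | None = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise InvalidDatasetError("responses must be (samples, sensors, times)")
        n, s, t = self.responses.shape
        if n == 0 or s == 0 or t == 0:
            raise InvalidDatasetError("empty dataset")
        if not np.all(np.isfinite(self.responses)):
            raise NonNumericResponseError("responses contain non-finite values")
        self.class_labels = np.asarray(self.class_labels)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
        if self.class_labels.shape != (n,) or self.replicate_ids.shape != (n,):
            raise InvalidDatasetError("per-sample metadata length mismatch")
        self.sensor_families = tuple(self.sensor_families)
        if len(self.sensor_families) != s:
            raise InvalidDatasetError("one family tag per sensor required")
        self.time_points_s = tuple(float(x) for x in self.time_points_s)
        if len(self.time_points_s) != t:
            raise InvalidDatasetError("one time value per time index required")
        if np.any(np.diff(self.time_points_s) <= 0):
            raise InvalidDatasetError("time_points_s must be strictly increasing")
        if self.sample_ids is None:
            self.sample_ids = np.arange(1, n + 1)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=int)
            if self.sample_ids.shape != (n,):
                raise InvalidDatasetError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.responses.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.responses.shape[1]

    @property
    def n_times(self) -> int:
        return self.responses.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.class_labels)

    def is_balanced(self) -> bool:
        _, counts = np.unique(self.class_labels, return_counts=True)
        return bool(np.all(counts == counts[0]))

    def family_map(self) -> dict[int, str]:
        return {s + 1: fam for s, fam in enumerate(self.sensor_families)}

    def subset(self, sample_indices) -> "SensorArrayDataset":
        """Row-subset (0-based positional indices); sensors/times unchanged."""
        idx = np.asarray(sample_indices, dtype=int)
        return SensorArrayDataset(
            responses=self.responses[idx],
            class_labels=self.class_labels[idx],
            replicate_ids=self.replicate_ids[idx],
            sensor_families=self.sensor_families,
            time_points_s=self.time_points_s,
            sample_ids=self.sample_ids[idx],
        )

    def full_feature_set(self) -> FeatureSet:
        return FeatureSet(
            sensors=tuple(range(1, self.n_sensors + 1)),
            time_indices=tuple(range(1, self.n_times + 1)),
        )


@dataclass
class FeatureMatrix:
    """A 2-D feature view of a dataset for one feature set.

    Columns are ordered sensor-major, then time index ascending.
    """

    values: np.ndarray  # (n_samples, n_features)
    column_index: list[tuple[int, int]] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidDatasetError("feature matrix must be 2-D")
        if self.column_index and len(self.column_index) != self.values.shape[1]:
            raise InvalidDatasetError("column_index length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise InvalidDatasetError("labels length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, cols) -> "FeatureMatrix":
        cols = list(cols)
        return FeatureMatrix(
            values=self.values[:, cols],
            column_index=[self.column_index[c] for c in cols] if self.column_index else [],
            labels=self.labels,
        )


def extract_features(dataset: SensorArrayDataset, fs: FeatureSet) -> FeatureMatrix:
    """Slice the (sensor, time) grid of ``fs`` out of a dataset.

    ``values[i, j] == dataset.responses[i, sensor(j)-1, time(j)-1]`` with
    columns ordered sensor-major.
    """
    for s in fs.sensors:
        if not 1 <= s <= dataset.n_sensors:
            raise UnknownSensorError(f"sensor {s} not in 1..{dataset.n_sensors}")
    for t in fs.time_indices:
        if not 1 <= t <= dataset.n_times:
            raise UnknownTimeIndexError(f"time index {t} not in 1..{dataset.n_times}")
    cols = fs.columns()
    sens = np.array([c[0] - 1 for c in cols])
    times = np.array([c[1] - 1 for c in cols])
    values = dataset.responses[:, sens, times]
    return FeatureMatrix(values=values, column_index=cols, labels=dataset.class_labels.copy())


def _family_defaults(n_sensors: int) -> tuple[str, ...]:
    if n_sensors == 12:
        return DEFAULT_FAMILIES
    half = n_sensors // 2
    return (CTO,) * half + (SNO2,) * (n_sensors - half)


def load_dataset(path, family_map: dict[int, str] | None = None) -> SensorArrayDataset:
    """Load the canonical long-format CSV into a dense dataset.

    Every (sample, sensor, time) combination must appear exactly once.
    Family tags come from the optional ``family`` column, the ``family_map``
    argument, or default to CTO for the first half of sensors and SnO2 for
    the rest.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InvalidDatasetError(f"missing columns: {missing_cols}")
    if df.empty:
        raise InvalidDatasetError("no data rows")
    if not pd.api.types.is_numeric_dtype(df["response"]):
        bad = df.loc[pd.to_numeric(df["response"], errors="coerce").isna(), "response"]
        raise NonNumericResponseError(f"non-numeric responses, e.g. {bad.iloc[0]!r}")
    if df["response"].isna().any() or not np.all(np.isfinite(df["response"].to_numpy(float))):
        raise NonNumericResponseError("NaN/inf responses present")

    sample_ids = np.sort(df["sample_id"].unique())
    sensors = np.sort(df["sensor"].unique())
    times = np.sort(df["time_s"].unique())
    n, s, t = len(sample_ids), len(sensors), len(times)
    if not np.array_equal(sensors, np.arange(1, s + 1)):
        raise InvalidDatasetError(f"sensor ids must be 1..{s}, got {sensors}")

    dup = df.duplicated(subset=["sample_id", "sensor", "time_s"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise DuplicateCellError(
            f"duplicate cell (sample {row.sample_id}, sensor {row.sensor}, t={row.time_s})"
        )
    if len(df) != n * s * t:
        # locate one missing combination for the error message
        have = set(zip(df["sample_id"], df["sensor"], df["time_s"]))
        for combo in itertools.product(sample_ids, sensors, times):
            if combo not in have:
                raise MissingCellError(
                    f"missing cell (sample {combo[0]}, sensor {combo[1]}, t={combo[2]})"
                )
        raise InvalidDatasetError("row count inconsistent with index grid")

    sid_pos = {v: i for i, v in enumerate(sample_ids)}
    t_pos = {v: i for i, v in enumerate(times)}
    responses = np.empty((n, s, t))
    responses[
        df["sample_id"].map(sid_pos).to_numpy(),
        df["sensor"].to_numpy(int) - 1,
        df["time_s"].map(t_pos).to_numpy(),
    ] = df["response"].to_numpy(float)

    first = df.drop_duplicates("sample_id").set_index("sample_id").loc[sample_ids]
    class_labels = first["class"].astype(str).to_numpy()
    replicate_ids = first["replicate"].to_numpy(int)

    if "family" in df.columns:
        fam_rows = df.drop_duplicates("sensor").set_index("sensor").loc[sensors]
        families = tuple(str(f) for f in fam_rows["family"])
    elif family_map is not None:
        families = tuple(family_map[sid] for sid in sensors)
    else:
        families = _family_defaults(s)

    return SensorArrayDataset(
        responses=responses,
        class_labels=class_labels,
        replicate_ids=replicate_ids,
        sensor_families=families,
        time_points_s=tuple(times),
        sample_ids=sample_ids,
    )


def write_dataset(dataset: SensorArrayDataset, path) -> str:
    """Write the canonical long-format CSV (one row per cell) to ``path``."""
    n, s, t = dataset.responses.shape
    sample_col = np.repeat(dataset.sample_ids, s * t)
    class_col = np.repeat(dataset.class_labels, s * t)
    rep_col = np.repeat(dataset.replicate_ids, s * t)
    sensor_col = np.tile(np.repeat(np.arange(1, s + 1), t), n)
    time_col = np.tile(np.array(dataset.time_points_s), n * s)
    fam_col = np.tile(np.repeat(np.array(dataset.sensor_families, dtype=object), t), n)
    df = pd.DataFrame(
        {
            "sample_id": sample_col,
            "class": class_col,
            "replicate": rep_col,
            "sensor": sensor_col,
            "time_s": time_col,
            "response": dataset.responses.reshape(-1),
            "family": fam_col,
        }
    )
    try:
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise UnwritablePathError(str(exc)) from exc
    return str(path)
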