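"""Synthetic electronic-nose data with a known informative structure.

The generator emulates a metal-oxide sensor array measuring headspace
samples of pure chemicals: each sensor's response to a sample follows a
double-exponential rise/decay curve whose peak amplitude depends on the
(sensor, chemical) pair, sampled at a handful of fixed time points.  Two
sensor families are emulated: low-amplitude CTO sensors (peaks in
0.05-0.25) and high-amplitude SnO2 sensors (peaks in 0.4-1.0), matching
the roughly 0.2 vs 0.9 maximum fractional responses typical of such
arrays.

"Informative" sensors have a different peak amplitude for every chemical
class; non-informative sensors respond identically to every class, so with
zero noise they carry exactly zero information about chemical identity.
That planted structure is the ground truth against which feature selection
is tested.

Response model for sample i (class c), sensor s, time t::

    r[i, s, t] = A[s, c] * g_s(t) * (1 + eta_mult) + eta_add

where g_s(t) = (1 - exp(-t/tau_rise_s)) * exp(-t/tau_decay_s), normalised
to unit maximum so that A[s, c] is literally the peak response, and
eta_mult ~ N(0, multiplicative_noise_sd), eta_add ~ N(0, additive_noise_sd)
are drawn independently per (sample, sensor) and per cell respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import (
    CTO,
    DEFAULT_TIME_POINTS_S,
    SNO2,
    FeatureSet,
    SensorArrayDataset,
)

CTO_AMPLITUDE_RANGE = (0.05, 0.25)
SNO2_AMPLITUDE_RANGE = (0.4, 1.0)

# rise/decay time constants (seconds) are drawn per sensor from these ranges;
# they put the response peak at tau_r*ln(1 + tau_d/tau_r), i.e. ~40-60 s.
RISE_TAU_RANGE_S = (20.0, 30.0)
DECAY_TAU_RANGE_S = (120.0, 180.0)


class InvalidConfigError(ValueError):
    pass


class UnsatisfiableConstraintError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic e-nose generator.

    Defaults reproduce the shape of a 20-chemical, 10-replicate study on a
    12-sensor (6 CTO + 6 SnO2) array sampled at 10..60 s: 200 samples in
    all.  Six sensors (three per family) are informative by default; the
    remaining six are flat across classes.
    """

    n_classes: int = 20
    n_replicates: int = 10
    n_sensors: int = 12
    time_points_s: tuple[float, ...] = DEFAULT_TIME_POINTS_S
    informative_sensors: tuple[int, ...] = (1, 2, 3, 7, 8, 9)
    additive_noise_sd: float = 0.01
    multiplicative_noise_sd: float = 0.05
    seed: int = 0
    # optional explicit kinetics/amplitudes; drawn from `seed` when None
    amplitude_matrix: np.ndarray | None = None  # (n_sensors, n_classes)
    rise_tau_s: tuple[float, ...] | None = None
    decay_tau_s: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n_classes < 1 or self.n_replicates < 1 or self.n_sensors < 1:
            raise InvalidConfigError("counts must be >= 1")
        if self.additive_noise_sd < 0 or self.multiplicative_noise_sd < 0:
            raise InvalidConfigError("noise sds must be >= 0")
        if len(self.time_points_s) < 1 or np.any(np.diff(self.time_points_s) <= 0):
            raise InvalidConfigError("time_points_s must be non-empty, strictly increasing")
        for s in self.informative_sensors:
            if not 1 <= s <= self.n_sensors:
                raise InvalidConfigError(
                    f"informative sensor {s} outside 1..{self.n_sensors}"
                )
        if self.amplitude_matrix is not None:
            a = np.asarray(self.amplitude_matrix, float)
            if a.shape != (self.n_sensors, self.n_classes):
                raise InvalidConfigError("amplitude_matrix must be (n_sensors, n_classes)")
        for tau in (self.rise_tau_s, self.decay_tau_s):
            if tau is not None and len(tau) != self.n_sensors:
                raise InvalidConfigError("need one time constant per sensor")

    @property
    def families(self) -> tuple[str, ...]:
        half = self.n_sensors // 2
        return (CTO,) * half + (SNO2,) * (self.n_sensors - half)

    @property
    def n_times(self) -> int:
        return len(self.time_points_s)


def _resolve_model(config: SyntheticConfig):
    """Draw (or pass through) amplitudes and time constants, deterministically."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xA17]))
    fams = config.families
    if config.rise_tau_s is None:
        rise = rng.uniform(*RISE_TAU_RANGE_S, size=config.n_sensors)
    else:
        rise = np.asarray(config.rise_tau_s, float)
    if config.decay_tau_s is None:
        decay = rng.uniform(*DECAY_TAU_RANGE_S, size=config.n_sensors)
    else:
        decay = np.asarray(config.decay_tau_s, float)
    if config.amplitude_matrix is None:
        amp = np.empty((config.n_sensors, config.n_classes))
        informative = set(config.informative_sensors)
        for s in range(config.n_sensors):
            lo, hi = CTO_AMPLITUDE_RANGE if fams[s] == CTO else SNO2_AMPLITUDE_RANGE
            if (s + 1) in informative:
                amp[s] = rng.uniform(lo, hi, size=config.n_classes)
            else:
                amp[s] = rng.uniform(lo, hi)  # one value, shared by all classes
    else:
        amp = np.asarray(config.amplitude_matrix, float)
    return amp, rise, decay


def _response_kernel(time_points_s, rise, decay) -> np.ndarray:
    """Unit-peak double-exponential kernel, shape (n_sensors, n_times)."""
    t = np.asarray(time_points_s, float)[None, :]
    r = rise[:, None]
    d = decay[:, None]
    g = (1.0 - np.exp(-t / r)) * np.exp(-t / d)
    t_peak = r * np.log1p(d / r)
    g_peak = (1.0 - np.exp(-t_peak / r)) * np.exp(-t_peak / d)
    return g / g_peak


def noiseless_class_means(config: SyntheticConfig) -> np.ndarray:
    """Expected responses per class: array (n_classes, n_sensors, n_times)."""
    amp, rise, decay = _resolve_model(config)
    kernel = _response_kernel(config.time_points_s, rise, decay)
    # (c, s, t) = A[s, c] * g[s, t]
    return amp.T[:, :, None] * kernel[None, :, :]


@dataclass
class SyntheticDataset:
    """A generated dataset together with its planted ground truth."""

    dataset: SensorArrayDataset
    informative_sensors: tuple[int, ...]
    config: SyntheticConfig = field(repr=False, default=None)


def generate_enose_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a balanced synthetic e-nose dataset.

    Fully deterministic for a fixed config (including seed).  Classes are
    labelled ``chem01..chemNN``; every class has exactly ``n_replicates``
    samples.
    """
    means = noiseless_class_means(config)  # (C, S, T)
    n = config.n_classes * config.n_replicates
    class_idx = np.repeat(np.arange(config.n_classes), config.n_replicates)
    replicate_ids = np.tile(np.arange(1, config.n_replicates + 1), config.n_classes)

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xB0DE]))
    clean = means[class_idx]  # (n, S, T)
    mult = rng.normal(0.0, 1.0, size=(n, config.n_sensors, 1))
    add = rng.normal(0.0, 1.0, size=clean.shape)
    responses = (
        clean * (1.0 + config.multiplicative_noise_sd * mult)
        + config.additive_noise_sd * add
    )

    width = max(2, len(str(config.n_classes)))
    labels = np.array([f"chem{c + 1:0{width}d}" for c in class_idx])
    dataset = SensorArrayDataset(
        responses=responses,
        class_labels=labels,
        replicate_ids=replicate_ids,
        sensor_families=config.families,
        time_points_s=config.time_points_s,
    )
    return SyntheticDataset(
        dataset=dataset,
        informative_sensors=tuple(sorted(config.informative_sensors)),
        config=config,
    )


def _discrete_plugin_mi(rows: np.ndarray) -> float:
    """Plug-in MI (nats) between equiprobable classes and discretised rows.

    ``rows`` holds one integer-valued feature row per class; classes are
    equiprobable so I(S; C) = H(rows) = H(C) - H(C|rows) with H(C|rows)
    counting classes that share a row.
    """
    _, counts = np.unique(rows, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def planted_best_feature_set(
    config: SyntheticConfig,
    constraint,
    bin_width: float = 0.05,
) -> FeatureSet:
    """Ground-truth most-informative feature set under a size constraint.

    Brute force over every candidate set: the noiseless class-conditional
    mean responses are discretised into bins of ``bin_width`` and the exact
    plug-in MI between the binned feature rows and the (equiprobable) class
    is maximised; ties break lexicographically.  Serves as the oracle for
    recovery tests; independent of the kNN estimation path.
    """
    from .feature_selection import SizeConstraint, enumerate_feature_sets

    if not isinstance(constraint, SizeConstraint):
        constraint = SizeConstraint(*constraint)
    if constraint.n_sensors > config.n_sensors or constraint.n_times > config.n_times:
        raise UnsatisfiableConstraintError(
            f"constraint {constraint} exceeds {config.n_sensors} sensors / "
            f"{config.n_times} time points"
        )
    means = noiseless_class_means(config)  # (C, S, T)
    binned = np.floor(means / bin_width).astype(np.int64)

    best = None
    best_mi = -np.inf
    for fs in enumerate_feature_sets(constraint, config.n_sensors, config.n_times):
        sens = [s - 1 for s in fs.sensors]
        times = [t - 1 for t in fs.time_indices]
        rows = binned[:, sens][:, :, times].reshape(config.n_classes, -1)
        mi = _discrete_plugin_mi(rows)
        if mi > best_mi + 1e-12:
            best, best_mi = fs, mi
    return best
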