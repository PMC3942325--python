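import numpy as np
import pytest

from enosemi import SensorArrayDataset, SyntheticConfig, generate_enose_dataset


@pytest.fixture(scope="session")
def paper_shaped():
    """Default-shaped synthetic dataset: 20 classes x 10 replicates,
    12 sensors (6 CTO + 6 SnO2), 6 time points."""
    return generate_enose_dataset(SyntheticConfig(seed=7))


@pytest.fixture()
def tiny_discrete_dataset():
    """4 classes x 8 replicates, 4 sensors, 3 times, integer responses.

    Sensors 1-2 carry class information; sensors 3-4 are pure noise.
    Suitable for the exact plug-in estimator.
    """
    rng = np.random.default_rng(42)
    n_classes, n_rep, n_sensors, n_times = 4, 8, 4, 3
    n = n_classes * n_rep
    class_idx = np.repeat(np.arange(n_classes), n_rep)
    responses = rng.integers(0, 3, size=(n, n_sensors, n_times)).astype(float)
    for s in (0, 1):  # informative sensors: add a class-dependent offset
        responses[:, s, :] += 3 * class_idx[:, None]
    return SensorArrayDataset(
        responses=responses,
        class_labels=np.array([f"c{c}" for c in class_idx]),
        replicate_ids=np.tile(np.arange(1, n_rep + 1), n_classes),
        sensor_families=("CTO", "CTO", "SnO2", "SnO2"),
        time_points_s=(10.0, 20.0, 30.0),
    )


def two_gaussian_matrix(n, seed, sep=3.0):
    """1-D two-class Gaussian benchmark: X|C=0 ~ N(0,1), X|C=1 ~ N(sep,1)."""
    from enosemi import FeatureMatrix

    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    x = np.where(labels == 0, rng.normal(0.0, 1.0, n), rng.normal(sep, 1.0, n))
    return FeatureMatrix(values=x[:, None], labels=labels)


def two_gaussian_true_mi(sep=3.0):
    """I(X; C) for the equiprobable two-Gaussian mixture, by 1-D numerical
    integration of the mixture entropy (independent oracle)."""
    from scipy.integrate import quad

    def f(v):
        return 0.5 * (
            np.exp(-(v**2) / 2) + np.exp(-((v - sep) ** 2) / 2)
        ) / np.sqrt(2 * np.pi)

    h_mix = quad(lambda v: -f(v) * np.log(f(v)), -12.0, sep + 12.0)[0]
    h_cond = 0.5 * np.log(2 * np.pi * np.e)
    return h_mix - h_cond
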