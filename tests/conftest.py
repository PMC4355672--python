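import numpy as np
import pytest

from wrda import SimulationSpec, TimeCourseDataset, simulate


def make_dataset(values, group, time_point, sampling_time=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    return TimeCourseDataset(
        values=values,
        feature_ids=feature_ids or [f"F{k}" for k in range(f)],
        group=np.asarray(group),
        time_point=np.asarray(time_point),
        sampling_time=np.zeros(n, dtype=int) if sampling_time is None else np.asarray(sampling_time),
    )


def random_dataset(rng, n_features=None, n_time_points=None, p_max=3, n_per_cell=None):
    """Small random dataset with arbitrary (possibly ragged) sampling times."""
    F = n_features or int(rng.integers(2, 21))
    N = n_time_points or int(rng.integers(2, 6))
    p = rng.integers(1, p_max + 1, size=N)
    rows, groups, tps, sts = [], [], [], []
    for i in range(N):
        for j in range(p[i]):
            for g in ("C", "M"):
                n = n_per_cell or int(rng.integers(2, 5))
                rows.append(rng.gamma(5.0, 20.0, size=(n, F)))
                groups += [g] * n
                tps += [i] * n
                sts += [j] * n
    return make_dataset(np.vstack(rows), groups, tps, sts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_balanced():
    """2 features, 2 time points, 2 samples per (group, time point)."""
    return make_dataset(
        values=[[1, 10], [3, 12], [5, 20], [7, 22], [2, 11], [4, 13], [6, 21], [8, 23]],
        group=["C", "C", "C", "C", "M", "M", "M", "M"],
        time_point=[0, 0, 1, 1, 0, 0, 1, 1],
    )


@pytest.fixture
def null_cohort():
    """No planted signal: C and M identically distributed."""
    spec = SimulationSpec(
        n_features=40,
        n_signal=0,
        n_time_points=4,
        p_per_time_point=(1,) * 4,
        samples_per_cell={"C": 6, "M": 6},
        onset_time_point=0,
        seed=7,
    )
    return simulate(spec)[0]
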