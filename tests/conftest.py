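import numpy as np
import pytest

from tlbkit import Cohort, GridSpec, Thermogram
from tlbkit.preprocess import FeatureVector


@pytest.fixture
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def thermogram_from(fn, sample_id="S", t_lo=40.0, t_hi=95.0, step=0.1) -> Thermogram:
    """Sample a callable cp(T) on a uniform raw grid."""
    n = round((t_hi - t_lo) / step)
    t = t_lo + np.arange(n + 1) * step
    return Thermogram(sample_id, t, fn(t))


def feature_vectors_from_matrix(X, grid_temps=None) -> list[FeatureVector]:
    """Wrap a (n_samples, n_temps) matrix as FeatureVectors on a shared grid."""
    X = np.asarray(X, dtype=float)
    if grid_temps is None:
        grid_temps = 55.0 + np.arange(X.shape[1])
    return [
        FeatureVector(f"S{i:02d}", np.asarray(grid_temps, float), X[i])
        for i in range(X.shape[0])
    ]


def small_cohort(n=3) -> Cohort:
    thermos = [
        thermogram_from(
            lambda t, k=k: np.exp(-((t - 65 - k) ** 2) / 50.0) + 0.01,
            sample_id=f"S{k}",
        )
        for k in range(n)
    ]
    labels = {f"S{k}": ("positive" if k % 2 else "negative") for k in range(n)}
    confirmed = {f"S{k}": k < max(1, n - 1) for k in range(n)}
    return Cohort(thermos, labels, confirmed)
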