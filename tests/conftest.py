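import numpy as np
import pytest

from alsurv.curves import CensoredSample, SurvivalCurve
from alsurv.models.base import FeatureMatrix
from alsurv.synthetic import SimConfig, simulate_cohort


def random_curve(rng, interpolation=None, n_knots=None, reach_zero=None):
    """A random valid survival curve for property tests."""
    n_knots = n_knots or rng.integers(2, 12)
    times = np.concatenate(([0.0], np.sort(rng.uniform(0.5, 100.0, size=n_knots - 1))))
    times = np.unique(times)
    drops = rng.dirichlet(np.ones(times.size - 1))
    total = rng.uniform(0.3, 1.0) if reach_zero is None else (1.0 if reach_zero else 0.7)
    surv = np.concatenate(([1.0], 1.0 - total * np.cumsum(drops)))
    surv = np.clip(surv, 0.0, 1.0)
    interp = interpolation or ("step" if rng.random() < 0.5 else "linear")
    return SurvivalCurve(times, surv, interpolation=interp)


def random_censored_sample(rng, n=30, censor_rate=0.4):
    times = rng.exponential(20.0, size=n) + 0.1
    events = (rng.uniform(size=n) > censor_rate).astype(int)
    if events.sum() == 0:
        events[0] = 1
    return CensoredSample(times, events)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_cohort():
    """A small informative cohort: signal in the clinical block only."""
    cfg = SimConfig(
        n_patients=120,
        n_clinical=8,
        n_image=6,
        n_informative_clinical=5,
        coef_value=0.25,
        missing_rate=0.03,
        seed=42,
    )
    return simulate_cohort(cfg)


def feature_matrix(X, prefix="clin"):
    X = np.asarray(X, dtype=float)
    names = tuple(f"{prefix}_{j}" for j in range(X.shape[1]))
    block = "clinical" if prefix == "clin" else "image"
    return FeatureMatrix(X, names, (block,) * X.shape[1])
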