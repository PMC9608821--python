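import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from comprep.io import generate_fixture
from comprep.panel import DietPanel
from comprep.qfasa import DietSolver

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fx():
    """Shared synthetic data set: separable 6-species x 12-FA prey library,
    calibration, and panels sampled from a known-repeatability grid."""
    return generate_fixture(seed=3, grid_rows=200)


@pytest.fixture(scope="session")
def library(fx):
    return fx.library


@pytest.fixture(scope="session")
def cc(fx):
    return fx.cc


@pytest.fixture(scope="session")
def balanced_panel(fx):
    return fx.panel_balanced


@pytest.fixture(scope="session")
def unbalanced_panel(fx):
    return fx.panel_unbalanced


@pytest.fixture(scope="session")
def solver(fx):
    """Single-start QFASA solver (the objective is convex in the mixture)."""
    return DietSolver(fx.library, fx.cc, n_restarts=1, seed=0)


def univariate_panel(values: np.ndarray, missing: set | None = None):
    """(n, k) array of scalar responses -> labels + flat values, optionally
    dropping (i, j) cells.  Used by the Euclidean-distance oracle tests."""
    preds, times, flat = [], [], []
    n, k = values.shape
    for i in range(n):
        for j in range(k):
            if missing and (i, j) in missing:
                continue
            preds.append(f"P{i}")
            times.append(f"T{j}")
            flat.append(values[i, j])
    return np.asarray(flat), preds, times


def random_compositions(rng, n, m, zero_rate=0.3):
    """Random compositions with essential zeros."""
    x = rng.dirichlet(np.full(m, 0.6), size=n)
    mask = rng.random(size=x.shape) < zero_rate
    # never zero out a whole row
    mask[np.arange(n), x.argmax(axis=1)] = False
    x = np.where(mask, 0.0, x)
    return x / x.sum(axis=1, keepdims=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
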