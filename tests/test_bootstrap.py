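"""Cluster bootstrap, jackknife, studentized-T and BCa intervals, bias."""

import numpy as np
import pandas as pd
import pytest

from comprep.bootstrap import (
    BootstrapEnsemble,
    PanelEngine,
    bca_interval,
    cluster_bootstrap,
    estimate_bias,
    jackknife_variance,
    repeatability_with_ci,
    studentized_t_interval,
)
from comprep.errors import DegenerateDesignError
from comprep.panel import DietPanel
from comprep.repeatability import estimate_repeatability


def _tiny_panel(n=5, seed=0):
    rng = np.random.default_rng(seed)
    values, preds, times = [], [], []
    for i in range(n):
        base = rng.dirichlet(np.ones(4))
        for j in range(2):
            noisy = np.maximum(base + rng.normal(0, 0.05, 4), 0.0)
            values.append(noisy / noisy.sum())
            preds.append(f"P{i}")
            times.append(f"T{j}")
    return DietPanel.from_arrays(np.asarray(values), preds, times, list("abcd"))


def _ensemble(rho_star, rho_ss, z, v=None, seed=None):
    B, R = rho_ss.shape
    v = np.ones_like(rho_ss) if v is None else v
    return BootstrapEnsemble(B, R, rho_star, rho_ss, z, v, seed)


# -- cluster bootstrap ------------------------------------------------------
def test_cluster_bootstrap_requires_two_predators():
    one = DietPanel.from_arrays(
        [[0.5, 0.5], [0.6, 0.4]], ["a", "a"], ["t1", "t2"], ["s1", "s2"]
    )
    with pytest.raises(DegenerateDesignError):
        cluster_bootstrap(one, np.random.default_rng(0))


def test_cluster_bootstrap_copies_whole_predators():
    panel = _tiny_panel()
    rng = np.random.default_rng(3)
    boot = cluster_bootstrap(panel, rng)
    assert boot.n == panel.n
    originals = {p: panel.data.loc[p].to_numpy() for p in panel.predators}
    for p in boot.predators:
        src = p.split("#")[0]
        assert np.allclose(boot.data.loc[p].to_numpy(), originals[src])


def test_cluster_bootstrap_uniform_sampling():
    """Over 2000 resamples of n=5, each predator fills ~1/5 of the slots."""
    panel = _tiny_panel()
    rng = np.random.default_rng(9)
    counts = {p: 0 for p in panel.predators}
    total = 0
    for _ in range(2000):
        boot = cluster_bootstrap(panel, rng)
        for p in boot.predators:
            counts[p.split("#")[0]] += 1
            total += 1
    for p, c in counts.items():
        assert c / total == pytest.approx(0.2, abs=0.02)


# -- jackknife --------------------------------------------------------------
def test_jackknife_constant_statistic_is_zero():
    panel = _tiny_panel()
    assert jackknife_variance(panel, lambda p: 3.14) == 0.0


def test_jackknife_of_mean_matches_closed_form():
    """Delete-one jackknife variance of the mean of per-predator summaries
    equals s^2 / n."""
    panel = _tiny_panel(n=7)
    summaries = panel.data.groupby(level="predator_id", sort=False).mean().iloc[:, 0]

    def stat(p):
        return p.data.groupby(level="predator_id", sort=False).mean().iloc[:, 0].mean()

    v = jackknife_variance(panel, stat)
    expected = summaries.var(ddof=1) / len(summaries)
    assert v == pytest.approx(expected, rel=1e-10)


def test_jackknife_n3_brute_force():
    panel = _tiny_panel(n=3)
    stat = lambda p: estimate_repeatability(p).rho_hat
    reps = []
    for drop in panel.predators:
        keep = [p for p in panel.predators if p != drop]
        reps.append(estimate_repeatability(panel.select_predators(keep)).rho_hat)
    reps = np.asarray(reps)
    expected = (2.0 / 3.0) * np.sum((reps - reps.mean()) ** 2)
    assert jackknife_variance(panel, stat) == pytest.approx(expected, rel=1e-10)


def test_panel_engine_jackknife_matches_public_op(balanced_panel):
    eng = PanelEngine.from_panel(balanced_panel)
    v_engine, _ = eng.jackknife()
    v_public = jackknife_variance(balanced_panel, lambda p: estimate_repeatability(p).rho_hat)
    assert v_engine == pytest.approx(v_public, rel=1e-10)


# -- studentized T ----------------------------------------------------------
def test_t_interval_with_injected_normal_pivots():
    rng = np.random.default_rng(4)
    z = rng.standard_normal((50, 400))
    ens = _ensemble(np.zeros(50), np.zeros((50, 400)), z)
    lo, hi = studentized_t_interval(ens, rho_raw=0.5, v_orig=1.0, level=0.95)
    assert lo == pytest.approx(0.5 - 1.96, abs=0.05)
    assert hi == pytest.approx(0.5 + 1.96, abs=0.05)


def test_t_interval_degenerate_replicates_warns():
    ens = _ensemble(np.full(3, 0.4), np.full((3, 40), 0.4), np.zeros((3, 40)))
    with pytest.warns(UserWarning):
        lo, hi = studentized_t_interval(ens, 0.4, 0.01, 0.95)
    assert lo == hi == 0.4


def test_t_interval_level_nesting():
    rng = np.random.default_rng(8)
    z = rng.standard_normal((20, 200))
    ens = _ensemble(np.zeros(20), np.zeros((20, 200)), z)
    lo95, hi95 = studentized_t_interval(ens, 0.3, 0.04, 0.95)
    lo90, hi90 = studentized_t_interval(ens, 0.3, 0.04, 0.90)
    assert lo95 <= lo90 <= hi90 <= hi95


# -- BCa --------------------------------------------------------------------
def test_bca_reduces_to_percentile_when_unbiased_symmetric():
    rho = 0.5
    offsets = np.linspace(-0.2, 0.2, 401)
    offsets = offsets[offsets != 0.0]
    reps = (rho + offsets).reshape(40, 10)
    ens = _ensemble(np.full(40, rho), reps, np.zeros((40, 10)))
    jack = np.array([0.4, 0.5, 0.6])  # symmetric -> acceleration 0
    lo, hi = bca_interval(ens, rho, jack, 0.95)
    plo, phi = np.quantile(reps.ravel(), [0.025, 0.975])
    assert lo == pytest.approx(plo, abs=1e-12)
    assert hi == pytest.approx(phi, abs=1e-12)


def test_bca_one_sided_replicates_falls_back():
    reps = np.full((10, 20), 0.9)
    ens = _ensemble(np.full(10, 0.9), reps, np.zeros((10, 20)))
    with pytest.warns(UserWarning):
        lo, hi = bca_interval(ens, 0.1, np.array([0.1, 0.2, 0.3]), 0.95)
    assert lo == hi == 0.9


def test_bca_gaussian_mean_coverage():
    """Toy problem: BCa interval for a Gaussian mean attains ~95% coverage
    over 500 simulations (within +/- 4%)."""
    rng = np.random.default_rng(17)
    n, n_boot, hits = 25, 600, 0
    for _ in range(500):
        x = rng.normal(0.0, 1.0, n)
        idx = rng.integers(0, n, (n_boot, n))
        boots = x[idx].mean(axis=1).reshape(30, 20)
        ens = _ensemble(np.full(30, x.mean()), boots, np.zeros((30, 20)))
        loo = (x.sum() - x) / (n - 1)  # jackknife replicates of the mean
        lo, hi = bca_interval(ens, float(x.mean()), loo, 0.95)
        hits += lo <= 0.0 <= hi
    assert hits / 500 == pytest.approx(0.95, abs=0.04)


# -- bias and the full report ----------------------------------------------
def test_estimate_bias_values():
    assert estimate_bias(np.full(10, 0.6), 0.6) == pytest.approx(0.0, abs=1e-15)
    assert estimate_bias(np.full(4, 0.5), 0.6) == pytest.approx(-0.1)


def test_report_contracts_and_reproducibility(library, cc):
    panel = _tiny_panel(n=6, seed=2)
    # map 4-species panel onto library species space
    data = panel.data.copy()
    data.columns = library.species_list[:4]
    for extra in library.species_list[4:]:
        data[extra] = 0.0
    panel6 = DietPanel(data)
    # no shared solver: repeatability_with_ci builds its own deterministic one
    kwargs = dict(B=4, R=30, level=0.95, rng=123, variance="per_b")
    rep1 = repeatability_with_ci(panel6, library, cc, **kwargs)
    rep2 = repeatability_with_ci(panel6, library, cc, **kwargs)
    assert rep1.rho_adjusted == pytest.approx(rep1.rho_raw - rep1.d_hat, abs=1e-14)
    for m, ci in rep1.intervals.items():
        assert ci.lower <= ci.upper
        assert ci.lower_shifted == pytest.approx(ci.lower - 2 * rep1.d_hat, abs=1e-14)
        assert ci.upper_shifted == pytest.approx(ci.upper - 2 * rep1.d_hat, abs=1e-14)
        assert 0.0 <= ci.lower_reported <= ci.upper_reported <= 1.0
        assert ci.lower_reported == pytest.approx(rep2.intervals[m].lower_reported, abs=1e-14)
    assert rep1.rho_raw == rep2.rho_raw
    assert rep1.d_hat == rep2.d_hat
    assert np.array_equal(rep1.ensemble.rho_star_star, rep2.ensemble.rho_star_star)
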