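"""Gower centering and sequential distance-based sums of squares.

The key oracle: on univariate responses with Euclidean distance, the
distance-based SS must equal a classical sequential least-squares ANOVA,
for any layout.  An independent cross-check against vegan's adonis2 runs
on a multivariate CS-distance panel.
"""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from comprep.dbanova import balanced_ss_from_d2, gower_center, sequential_ss
from comprep.distance import distance_matrix, pairwise_cs
from comprep.errors import DegenerateDesignError, DomainError, DuplicateObservationError

from conftest import random_compositions, univariate_panel


def classical_sequential_ss(y, preds, times, predator_first=True):
    """Independent oracle: sequential least-squares ANOVA via RSS deltas."""

    def rss(factors):
        x = np.ones((len(y), 1))
        for f in factors:
            x = np.hstack([x, pd.get_dummies(pd.Series(f)).to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return float(resid @ resid)

    first, second = (preds, times) if predator_first else (times, preds)
    rss0 = rss([])
    rss1 = rss([first])
    rss2 = rss([first, second])
    ss_first, ss_second, ss_resid = rss0 - rss1, rss1 - rss2, rss2
    return (ss_first, ss_second, ss_resid) if predator_first else (ss_second, ss_first, ss_resid)


def test_gower_univariate_centering_identity():
    x = np.array([1.0, 2.0, 4.0])
    d = np.abs(x[:, None] - x[None, :])
    g = gower_center(d)
    expected = np.outer(x - x.mean(), x - x.mean())
    assert np.allclose(g, expected, atol=1e-12)


def test_gower_zero_distance():
    assert np.allclose(gower_center(np.zeros((4, 4))), 0.0)


def test_gower_trace_identity(rng):
    x = rng.random((10, 3))
    d = squareform(pdist(x))
    g = gower_center(d)
    brute = sum(d[a, b] ** 2 for a in range(10) for b in range(a + 1, 10)) / 10
    assert np.trace(g) == pytest.approx(brute, rel=1e-10)
    assert np.allclose(g.sum(axis=0), 0.0, atol=1e-9)


def test_gower_rejects_asymmetric():
    with pytest.raises(DomainError):
        gower_center(np.array([[0.0, 1.0], [2.0, 0.0]]))


@pytest.mark.parametrize("missing", [None, {(0, 1), (2, 0), (4, 2)}])
@pytest.mark.parametrize("predator_first", [True, False])
def test_univariate_euclidean_oracle(rng, missing, predator_first):
    """Distance-based sequential SS == classical least-squares ANOVA SS."""
    vals = rng.normal(0, 1, (5, 3)) + rng.normal(0, 1, (5, 1))
    y, preds, times = univariate_panel(vals, missing)
    d = squareform(pdist(y[:, None]))
    order = ("predator", "time") if predator_first else ("time", "predator")
    tab = sequential_ss(gower_center(d), preds, times, order)
    ss_p, ss_t, ss_e = classical_sequential_ss(y, preds, times, predator_first)
    assert tab.ss_predator == pytest.approx(ss_p, abs=1e-10)
    assert tab.ss_time == pytest.approx(ss_t, abs=1e-10)
    assert tab.ss_residual == pytest.approx(ss_e, abs=1e-10)
    # design df sanity on the complete layout
    if missing is None:
        assert (tab.df_predator, tab.df_time, tab.df_residual) == (4, 2, 8)


def test_identical_observations_zero_ss():
    d = np.zeros((6, 6))
    tab = sequential_ss(gower_center(d), list("aabbcc"), list("stststs"[:6]))
    assert tab.ss_total == pytest.approx(0.0, abs=1e-14)


def test_additivity_any_layout(rng):
    q = random_compositions(rng, 11, 6)
    d = pairwise_cs(q)
    g = gower_center(d)
    preds = ["p1"] * 3 + ["p2"] * 2 + ["p3"] * 3 + ["p4"] * 3
    times = ["t1", "t2", "t3", "t1", "t3", "t1", "t2", "t3", "t1", "t2", "t3"]
    tab = sequential_ss(g, preds, times)
    assert tab.ss_predator + tab.ss_time + tab.ss_residual == pytest.approx(
        np.trace(g), rel=1e-10
    )


def test_balanced_order_invariance(rng):
    q = random_compositions(rng, 8, 5)
    g = gower_center(pairwise_cs(q))
    preds = [f"p{i}" for i in range(4) for _ in range(2)]
    times = ["t1", "t2"] * 4
    a = sequential_ss(g, preds, times, ("predator", "time"))
    b = sequential_ss(g, preds, times, ("time", "predator"))
    assert a.ss_predator == pytest.approx(b.ss_predator, abs=1e-10)
    assert a.ss_time == pytest.approx(b.ss_time, abs=1e-10)


def test_distance_scaling_scales_ss(rng):
    q = random_compositions(rng, 8, 5)
    d = pairwise_cs(q)
    preds = [f"p{i}" for i in range(4) for _ in range(2)]
    times = ["t1", "t2"] * 4
    a = sequential_ss(gower_center(d), preds, times)
    b = sequential_ss(gower_center(3.0 * d), preds, times)
    for term in ("ss_predator", "ss_time", "ss_residual"):
        assert getattr(b, term) == pytest.approx(9.0 * getattr(a, term), rel=1e-10)


def test_degenerate_designs():
    g = gower_center(np.ones((4, 4)) - np.eye(4))
    with pytest.raises(DuplicateObservationError):
        sequential_ss(g, ["a", "a", "b", "b"], ["t", "t", "t", "u"])
    with pytest.raises(DegenerateDesignError):
        sequential_ss(g, ["a", "b", "c", "d"], ["t"] * 4)  # single time level
    with pytest.raises(DegenerateDesignError):
        sequential_ss(g, ["a"] * 4, ["t", "u", "v", "w"])  # single predator


def test_balanced_fast_path_equals_projection_path(rng):
    q = random_compositions(rng, 12, 5)
    d = pairwise_cs(q)
    preds = np.repeat(np.arange(6), 2)
    times = np.tile(np.arange(2), 6)
    fast = balanced_ss_from_d2(d * d, preds, times)
    tab = sequential_ss(gower_center(d), [f"p{i}" for i in preds], [f"t{j}" for j in times])
    assert fast[0] == pytest.approx(tab.ss_predator, rel=1e-8, abs=1e-10)
    assert fast[1] == pytest.approx(tab.ss_time, rel=1e-8, abs=1e-10)
    assert fast[2] == pytest.approx(tab.ss_residual, rel=1e-8, abs=1e-10)


_ADONIS_SCRIPT = """
suppressMessages(library(vegan))
args <- commandArgs(trailingOnly=TRUE)
d <- as.dist(as.matrix(read.csv(args[1], row.names=1)))
meta <- read.csv(args[2])
fit <- adonis2(d ~ predator + time, data=meta, permutations=0, by="terms")
write.csv(data.frame(term=rownames(fit), ss=fit$SumOfSqs), args[3], row.names=FALSE)
"""


def test_cross_check_against_vegan_adonis2(tmp_path, unbalanced_panel):
    """Independent PERMANOVA implementation agrees on an unbalanced panel."""
    dm = distance_matrix(unbalanced_panel)
    tab = sequential_ss(
        gower_center(dm.values), unbalanced_panel.predator_labels, unbalanced_panel.time_labels
    )
    labels = [f"o{i}" for i in range(dm.n)]
    pd.DataFrame(dm.values, index=labels, columns=labels).to_csv(tmp_path / "d.csv")
    pd.DataFrame(
        {"predator": unbalanced_panel.predator_labels, "time": unbalanced_panel.time_labels}
    ).to_csv(tmp_path / "meta.csv", index=False)
    script = tmp_path / "adonis.R"
    script.write_text(_ADONIS_SCRIPT)
    subprocess.run(
        ["Rscript", str(script), str(tmp_path / "d.csv"), str(tmp_path / "meta.csv"),
         str(tmp_path / "out.csv")],
        check=True, capture_output=True,
    )
    ref = pd.read_csv(tmp_path / "out.csv").set_index("term")["ss"]
    assert tab.ss_predator == pytest.approx(ref["predator"], rel=1e-6)
    assert tab.ss_time == pytest.approx(ref["time"], rel=1e-6)
    assert tab.ss_residual == pytest.approx(ref["Residual"], rel=1e-6)
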