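"""Nested bootstrap confidence intervals for repeatability of diet estimates.

Two error sources are propagated:

* **sampling error** — predators (clusters) are resampled with replacement,
  each carrying its complete set of repeated diets;
* **measurement error** — diets are QFASA estimates, so before resampling,
  each outer replicate ``b`` regenerates the whole panel as *pseudo-predators*
  (true diet := the observed estimate) and re-estimates their diets.

For b = 1..B pseudo panels and r = 1..R cluster resamples of each, the
repeatabilities ``rho**_{br}`` and studentized pivots
``z_{br} = (rho**_{br} - rho*_b) / sqrt(v_{br})`` are pooled into a single
empirical distribution (B x R replicates).  Intervals:

* studentized T: ``(rho_hat - sqrt(v_orig) q_{1-a/2}(z), rho_hat - sqrt(v_orig) q_{a/2}(z))``;
* BCa: bias factor z0 from the pooled replicate distribution, acceleration
  from delete-one-predator jackknife skewness on the original panel.

The measurement-error bias ``d_hat = mean_b rho*_b - rho_hat`` shifts the
point estimate by ``d_hat`` and (under the assumption that the
pseudo-to-sample and sample-to-truth biases are equal) the interval
endpoints by ``2 d_hat``.  Standard errors come from the delete-one-predator
jackknife.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dbanova import _codes, _sequential_ss_arrays
from .errors import DegenerateDesignError, EstimationError, InsufficientReplicationError
from .panel import DietPanel
from .pseudo import PseudoPredatorConfig, simulate_estimated_panel
from .qfasa import DietSolver, PreyLibrary
from .repeatability import _estimate_from_ss, estimate_repeatability

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapEnsemble",
    "CIReport",
    "cluster_bootstrap",
    "jackknife_variance",
    "jackknife_replicates",
    "studentized_t_interval",
    "bca_interval",
    "estimate_bias",
    "repeatability_with_ci",
]


# ---------------------------------------------------------------------------
# fast repeatability evaluations over subsets of one fixed distance matrix
# ---------------------------------------------------------------------------
class PanelEngine:
    """Repeatability evaluations on cluster subsets of a fixed panel.

    The panel's squared-distance matrix is computed once; cluster resamples
    and jackknife deletions then only select rows/columns, which keeps the
    nested bootstrap loops cheap.  Results agree exactly with
    :func:`comprep.repeatability.estimate_repeatability` on the equivalent
    panel (tested).
    """

    def __init__(self, d2: np.ndarray, predator_labels, time_labels):
        self.d2 = np.asarray(d2, dtype=float)
        pred = np.asarray(predator_labels, dtype=object)
        self.time_codes = _codes(time_labels)
        order: dict = {}
        for p in pred:
            order.setdefault(p, len(order))
        self.clusters = [np.flatnonzero(pred == p) for p in order]
        self.n_clusters = len(self.clusters)

    @classmethod
    def from_panel(cls, panel: DietPanel, metric: str = "chisq") -> "PanelEngine":
        from .distance import distance_matrix

        d = distance_matrix(panel, metric=metric).values
        return cls(d * d, panel.predator_labels, panel.time_labels)

    def _rho(self, idx: np.ndarray, pred_codes: np.ndarray) -> float:
        time_codes = np.unique(self.time_codes[idx], return_inverse=True)[1]
        if time_codes.max() < 1:
            raise DegenerateDesignError("time factor has a single level in subset")
        if pred_codes.max() < 1:
            raise DegenerateDesignError("fewer than 2 predators in subset")
        d2 = self.d2[np.ix_(idx, idx)]
        a = -0.5 * d2
        g = a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()
        ss_p, ss_t, ss_e, *_ = _sequential_ss_arrays(g, pred_codes, time_codes, True)
        k_values = np.bincount(pred_codes).astype(float)
        rho, _, _ = _estimate_from_ss(ss_p, ss_t, ss_e, k_values, ("predator", "time"))
        return float(rho)

    def _subset(self, cluster_positions) -> tuple:
        idx = np.concatenate([self.clusters[c] for c in cluster_positions])
        pred_codes = np.concatenate(
            [np.full(self.clusters[c].size, j) for j, c in enumerate(cluster_positions)]
        )
        return idx, pred_codes

    def rho_full(self) -> float:
        idx, codes = self._subset(range(self.n_clusters))
        return self._rho(idx, codes)

    def rho_clusters(self, cluster_positions) -> float:
        idx, codes = self._subset(cluster_positions)
        return self._rho(idx, codes)

    def jackknife(self) -> tuple[float, np.ndarray]:
        """Delete-one-cluster jackknife (variance, replicates)."""
        n = self.n_clusters
        if n < 3:
            raise DegenerateDesignError("jackknife needs at least 3 predators")
        reps = np.empty(n)
        for i in range(n):
            keep = [c for c in range(n) if c != i]
            reps[i] = self.rho_clusters(keep)
        var = (n - 1) / n * np.sum((reps - reps.mean()) ** 2)
        return float(var), reps


# ---------------------------------------------------------------------------
# public resampling operations
# ---------------------------------------------------------------------------
def cluster_bootstrap(panel: DietPanel, rng: np.random.Generator) -> DietPanel:
    """Resample predators with replacement, carrying each predator's complete
    set of diets (and missingness); duplicates receive fresh ids."""
    if panel.n < 2:
        raise DegenerateDesignError("cluster bootstrap needs at least 2 predators")
    preds = panel.predators
    picks = rng.integers(0, len(preds), size=len(preds))
    return panel.select_predators([preds[i] for i in picks])


def jackknife_replicates(panel: DietPanel, statistic) -> np.ndarray:
    """statistic(panel minus predator i) for each predator i."""
    if panel.n < 3:
        raise DegenerateDesignError("jackknife needs at least 3 predators")
    reps = []
    for p in panel.predators:
        try:
            reps.append(float(statistic(panel.drop_predator(p))))
        except Exception as exc:  # propagate with context
            raise EstimationError(f"statistic failed with predator {p!r} deleted") from exc
    return np.asarray(reps)


def jackknife_variance(panel: DietPanel, statistic) -> float:
    """Delete-one-predator jackknife variance of a panel statistic."""
    reps = jackknife_replicates(panel, statistic)
    n = reps.size
    return float((n - 1) / n * np.sum((reps - reps.mean()) ** 2))


# ---------------------------------------------------------------------------
# ensembles and intervals
# ---------------------------------------------------------------------------
@dataclass
class BootstrapEnsemble:
    """All replicates of one nested bootstrap run (NaN = failed fit)."""

    B: int
    R: int
    rho_star: np.ndarray  # (B,)
    rho_star_star: np.ndarray  # (B, R)
    z_values: np.ndarray  # (B, R) studentized pivots
    v_values: np.ndarray  # (B, R) pivot variances
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rho_star.shape != (self.B,) or self.rho_star_star.shape != (self.B, self.R):
            raise ValueError("ensemble dimensions inconsistent")

    @property
    def n_replicates(self) -> int:
        return self.B * self.R

    @property
    def n_failed(self) -> int:
        return int(np.isnan(self.rho_star_star).sum() + np.isnan(self.rho_star).sum())


def _pooled(values: np.ndarray) -> np.ndarray:
    flat = np.asarray(values, dtype=float).ravel()
    return flat[np.isfinite(flat)]


def studentized_t_interval(
    ensemble: BootstrapEnsemble, rho_raw: float, v_orig: float, level: float = 0.95
) -> tuple[float, float]:
    """Bootstrap-T interval from the pooled studentized pivots."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if v_orig <= 0:
        raise ValueError("v_orig must be positive")
    z = _pooled(ensemble.z_values)
    if z.size == 0:
        raise EstimationError("no finite pivots in ensemble")
    if np.allclose(z, z[0]):
        warnings.warn("degenerate pivot distribution: zero-width interval")
        return (rho_raw, rho_raw)
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(z, [alpha / 2, 1 - alpha / 2])  # type-7 (linear)
    se = float(np.sqrt(v_orig))
    return (rho_raw - se * q_hi, rho_raw - se * q_lo)


def bca_interval(
    ensemble: BootstrapEnsemble,
    rho_raw: float,
    jackknife_reps: np.ndarray,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval on the pooled
    replicate distribution; acceleration from jackknife skewness."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    reps = _pooled(ensemble.rho_star_star)
    if reps.size < 100:
        raise EstimationError("BCa needs at least 100 pooled replicates")
    alpha = 1.0 - level
    prop = np.mean(reps < rho_raw)
    if prop <= 0.0 or prop >= 1.0:
        warnings.warn("all bootstrap replicates on one side of the estimate; "
                      "falling back to the percentile interval")
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        return (float(lo), float(hi))
    z0 = norm.ppf(prop)
    jk = np.asarray(jackknife_reps, dtype=float)
    dev = jk.mean() - jk
    denom = np.sum(dev**2) ** 1.5
    a = float(np.sum(dev**3) / (6.0 * denom)) if denom > 0 else 0.0
    out = []
    for z_alpha in (norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        out.append(float(np.quantile(reps, norm.cdf(adj))))
    return (out[0], out[1])


def estimate_bias(rho_star, rho_raw: float) -> float:
    """Measurement-error bias d_hat = mean_b(rho*_b) - rho_hat."""
    star = _pooled(np.asarray(rho_star, dtype=float))
    if star.size == 0:
        raise ValueError("need at least one pseudo-panel repeatability")
    return float(star.mean() - rho_raw)


@dataclass
class CIMethodResult:
    method: str
    lower: float
    upper: float
    lower_shifted: float
    upper_shifted: float
    lower_reported: float
    upper_reported: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CIReport:
    """Raw and bias-adjusted repeatability with shifted bootstrap intervals."""

    rho_raw: float
    d_hat: float
    rho_adjusted: float
    level: float
    intervals: dict
    truncated: bool
    n_failed: int
    seed: int | None = None
    ensemble: BootstrapEnsemble | None = field(default=None, repr=False)
    estimate: object | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "rho_raw": self.rho_raw,
            "d_hat": self.d_hat,
            "rho_adjusted": self.rho_adjusted,
            "level": self.level,
            "truncated": self.truncated,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "intervals": {k: v.to_dict() for k, v in self.intervals.items()},
        }
        if self.estimate is not None:
            out["point_estimate"] = self.estimate.to_dict()
        return out


def repeatability_with_ci(
    panel: DietPanel,
    library: PreyLibrary,
    cc,
    B: int = 100,
    R: int = 100,
    level: float = 0.95,
    methods: tuple = ("t", "bca"),
    config: PseudoPredatorConfig | None = None,
    rng: np.random.Generator | int | None = None,
    variance: str = "per_br",
    truncate: bool = True,
    solver: DietSolver | None = None,
    metric: str = "chisq",
) -> CIReport:
    """Point estimate, bias correction and nested-bootstrap CIs in one call.

    ``variance`` selects the pivot variance: ``"per_br"`` (delete-one-predator
    jackknife inside every cluster resample; self-studentizing, default) or
    ``"per_b"`` (one jackknife per pseudo panel; cheaper).
    Intervals are shifted by ``2 d_hat``; reported endpoints are truncated to
    [0, 1] when ``truncate`` (both versions are kept in the result).
    """
    if B < 2 or R < 2:
        raise ValueError("need B >= 2 and R >= 2")
    if variance not in ("per_br", "per_b"):
        raise ValueError(f"unknown variance mode {variance!r}")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(rng) if rng is not None else None
        rng = np.random.default_rng(rng)
    config = config or PseudoPredatorConfig()
    if solver is None:
        solver = DietSolver(library, cc)

    est = estimate_repeatability(panel, metric=metric)
    rho_raw = est.rho_hat
    engine = PanelEngine.from_panel(panel, metric=metric)
    v_orig, jack_reps = engine.jackknife()
    if v_orig <= 0:
        raise EstimationError("jackknife variance of the original panel is zero")

    rho_star = np.full(B, np.nan)
    rho_ss = np.full((B, R), np.nan)
    z_vals = np.full((B, R), np.nan)
    v_vals = np.full((B, R), np.nan)
    n_clusters = engine.n_clusters
    failures = 0
    for b in range(B):
        try:
            pseudo = simulate_estimated_panel(panel, library, cc, config, rng, solver)
            eng_b = PanelEngine.from_panel(pseudo, metric=metric)
            rho_star[b] = eng_b.rho_full()
            if variance == "per_b":
                v_b, _ = eng_b.jackknife()
        except (DegenerateDesignError, InsufficientReplicationError, EstimationError) as exc:
            logger.warning("pseudo panel %d failed: %s", b, exc)
            failures += R
            continue
        for r in range(R):
            picks = rng.integers(0, n_clusters, size=n_clusters)
            try:
                rho_ss[b, r] = eng_b.rho_clusters(picks)
                if variance == "per_br":
                    reps = np.empty(n_clusters)
                    for i in range(n_clusters):
                        reps[i] = eng_b.rho_clusters(np.delete(picks, i))
                    v_br = (n_clusters - 1) / n_clusters * np.sum((reps - reps.mean()) ** 2)
                else:
                    v_br = v_b
                if v_br > 0:
                    v_vals[b, r] = v_br
                    z_vals[b, r] = (rho_ss[b, r] - rho_star[b]) / np.sqrt(v_br)
                else:
                    failures += 1
            except (DegenerateDesignError, InsufficientReplicationError) as exc:
                logger.debug("resample (%d, %d) failed: %s", b, r, exc)
                failures += 1
    if failures > 0.05 * B * R:
        raise EstimationError(f"{failures} of {B * R} bootstrap fits failed (> 5%)")
    if failures:
        logger.info("dropped %d failed bootstrap fits", failures)

    ensemble = BootstrapEnsemble(B, R, rho_star, rho_ss, z_vals, v_vals, seed)
    d_hat = estimate_bias(rho_star, rho_raw)
    shift = 2.0 * d_hat
    intervals: dict = {}
    for method in methods:
        if method == "t":
            lo, hi = studentized_t_interval(ensemble, rho_raw, v_orig, level)
        elif method == "bca":
            lo, hi = bca_interval(ensemble, rho_raw, jack_reps, level)
        else:
            raise ValueError(f"unknown CI method {method!r}")
        lo_s, hi_s = lo - shift, hi - shift
        if truncate:
            lo_r, hi_r = min(max(lo_s, 0.0), 1.0), min(max(hi_s, 0.0), 1.0)
            if (lo_r, hi_r) != (lo_s, hi_s):
                logger.info("%s interval truncated to [0, 1]: (%.4f, %.4f)", method, lo_s, hi_s)
        else:
            lo_r, hi_r = lo_s, hi_s
        intervals[method] = CIMethodResult(method, lo, hi, lo_s, hi_s, lo_r, hi_r)
    return CIReport(
        rho_raw=rho_raw,
        d_hat=d_hat,
        rho_adjusted=rho_raw - d_hat,
        level=level,
        intervals=intervals,
        truncated=truncate,
        n_failed=failures,
        seed=seed,
        ensemble=ensemble,
        estimate=est,
    )
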