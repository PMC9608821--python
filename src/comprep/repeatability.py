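"""Repeatability (intraclass correlation) of compositional repeated measures.

The population repeatability of a two-way (individual x time) layout is

    rho = sigma_s^2 / (sigma_s^2 + theta_t + sigma_e^2),

the share of total variance attributable to differences among individuals,
where ``theta_t = sum_j t_j^2 / (k - 1)`` summarizes fixed time effects.  The
balanced estimator plugs in mean squares from the (distance-based) two-way
ANOVA:

    rho_hat = (MSs - MSe) / (MSs + (k-1) MSe + (k/n)(MSt - MSe)).

With unequal per-individual counts k_i the harmonic mean
``k_tilde = n / sum_i (1/k_i)`` replaces k, and the mean squares are formed
from the *sequential* sums of squares with modified degrees of freedom

    df_s = n - 1,  df_t = k_tilde - 1,  df_e = (sum_i k_i) - 1 - df_s - df_t,

which reduce to the classical balanced df when every k_i = k.  Estimates are
never clamped to [0, 1]: negative values are reported as-is so that bootstrap
distributions built on top of them stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dbanova import AnovaTable, gower_center, sequential_ss
from .distance import DistanceMatrix, distance_matrix
from .errors import DegenerateDesignError, DomainError, InsufficientReplicationError
from .panel import DietPanel

__all__ = [
    "harmonic_k",
    "rho_balanced",
    "rho_unbalanced",
    "estimate_repeatability",
    "repeatability_from_distance",
    "RepeatabilityEstimate",
]


def harmonic_k(k_values) -> float:
    """Harmonic mean of per-predator observation counts, n / sum(1/k_i)."""
    k = np.asarray(list(k_values), dtype=float)
    if k.size == 0:
        raise DomainError("empty k_values")
    if (k < 1).any():
        raise DomainError("every k_i must be >= 1")
    return float(k.size / np.sum(1.0 / k))


def _rho_formula(ms_s: float, ms_t: float, ms_e: float, n: float, k: float) -> float:
    denom = ms_s + (k - 1.0) * ms_e + (k / n) * (ms_t - ms_e)
    if denom == 0:
        raise DegenerateDesignError("degenerate repeatability estimate: zero denominator")
    return (ms_s - ms_e) / denom


def rho_balanced(anova: AnovaTable, n: int, k: int) -> float:
    """Balanced two-way mixed-model ICC from an ANOVA table's mean squares."""
    if n < 2 or k < 2:
        raise DegenerateDesignError("need n >= 2 predators and k >= 2 time points")
    return _rho_formula(anova.ms_predator, anova.ms_time, anova.ms_residual, n, k)


def rho_unbalanced(anova: AnovaTable, k_values) -> float:
    """Unbalanced ICC: harmonic-mean k_tilde and modified degrees of freedom.

    ``anova`` must come from a sequential fit with the predator factor
    entered first; only its sums of squares are used (its design df are
    replaced by the k_tilde-based df).
    """
    k = np.asarray(list(k_values), dtype=float)
    n = k.size
    if n < 2:
        raise DegenerateDesignError("need n >= 2 predators")
    k_tilde = harmonic_k(k)
    df_s = n - 1.0
    df_t = k_tilde - 1.0
    df_e = k.sum() - 1.0 - df_s - df_t
    if df_e <= 0:
        raise InsufficientReplicationError(f"residual df {df_e:.3f} <= 0")
    ms_s = anova.ss_predator / df_s
    ms_t = anova.ss_time / df_t
    ms_e = anova.ss_residual / df_e
    return _rho_formula(ms_s, ms_t, ms_e, n, k_tilde)


@dataclass
class RepeatabilityEstimate:
    """Point estimate of repeatability together with the ANOVA it came from."""

    rho_hat: float
    design: str  # "balanced" | "unbalanced"
    n: int
    k_values: pd.Series
    k_effective: float
    anova: AnovaTable

    def to_dict(self) -> dict:
        return {
            "rho_hat": self.rho_hat,
            "design": self.design,
            "n": self.n,
            "k_values": [int(v) for v in self.k_values],
            "k_effective": self.k_effective,
            "anova": self.anova.to_frame().to_dict(orient="records"),
        }


def _estimate_from_ss(ss_p, ss_t, ss_e, k_values: np.ndarray, order) -> tuple:
    """rho and the Eq-style AnovaTable given sequential SS and counts."""
    n = k_values.size
    k_tilde = harmonic_k(k_values)
    df_s = n - 1.0
    df_t = k_tilde - 1.0
    df_e = k_values.sum() - 1.0 - df_s - df_t
    if df_e <= 0:
        raise InsufficientReplicationError(f"residual df {df_e:.3f} <= 0")
    table = AnovaTable(ss_p, ss_t, ss_e, df_s, df_t, df_e, tuple(order))
    rho = _rho_formula(table.ms_predator, table.ms_time, table.ms_residual, n, k_tilde)
    return rho, table, k_tilde


def repeatability_from_distance(
    dist: DistanceMatrix | np.ndarray,
    predator_labels=None,
    time_labels=None,
    order: tuple = ("predator", "time"),
) -> RepeatabilityEstimate:
    """Repeatability from an arbitrary distance matrix over labelled cells.

    Accepts either a :class:`DistanceMatrix` (labels taken from its ids) or a
    plain square array plus explicit label vectors.  This is the hook for
    non-compositional responses (e.g. univariate Euclidean oracle checks).
    """
    if isinstance(dist, DistanceMatrix):
        d = dist.values
        if predator_labels is None:
            predator_labels = [p for p, _ in dist.ids]
        if time_labels is None:
            time_labels = [t for _, t in dist.ids]
    else:
        d = np.asarray(dist, dtype=float)
        if predator_labels is None or time_labels is None:
            raise ValueError("labels required with a raw distance array")
    g = gower_center(d)
    table = sequential_ss(g, predator_labels, time_labels, order)
    pred = np.asarray(predator_labels, dtype=object)
    k_series = pd.Series(pred).groupby(pred, sort=False).size()
    k_values = k_series.to_numpy(dtype=float)
    rho, eq_table, k_tilde = _estimate_from_ss(
        table.ss_predator, table.ss_time, table.ss_residual, k_values, order
    )
    balanced = bool((k_values == k_values[0]).all())
    return RepeatabilityEstimate(
        rho_hat=float(rho),
        design="balanced" if balanced else "unbalanced",
        n=int(k_values.size),
        k_values=k_series,
        k_effective=float(k_tilde),
        anova=eq_table,
    )


def estimate_repeatability(
    panel: DietPanel,
    metric: str = "chisq",
    order: tuple = ("predator", "time"),
) -> RepeatabilityEstimate:
    """Repeatability of a diet panel: CS distances, Gower centering,
    sequential SS (predator first by default), then the balanced or
    unbalanced estimator depending on the panel's occupancy."""
    if panel.n < 2:
        raise DegenerateDesignError("need at least 2 predators")
    if len(panel.times) < 2:
        raise DegenerateDesignError("need at least 2 time levels")
    dm = distance_matrix(panel, metric=metric)
    return repeatability_from_distance(dm, order=order)
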