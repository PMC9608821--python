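"""Distance-based two-way crossed ANOVA without replication.

Sums of squares are obtained from a distance matrix by Gower centering
(the McArdle–Anderson trace formulation): with ``A = -0.5 * D∘D`` and the
centering matrix ``C = I - 11'/N``, the inner-product matrix is ``G = C A C``
and the sum of squares attributable to a design matrix X with hat matrix H is
``tr(H G)``.  Factors are entered *sequentially* (nested projections), which
matters when the layout is unbalanced: the convention here, configurable, is
predator first, then time.

Permutation-based significance testing is deliberately out of scope; only the
sums of squares and mean squares are needed for repeatability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orth

from .errors import (
    DegenerateDesignError,
    DimensionError,
    DomainError,
    DuplicateObservationError,
)

__all__ = ["AnovaTable", "gower_center", "sequential_ss", "balanced_ss_from_d2"]

_FACTORS = ("predator", "time")


@dataclass
class AnovaTable:
    """Sequential SS/df/MS for the predator, time and residual terms.

    Degrees of freedom may be non-integer: the unbalanced repeatability
    estimator replaces the design df of the time term with ``k_tilde - 1``
    (harmonic-mean based) and adjusts the residual df accordingly.
    """

    ss_predator: float
    ss_time: float
    ss_residual: float
    df_predator: float
    df_time: float
    df_residual: float
    term_order: tuple = _FACTORS

    def __post_init__(self) -> None:
        for name in ("df_predator", "df_time", "df_residual"):
            if getattr(self, name) <= 0:
                raise DegenerateDesignError(f"{name} = {getattr(self, name)} must be > 0")

    @property
    def ss_total(self) -> float:
        return self.ss_predator + self.ss_time + self.ss_residual

    @property
    def ms_predator(self) -> float:
        return self.ss_predator / self.df_predator

    @property
    def ms_time(self) -> float:
        return self.ss_time / self.df_time

    @property
    def ms_residual(self) -> float:
        return self.ss_residual / self.df_residual

    def with_df(self, df_predator, df_time, df_residual) -> "AnovaTable":
        """Same SS with overridden degrees of freedom."""
        return AnovaTable(
            self.ss_predator,
            self.ss_time,
            self.ss_residual,
            df_predator,
            df_time,
            df_residual,
            self.term_order,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term in self.term_order:
            rows.append((term, getattr(self, f"ss_{term}"), getattr(self, f"df_{term}"),
                         getattr(self, f"ms_{term}")))
        rows.append(("residual", self.ss_residual, self.df_residual, self.ms_residual))
        rows.append(("total", self.ss_total, float("nan"), float("nan")))
        return pd.DataFrame(rows, columns=["term", "ss", "df", "ms"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = C (-0.5 D∘D) C.

    Rows and columns of G sum to zero, and ``tr(G)`` equals the total sum of
    squared distances divided by N.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DimensionError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise DomainError("distance matrix must be symmetric")
    a = -0.5 * d * d
    row_mean = a.mean(axis=0, keepdims=True)
    col_mean = a.mean(axis=1, keepdims=True)
    return a - row_mean - col_mean + a.mean()


def _codes(labels) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels, dtype=object).astype(str), return_inverse=True)
    return codes


def _dummies(codes: np.ndarray) -> np.ndarray:
    n_levels = codes.max() + 1
    x = np.zeros((codes.size, n_levels))
    x[np.arange(codes.size), codes] = 1.0
    return x


def _sequential_ss_arrays(
    g: np.ndarray, pred_codes: np.ndarray, time_codes: np.ndarray, predator_first: bool
):
    """Core trace computation; returns (ss_pred, ss_time, ss_resid, design dfs)."""
    n = g.shape[0]
    xp = _dummies(pred_codes)
    xt = _dummies(time_codes)
    first, second = (xp, xt) if predator_first else (xt, xp)
    ones = np.ones((n, 1))
    # nested orthonormal bases: intercept ⊂ intercept+first ⊂ intercept+both
    u1 = orth(np.hstack([ones, first]))
    u2 = orth(np.hstack([ones, first, second]))
    tr_g = float(np.trace(g))
    tr0 = float(g.mean() * n)  # tr(H0 G) with H0 = 11'/n
    tr1 = float(np.sum(u1 * (g @ u1)))
    tr2 = float(np.sum(u2 * (g @ u2)))
    ss_first = tr1 - tr0
    ss_second = tr2 - tr1
    ss_resid = tr_g - tr2
    df_first = u1.shape[1] - 1
    df_second = u2.shape[1] - u1.shape[1]
    df_resid = n - u2.shape[1]
    if predator_first:
        return ss_first, ss_second, ss_resid, df_first, df_second, df_resid
    return ss_second, ss_first, ss_resid, df_second, df_first, df_resid


def sequential_ss(
    g: np.ndarray,
    predator_labels,
    time_labels,
    order: tuple = _FACTORS,
) -> AnovaTable:
    """Sequential sums of squares from a Gower-centered matrix.

    ``order`` gives the entry order of the two factors; the degrees of
    freedom recorded here are the design ranks (diagnostic), which the
    unbalanced repeatability estimator later overrides.
    """
    g = np.asarray(g, dtype=float)
    pred = np.asarray(predator_labels, dtype=object)
    time = np.asarray(time_labels, dtype=object)
    if not (g.shape[0] == pred.size == time.size):
        raise DimensionError("labels must align with the centered matrix rows")
    if tuple(order) not in ((_FACTORS), ("time", "predator"), ("predator", "time")):
        raise ValueError(f"order must be a permutation of {_FACTORS}, got {order!r}")
    cells = list(zip(pred, time))
    if len(set(cells)) != len(cells):
        raise DuplicateObservationError("duplicated (predator, time) cells")
    pred_codes = _codes(pred)
    time_codes = _codes(time)
    if pred_codes.max() < 1:
        raise DegenerateDesignError("predator factor has a single level")
    if time_codes.max() < 1:
        raise DegenerateDesignError("time factor has a single level")
    predator_first = tuple(order)[0] == "predator"
    ss_p, ss_t, ss_e, df_p, df_t, df_e = _sequential_ss_arrays(
        g, pred_codes, time_codes, predator_first
    )
    if df_e <= 0:
        raise DegenerateDesignError("saturated design: no residual degrees of freedom")
    return AnovaTable(ss_p, ss_t, ss_e, df_p, df_t, df_e, tuple(order))


def balanced_ss_from_d2(d2: np.ndarray, pred_codes: np.ndarray, time_codes: np.ndarray):
    """(ss_pred, ss_time, ss_resid) for a complete balanced layout, O(N^2).

    Uses the Huygens identities on squared distances: the total SS is the
    mean over all pairs, and each factor SS is the total minus the pooled
    within-group SS of that factor.  Valid only when every predator is
    observed at every time (orthogonal design); agrees with
    :func:`sequential_ss` there.
    """
    d2 = np.asarray(d2, dtype=float)
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)

    def within(codes: np.ndarray) -> float:
        total = 0.0
        for c in np.unique(codes):
            idx = np.flatnonzero(codes == c)
            total += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
        return total

    ss_pred = ss_total - within(pred_codes)
    ss_time = ss_total - within(time_codes)
    ss_resid = ss_total - ss_pred - ss_time
    return ss_pred, ss_time, ss_resid
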