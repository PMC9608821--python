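"""Chi-square (CS) distance for compositions with essential zeros.

The CS distance between two compositions ``p1``, ``p2`` over M components is

    CS(p1, p2) = c * sqrt( sum_m r_m ),   c = sqrt(2 / M),

where, writing ``q1``, ``q2`` for the sum-normalized vectors,

    r_m = 0                                  if q1_m = q2_m = 0
    r_m = (q1_m - q2_m)^2 / (q1_m + q2_m)    otherwise.

The inner sum is the triangular discrimination between q1 and q2; its square
root is a metric, so CS is a metric on the simplex that tolerates exact zeros
(unlike Aitchison-type log-ratio distances).  This is *not* the
correspondence-analysis chi-square distance: no column standardization over
observations is performed.  The leading constant cancels from every
repeatability estimate downstream, so only raw distance values depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, DomainError
from .panel import DietPanel

__all__ = ["cs_distance", "pairwise_cs", "distance_matrix", "DistanceMatrix"]


def _normalize(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise DimensionError(f"{name} must be a vector of length >= 2")
    if not np.isfinite(p).all():
        raise DomainError(f"{name} contains non-finite values")
    if (p < 0).any():
        raise DomainError(f"{name} contains negative components")
    s = p.sum()
    if s <= 0:
        raise DomainError(f"{name} has zero sum")
    return p / s


def cs_distance(p1, p2) -> float:
    """CS distance between two compositions (scale-invariant in each input)."""
    q1 = _normalize(p1, "p1")
    q2 = _normalize(p2, "p2")
    if q1.size != q2.size:
        raise DimensionError(f"length mismatch: {q1.size} vs {q2.size}")
    m = q1.size
    num = (q1 - q2) ** 2
    den = q1 + q2
    # both-zero components contribute 0 by definition (exact-zero rule)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(np.sqrt((2.0 / m) * r.sum()))


def pairwise_cs(compositions: np.ndarray) -> np.ndarray:
    """Pairwise CS distance matrix for rows of ``compositions``.

    Rows are sum-normalized first; the result is symmetric with zero diagonal.
    """
    q = np.asarray(compositions, dtype=float)
    if q.ndim != 2:
        raise DimensionError("expected a 2-d array of compositions")
    if (q < 0).any():
        raise DomainError("negative components")
    sums = q.sum(axis=1)
    if (sums <= 0).any():
        raise DomainError("zero-sum rows")
    q = q / sums[:, None]
    n, m = q.shape
    d2 = np.empty((n, n))
    # row-blocked O(N^2 M); avoids allocating an N*N*M cube for large panels
    block = max(1, int(4e6 // (n * m + 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        diff2 = (q[start:stop, None, :] - q[None, :, :]) ** 2
        den = q[start:stop, None, :] + q[None, :, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, diff2 / np.where(den > 0, den, 1.0), 0.0)
        d2[start:stop] = (2.0 / m) * r.sum(axis=2)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.maximum(d2, 0.0))
    return (d + d.T) / 2.0


@dataclass
class DistanceMatrix:
    """Square distance matrix over the observed cells of a panel."""

    values: np.ndarray
    ids: list  # (predator_id, time_label) per row/column

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise DimensionError("ids do not match matrix size")
        if not np.isfinite(v).all():
            raise DomainError("non-finite distances")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DomainError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise DomainError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise DomainError("distances must be nonnegative")
        self.values = np.maximum(v, 0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{p}:{t}" for p, t in self.ids]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def distance_matrix(panel: DietPanel, metric: str = "chisq") -> DistanceMatrix:
    """Distance matrix between all observed diet estimates of a panel.

    ``metric`` is ``"chisq"`` (CS distance, default) or ``"euclidean"``
    (plain Euclidean on the normalized rows, useful for oracle checks).
    """
    q = panel.values()
    if metric == "chisq":
        d = pairwise_cs(q)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(q, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(d, panel.cell_ids())
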