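"""QFASA diet estimation.

Quantitative fatty acid signature analysis (QFASA) estimates a predator's
diet as the simplex mixture of mean prey FA signatures that best matches the
predator's calibrated signature.  The steps are:

1. calibrate the predator signature: divide by per-FA calibration
   coefficients (from controlled feeding studies) and renormalize;
2. minimize a distance between the calibrated signature and a convex
   combination ``m(alpha) = sum_s alpha_s * mu_s`` of species-mean prey
   signatures over the simplex ``alpha >= 0, sum alpha = 1``;
3. convert the FA-space mixture to diet proportions by weighting with the
   per-species fat content: ``pi_s = (alpha_s / fat_s) / sum_c (alpha_c / fat_c)``.

The default objective is the symmetric Kullback–Leibler-type divergence
``sum_f (q_f - m_f) log(q_f / m_f)`` with components floored at 1e-6 and
renormalized before taking logs; it is convex in the mixture weights.  A
squared-CS and an Aitchison (clr-Euclidean on floored values) objective are
also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import DomainError, EstimationError, SchemaError

__all__ = [
    "PreyLibrary",
    "DietEstimate",
    "DietSolver",
    "calibrate_signature",
    "estimate_diet",
    "read_calibration",
]

_FLOOR = 1e-6


def _floor_renorm(v: np.ndarray, floor: float = _FLOOR) -> np.ndarray:
    v = np.maximum(np.asarray(v, dtype=float), floor)
    return v / v.sum()


@dataclass
class PreyLibrary:
    """Per-individual prey FA signatures with species labels and fat content.

    Parameters
    ----------
    signatures : pandas.DataFrame
        One row per prey individual, one column per fatty acid; rows are
        renormalized to sum to 1.
    species : pandas.Series
        Species label per individual (same index as ``signatures``).
    fat : pandas.Series
        Per-species lipid content (percent), strictly positive.
    """

    signatures: pd.DataFrame
    species: pd.Series
    fat: pd.Series

    def __post_init__(self) -> None:
        if self.signatures.shape[1] < 2:
            raise DomainError("need at least 2 fatty acids")
        if not self.signatures.index.equals(self.species.index):
            raise SchemaError("species labels must be indexed like the signature rows")
        vals = self.signatures.to_numpy(dtype=float)
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise DomainError("signatures must be finite and nonnegative")
        sums = vals.sum(axis=1)
        if (sums <= 0).any():
            raise DomainError("zero-sum signature rows")
        self.signatures = pd.DataFrame(
            vals / sums[:, None], index=self.signatures.index, columns=self.signatures.columns
        )
        sp = pd.unique(self.species)
        if len(sp) < 2:
            raise DomainError("need at least 2 prey species")
        missing_fat = [s for s in sp if s not in self.fat.index]
        if missing_fat:
            raise SchemaError(f"species without fat content: {missing_fat}")
        if (self.fat.loc[list(sp)] <= 0).any():
            raise DomainError("fat content must be strictly positive")
        self.fat = self.fat.loc[list(sp)].astype(float)

    @property
    def species_list(self) -> list:
        return list(self.fat.index)

    @property
    def fa_labels(self) -> list:
        return list(self.signatures.columns)

    def species_means(self) -> pd.DataFrame:
        """Species-mean signatures (rows renormalized), species x FA."""
        means = self.signatures.groupby(self.species, sort=False).mean()
        means = means.div(means.sum(axis=1), axis=0)
        return means.reindex(self.species_list)

    def individuals_of(self, species) -> pd.DataFrame:
        mask = (self.species == species).to_numpy()
        if not mask.any():
            raise KeyError(f"species {species!r} not in library")
        return self.signatures.loc[mask]

    def restrict_fa(self, fa_subset) -> "PreyLibrary":
        """Library restricted to an FA subset (rows renormalized again)."""
        missing = [f for f in fa_subset if f not in self.signatures.columns]
        if missing:
            raise SchemaError(f"unknown fatty acids: {missing}")
        return PreyLibrary(self.signatures[list(fa_subset)].copy(), self.species, self.fat)


def _align(y, labels, what: str) -> np.ndarray:
    if isinstance(y, pd.Series):
        if list(y.index) != list(labels):
            raise SchemaError(f"{what}: FA labels do not match")
        return y.to_numpy(dtype=float)
    arr = np.asarray(y, dtype=float)
    if arr.size != len(labels):
        raise SchemaError(f"{what}: expected {len(labels)} components, got {arr.size}")
    return arr


def calibrate_signature(y, cc) -> pd.Series | np.ndarray:
    """Calibrated predator signature (y_f / cc_f), renormalized.

    Exact zeros stay exactly zero.  ``y`` and ``cc`` must share FA labels
    when given as pandas Series.
    """
    if isinstance(y, pd.Series) and isinstance(cc, pd.Series):
        if list(y.index) != list(cc.index):
            raise SchemaError("calibration: FA labels do not match")
        labels = y.index
    else:
        labels = None
    yv = np.asarray(y, dtype=float)
    cv = np.asarray(cc, dtype=float)
    if yv.size != cv.size:
        raise SchemaError("calibration vector length mismatch")
    if (cv <= 0).any():
        raise DomainError("calibration coefficients must be strictly positive")
    if (yv < 0).any():
        raise DomainError("signature components must be nonnegative")
    out = yv / cv
    s = out.sum()
    if s <= 0:
        raise DomainError("calibrated signature has zero sum")
    out = out / s
    if labels is not None:
        return pd.Series(out, index=labels)
    return out


@dataclass
class DietEstimate:
    """Result of a QFASA fit."""

    diet: pd.Series  # fat-weighted proportions over species
    alpha: pd.Series  # FA-space mixture weights over species
    objective_value: float
    converged: bool


class DietSolver:
    """Reusable QFASA solver bound to one prey library and calibration.

    Building the solver once amortizes the species-mean and flooring work
    across the many fits done in bootstrap and simulation loops.
    """

    def __init__(
        self,
        library: PreyLibrary,
        cc,
        objective: str = "kl",
        n_restarts: int = 5,
        tol: float = 1e-8,
        seed: int = 0,
        floor: float = _FLOOR,
    ):
        self.library = library
        self.objective = objective
        self.n_restarts = int(n_restarts)
        self.tol = float(tol)
        self.floor = float(floor)
        self._rng = np.random.default_rng(seed)
        self.cc = _align(cc, library.fa_labels, "calibration")
        if (self.cc <= 0).any():
            raise DomainError("calibration coefficients must be strictly positive")
        means = library.species_means().to_numpy(dtype=float)
        # floor + renormalize species means once: mixtures stay on the simplex
        self.a_matrix = np.stack([_floor_renorm(row, floor) for row in means], axis=1)  # F x S
        self.n_species = self.a_matrix.shape[1]
        self.fat = library.fat.to_numpy(dtype=float)
        if objective not in ("kl", "cs", "aitchison"):
            raise ValueError(f"unknown objective {objective!r}")

    # objective and gradient in mixture space m = A @ alpha
    def _f_grad_m(self, q: np.ndarray, m: np.ndarray):
        if self.objective == "kl":
            logr = np.log(q / m)
            f = float(np.sum((q - m) * logr))
            g = -q / m - logr + 1.0
        elif self.objective == "cs":
            u = q - m
            v = q + m
            f = float(np.sum(u * u / v))
            g = (-2.0 * u * v - u * u) / (v * v)
        else:  # aitchison (clr Euclidean)
            e = np.log(m) - np.log(q)
            e = e - e.mean()
            f = float(np.sum(e * e))
            g = 2.0 * e / m
        return f, g

    def solve(self, y) -> DietEstimate:
        """Estimate the diet of one predator signature."""
        yv = _align(y, self.library.fa_labels, "predator signature")
        q = _floor_renorm(calibrate_signature(yv, self.cc), self.floor)
        a = self.a_matrix

        def fun(alpha):
            m = a @ alpha
            f, gm = self._f_grad_m(q, m)
            return f, a.T @ gm

        s = self.n_species
        starts = [np.full(s, 1.0 / s)]
        for _ in range(self.n_restarts):
            starts.append(self._rng.dirichlet(np.ones(s)))
        best = None
        any_success = False
        for x0 in starts:
            res = minimize(
                fun,
                x0,
                jac=True,
                method="SLSQP",
                bounds=[(0.0, 1.0)] * s,
                constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0,
                              "jac": lambda x: np.ones_like(x)}],
                options={"maxiter": 300, "ftol": self.tol},
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if not any_success:
            raise EstimationError(
                f"diet optimizer failed after {len(starts)} starts: {best.message}"
            )
        alpha = np.clip(best.x, 0.0, None)
        alpha[alpha < 1e-10] = 0.0  # essential zeros
        alpha = alpha / alpha.sum()
        diet = alpha / self.fat
        diet = diet / diet.sum()
        sp = self.library.species_list
        return DietEstimate(
            diet=pd.Series(diet, index=sp),
            alpha=pd.Series(alpha, index=sp),
            objective_value=float(best.fun),
            converged=True,
        )


def estimate_diet(
    y,
    library: PreyLibrary,
    cc,
    objective: str = "kl",
    n_restarts: int = 5,
    tol: float = 1e-8,
    seed: int = 0,
) -> DietEstimate:
    """One-shot QFASA diet estimate (see :class:`DietSolver` for reuse)."""
    return DietSolver(library, cc, objective=objective, n_restarts=n_restarts,
                      tol=tol, seed=seed).solve(y)


def read_calibration(path, fa_labels=None) -> pd.Series:
    """Calibration CSV (columns: fa_label, coefficient) -> Series."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError("calibration CSV needs fa_label and coefficient columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str).tolist())
    if fa_labels is not None:
        missing = [f for f in fa_labels if f not in s.index]
        if missing:
            raise SchemaError(f"calibration missing fatty acids: {missing}")
        s = s.loc[list(fa_labels)]
    return s
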