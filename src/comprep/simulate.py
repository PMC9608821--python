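"""Simulated populations of diets with a controllable true repeatability.

A population "grid" of N predators x k time points is built in isometric
log-ratio (ilr) space around a base diet mu:

    cell(i, j) = ilr(mu) + row_i + col_j + eps_ij,

with predator (row) effects drawn from a diagonal multivariate normal,
fixed time (column) effects ``col_j = +/- c * ilr(mu)`` (for k = 2; for
k > 2 equally spaced multiples summing to zero), and iid normal residual
noise.  Cells are mapped back to the simplex with the inverse ilr, so every
population diet is strictly positive — essential zeros enter the pipeline
only later, through QFASA estimation.  The grid's true repeatability is the
balanced estimator evaluated on the *entire* population of N x k diets with
the CS distance.

Increasing the row variance raises the true repeatability; increasing the
column constant c or the residual noise lowers it, which is what the grid
calibration exploits (bisection over c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.composition import ilr as _skbio_ilr
from skbio.stats.composition import ilr_inv as _skbio_ilr_inv

from .bootstrap import repeatability_with_ci
from .dbanova import balanced_ss_from_d2
from .distance import pairwise_cs
from .errors import CalibrationError, DomainError
from .panel import DietPanel
from .pseudo import PseudoPredatorConfig, simulate_estimated_panel
from .qfasa import DietSolver, PreyLibrary
from .repeatability import _estimate_from_ss

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "PopulationGrid",
    "ilr_transform",
    "ilr_inverse",
    "gridspec_from_diets",
    "build_population_grid",
    "calibrate_column_constant",
    "coverage_experiment",
    "coverage_margin_of_error",
    "CoverageResult",
]


def ilr_transform(x) -> np.ndarray:
    """Isometric log-ratio transform (fixed orthonormal basis); requires a
    strictly positive composition."""
    v = np.asarray(x, dtype=float)
    if (v <= 0).any():
        raise DomainError("ilr requires strictly positive components")
    return np.asarray(_skbio_ilr(v / v.sum()))


def ilr_inverse(z) -> np.ndarray:
    """Inverse ilr: any real vector -> strictly positive composition."""
    return np.asarray(_skbio_ilr_inv(np.asarray(z, dtype=float)))


@dataclass
class GridSpec:
    """Recipe for a population grid.

    ``row_cov_diagonal`` are the per-ilr-coordinate variances of the
    predator effects (the among-individual variance component);
    ``column_constant`` scales the fixed time effects; ``residual_sd`` is
    the iid noise SD in ilr space.
    """

    base_diet: pd.Series
    row_cov_diagonal: np.ndarray
    column_constant: float
    residual_sd: float
    N: int = 1000
    k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        base = self.base_diet.astype(float)
        if (base < 0).any() or base.sum() <= 0:
            raise DomainError("base diet must be nonnegative with positive sum")
        base = base[base > 0]  # zero-mean species carry no signal: prune + renormalize
        if base.size < 2:
            raise DomainError("base diet needs at least 2 positive species")
        self.base_diet = base / base.sum()
        m1 = base.size - 1
        cov = np.asarray(self.row_cov_diagonal, dtype=float)
        if cov.ndim == 0:
            cov = np.full(m1, float(cov))
        if cov.size != m1 or (cov < 0).any():
            raise DomainError(f"row_cov_diagonal must be {m1} nonnegative variances")
        self.row_cov_diagonal = cov
        if self.residual_sd < 0:
            raise DomainError("residual_sd must be >= 0")
        if self.k < 2:
            raise DomainError("need k >= 2 time points")
        if self.N < 10 * self.k:
            raise DomainError("need N >= 10 * k grid rows")

    def replace(self, **kwargs) -> "GridSpec":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class PopulationGrid:
    """N x k population of strictly positive diets and its true repeatability."""

    diets: np.ndarray  # (N, k, M)
    species: list
    true_rho: float
    spec: GridSpec = field(repr=False)

    @property
    def N(self) -> int:
        return self.diets.shape[0]

    @property
    def k(self) -> int:
        return self.diets.shape[1]

    def sample_panel(self, n: int, rng: np.random.Generator) -> DietPanel:
        """Balanced panel of n grid rows sampled without replacement."""
        rows = rng.choice(self.N, size=n, replace=False)
        values, preds, times = [], [], []
        for i, row in enumerate(rows):
            for j in range(self.k):
                values.append(self.diets[row, j])
                preds.append(f"P{i + 1}")
                times.append(f"T{j + 1}")
        return DietPanel.from_arrays(np.asarray(values), preds, times, self.species)


def gridspec_from_diets(
    diets: pd.DataFrame | DietPanel,
    column_constant: float = 0.0,
    residual_sd: float | None = None,
    N: int = 1000,
    k: int = 2,
    seed: int = 0,
    zero_floor: float = 1e-6,
) -> GridSpec:
    """GridSpec whose base diet and row variances are empirical.

    The base diet is the average of the supplied diet estimates (zero-mean
    species pruned); the row variances are the per-coordinate variances of
    the ilr-transformed diets, after flooring zeros at ``zero_floor`` so the
    log-ratios exist.  ``residual_sd`` defaults to a quarter of the median
    row-effect SD.
    """
    df = diets.data if isinstance(diets, DietPanel) else diets
    base = df.mean(axis=0)
    base = base[base > 0]
    base = base / base.sum()
    floored = df[base.index].to_numpy(dtype=float)
    floored = np.maximum(floored, zero_floor)
    floored = floored / floored.sum(axis=1, keepdims=True)
    z = np.vstack([ilr_transform(row) for row in floored])
    row_var = z.var(axis=0, ddof=1)
    if residual_sd is None:
        residual_sd = 0.25 * float(np.median(np.sqrt(row_var)))
    return GridSpec(base, row_var, column_constant, residual_sd, N=N, k=k, seed=seed)


def _column_effects(z0: np.ndarray, c: float, k: int) -> np.ndarray:
    """Fixed time effects: +/- c * ilr(mu) for k = 2, equally spaced
    multiples summing to zero for larger k."""
    if k == 2:
        scale = np.array([1.0, -1.0])
    else:
        scale = np.linspace(1.0, -1.0, k)
        scale = scale - scale.mean()
    return np.outer(scale, c * z0)


def true_rho_of_cells(cells: np.ndarray, k: int) -> float:
    """Balanced-estimator repeatability of an (N*k, M) stack of diets
    (rows grouped as N consecutive blocks of k)."""
    n_obs = cells.shape[0]
    n = n_obs // k
    d = pairwise_cs(cells)
    pred_codes = np.repeat(np.arange(n), k)
    time_codes = np.tile(np.arange(k), n)
    ss_p, ss_t, ss_e = balanced_ss_from_d2(d * d, pred_codes, time_codes)
    rho, _, _ = _estimate_from_ss(ss_p, ss_t, ss_e, np.full(n, float(k)), ("predator", "time"))
    return float(rho)


def build_population_grid(spec: GridSpec) -> PopulationGrid:
    """Generate the population grid and compute its true repeatability."""
    rng = np.random.default_rng(spec.seed)
    mu = spec.base_diet.to_numpy()
    z0 = ilr_transform(mu)
    m1 = z0.size
    rows = rng.normal(0.0, np.sqrt(spec.row_cov_diagonal), size=(spec.N, m1))
    cols = _column_effects(z0, spec.column_constant, spec.k)
    eps = rng.normal(0.0, spec.residual_sd, size=(spec.N, spec.k, m1))
    z = z0[None, None, :] + rows[:, None, :] + cols[None, :, :] + eps
    flat = z.reshape(-1, m1)
    comps = ilr_inverse(flat)
    diets = comps.reshape(spec.N, spec.k, m1 + 1)
    rho = true_rho_of_cells(comps, spec.k)
    return PopulationGrid(diets, list(spec.base_diet.index), rho, spec)


def calibrate_column_constant(
    spec: GridSpec,
    target_rho: float,
    tol: float = 0.01,
    max_iter: int = 60,
) -> float:
    """Column constant c such that the grid's true repeatability hits
    ``target_rho`` within ``tol`` (bisection on fixed-seed grids).

    The true repeatability is monotone decreasing in c at fixed variances;
    targets above the c = 0 ceiling (or outside [0.01, 0.98]) raise
    :class:`CalibrationError` — raise the row variances to lift the ceiling.
    """
    if not (0.01 <= target_rho <= 0.98):
        raise CalibrationError(f"target_rho {target_rho} outside the attainable range [0.01, 0.98]")

    if np.linalg.norm(ilr_transform(spec.base_diet.to_numpy())) < 1e-8:
        raise CalibrationError(
            "base diet is (near-)uniform: column effects c * ilr(mu) have no leverage"
        )

    def rho_at(c: float) -> float:
        return build_population_grid(spec.replace(column_constant=float(c))).true_rho

    lo_c, rho_lo = 0.0, rho_at(0.0)
    if rho_lo < target_rho - tol:
        raise CalibrationError(
            f"ceiling rho(c=0) = {rho_lo:.3f} below target {target_rho}; increase row variances"
        )
    if abs(rho_lo - target_rho) <= tol:
        return 0.0
    hi_c = 1.0
    rho_hi = rho_at(hi_c)
    doublings = 0
    while rho_hi > target_rho and doublings < 12:
        hi_c *= 2.0
        rho_hi = rho_at(hi_c)
        doublings += 1
    if rho_hi > target_rho:
        raise CalibrationError(f"could not bracket target {target_rho}: rho({hi_c}) = {rho_hi:.3f}")
    for _ in range(max_iter):
        mid = 0.5 * (lo_c + hi_c)
        rho_mid = rho_at(mid)
        if abs(rho_mid - target_rho) <= tol:
            return float(mid)
        if rho_mid > target_rho:
            lo_c = mid
        else:
            hi_c = mid
    raise CalibrationError(f"calibration did not converge in {max_iter} bisection steps")


def coverage_margin_of_error(p: float, nsim: int) -> float:
    """Normal-approximation margin of error 1.96 sqrt(p (1 - p) / nsim)."""
    if not (0 <= p <= 1) or nsim < 1:
        raise ValueError("need p in [0, 1] and nsim >= 1")
    return float(1.96 * np.sqrt(p * (1.0 - p) / nsim))


@dataclass
class CoverageResult:
    """Per-simulation interval records plus the grid's true repeatability."""

    records: pd.DataFrame  # sim, method, lower, upper, width, covered, rho_hat, d_hat
    true_rho: float
    nsim: int
    n_failed: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for method, grp in self.records.groupby("method", sort=False):
            p = float(grp["covered"].mean())
            rows.append({
                "method": method,
                "coverage": p,
                "margin_of_error": coverage_margin_of_error(p, len(grp)),
                "mean_width": float(grp["width"].mean()),
                "mean_d_hat": float(grp["d_hat"].mean()),
                "n_sims": len(grp),
            })
        return pd.DataFrame(rows)


def coverage_experiment(
    grid: PopulationGrid,
    n: int,
    library: PreyLibrary,
    cc,
    B: int = 100,
    R: int = 100,
    nsim: int = 100,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    config: PseudoPredatorConfig | None = None,
    methods: tuple = ("t", "bca"),
    solver: DietSolver | None = None,
    variance: str = "per_br",
) -> CoverageResult:
    """Empirical coverage of the shifted intervals against the grid's true
    repeatability.

    Each simulation samples n grid rows (true diets), observes them through
    the pseudo-predator + QFASA measurement process, and runs the full
    nested-bootstrap CI machinery on the estimated panel.
    """
    if n > grid.N:
        raise ValueError("n exceeds the number of grid rows")
    if nsim < 10:
        raise ValueError("need nsim >= 10")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    config = config or PseudoPredatorConfig()
    if solver is None:
        solver = DietSolver(library, cc)
    records = []
    failed = 0
    for sim in range(nsim):
        try:
            true_panel = grid.sample_panel(n, rng)
            observed = simulate_estimated_panel(true_panel, library, cc, config, rng, solver)
            report = repeatability_with_ci(
                observed, library, cc, B=B, R=R, level=level, methods=methods,
                config=config, rng=rng, variance=variance, solver=solver,
            )
        except Exception as exc:
            logger.warning("simulation %d failed: %s", sim, exc)
            failed += 1
            continue
        for method, ci in report.intervals.items():
            lo, hi = ci.lower_reported, ci.upper_reported
            records.append({
                "sim": sim,
                "method": method,
                "lower": lo,
                "upper": hi,
                "width": hi - lo,
                "covered": bool(lo <= grid.true_rho <= hi),
                "rho_hat": report.rho_raw,
                "d_hat": report.d_hat,
            })
    return CoverageResult(pd.DataFrame(records), grid.true_rho, nsim, failed)
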