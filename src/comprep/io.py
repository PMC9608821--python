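"""CSV formats and the synthetic fixture generator.

Diet panels travel as CSV in either *wide* form (``predator_id``,
``time_label``, one column per species) or *long* form (``predator_id``,
``time_label``, ``species``, ``proportion``).  Missing (predator, time)
cells are encoded by absent rows, never by zeros: a zero proportion is an
essential zero (estimated absence of a prey species), which must not be
conflated with a missing observation.  Proportions are stored as decimals;
percent-encoded inputs (rows summing to ~100) are detected and converted
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import pairwise_cs
from .errors import ValidationError
from .panel import PREDATOR_LEVEL, TIME_LEVEL, DietPanel
from .qfasa import PreyLibrary
from .simulate import GridSpec, PopulationGrid, build_population_grid

__all__ = [
    "read_diet_panel",
    "write_diet_panel",
    "read_prey_library",
    "Fixture",
    "generate_fixture",
]

_SUM_TOL_SILENT = 1e-6
_SUM_TOL_RENORM = 1e-4
_LONG_COLUMNS = {PREDATOR_LEVEL, TIME_LEVEL, "species", "proportion"}


def _validate_sums(wide: pd.DataFrame, source: str) -> pd.DataFrame:
    values = wide.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    # percent encoding: all rows summing near 100
    if np.all(np.abs(sums - 100.0) <= 100.0 * _SUM_TOL_RENORM):
        warnings.warn(f"{source}: rows sum to ~100; interpreting proportions as percent")
        values = values / 100.0
        sums = values.sum(axis=1)
    bad = np.abs(sums - 1.0) > _SUM_TOL_RENORM
    if bad.any():
        rows = wide.index[bad].tolist()
        raise ValidationError(
            f"{source}: diet rows do not sum to 1 within {_SUM_TOL_RENORM}: {rows[:10]}"
        )
    off = np.abs(sums - 1.0) > _SUM_TOL_SILENT
    if off.any():
        warnings.warn(f"{source}: renormalizing {int(off.sum())} rows with sums off by > 1e-6")
    return pd.DataFrame(values / sums[:, None], index=wide.index, columns=wide.columns)


def read_diet_panel(path, format: str = "auto") -> DietPanel:
    """Load a diet panel CSV (wide or long; ``format='auto'`` sniffs)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str, 1: str})
    cols = set(df.columns)
    if format == "auto":
        format = "long" if cols == _LONG_COLUMNS else "wide"
    if format == "long":
        if not _LONG_COLUMNS <= cols:
            raise ValidationError(f"{path}: long format needs columns {sorted(_LONG_COLUMNS)}")
        dup = df.duplicated([PREDATOR_LEVEL, TIME_LEVEL, "species"])
        if dup.any():
            raise ValidationError(f"{path}: duplicate (predator, time, species) rows")
        wide = df.pivot_table(
            index=[PREDATOR_LEVEL, TIME_LEVEL], columns="species", values="proportion",
            fill_value=0.0, sort=False,
        )
        wide = wide[sorted(wide.columns)]
    else:
        if PREDATOR_LEVEL not in cols or TIME_LEVEL not in cols:
            raise ValidationError(f"{path}: wide format needs {PREDATOR_LEVEL} and {TIME_LEVEL}")
        if df.duplicated([PREDATOR_LEVEL, TIME_LEVEL]).any():
            raise ValidationError(f"{path}: duplicate (predator, time) rows")
        wide = df.set_index([PREDATOR_LEVEL, TIME_LEVEL])
        wide = wide[sorted(wide.columns)]
    wide = _validate_sums(wide, str(path))
    return DietPanel(wide)


def write_diet_panel(panel: DietPanel, path, format: str = "wide") -> None:
    path = Path(path)
    if format == "wide":
        panel.data.reset_index().to_csv(path, index=False)
    elif format == "long":
        long = panel.data.stack().rename("proportion").reset_index()
        long.columns = [PREDATOR_LEVEL, TIME_LEVEL, "species", "proportion"]
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_prey_library(signatures_path, fat_path, fa_subset=None) -> PreyLibrary:
    """Prey library from CSVs: signatures (species, fa_1...), fat (species, lipid_pct).

    ``fa_subset`` (iterable of FA names, or a path to a newline-separated
    list) restricts and renormalizes the signatures.
    """
    sig = pd.read_csv(signatures_path)
    if "species" not in sig.columns:
        raise ValidationError(f"{signatures_path}: needs a 'species' column")
    species = sig["species"].astype(str)
    signatures = sig.drop(columns=["species"]).astype(float)
    fat_df = pd.read_csv(fat_path)
    fat = pd.Series(
        fat_df.iloc[:, 1].to_numpy(dtype=float), index=fat_df.iloc[:, 0].astype(str).tolist()
    )
    lib = PreyLibrary(signatures, species, fat)
    if fa_subset is not None:
        if isinstance(fa_subset, (str, Path)):
            fa_subset = [line.strip() for line in Path(fa_subset).read_text().splitlines()
                         if line.strip()]
        lib = lib.restrict_fa(fa_subset)
    return lib


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------
def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class Fixture:
    """Synthetic prey library, calibration, and panels with known truth."""

    library: PreyLibrary
    cc: pd.Series
    panel_balanced: DietPanel
    panel_unbalanced: DietPanel
    grid: PopulationGrid

    @property
    def true_rho(self) -> float:
        return self.grid.true_rho

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "prey": out / "prey_signatures.csv",
            "fat": out / "prey_fat.csv",
            "cc": out / "calibration.csv",
            "panel_balanced": out / "panel_balanced.csv",
            "panel_unbalanced": out / "panel_unbalanced.csv",
        }
        sig = self.library.signatures.copy()
        sig.insert(0, "species", self.library.species.to_numpy())
        sig.to_csv(paths["prey"], index=False)
        self.library.fat.rename("lipid_pct").rename_axis("species").reset_index().to_csv(
            paths["fat"], index=False
        )
        self.cc.rename("coefficient").rename_axis("fa_label").reset_index().to_csv(
            paths["cc"], index=False
        )
        write_diet_panel(self.panel_balanced, paths["panel_balanced"])
        write_diet_panel(self.panel_unbalanced, paths["panel_unbalanced"])
        return paths


def _species_means(rng, n_species: int, n_fa: int, min_separation: float) -> np.ndarray:
    for _ in range(200):
        means = _softmax(rng.normal(0.0, 1.2, size=(n_species, n_fa)))
        d = pairwise_cs(means)
        if d[np.triu_indices(n_species, 1)].min() > min_separation:
            return means
    raise RuntimeError("could not draw separable species mean signatures")


def generate_fixture(
    n_species: int = 6,
    n_fa: int = 12,
    n_per_species: int = 20,
    n_predators: int = 12,
    seed: int = 0,
    within_sd: float = 0.25,
    row_var: float = 1.0,
    residual_sd: float = 0.25,
    column_constant: float = 0.5,
    grid_rows: int = 200,
    min_separation: float = 0.2,
    occupancy: pd.DataFrame | None = None,
) -> Fixture:
    """Deterministic synthetic data set for the whole pipeline.

    Species mean signatures are redrawn until mutually distinguishable
    (min pairwise CS distance > ``min_separation``); individual signatures
    are logistic-normal around their species mean.  Panels are sampled from
    an ilr population grid, so both come with a known true repeatability.
    The unbalanced panel reproduces ``occupancy`` (boolean predator x time
    table) exactly; by default a staggered 2-4-of-4 pattern is used.
    """
    rng = np.random.default_rng(seed)
    fa = [f"fa_{i + 1}" for i in range(n_fa)]
    species = [f"species_{i + 1}" for i in range(n_species)]
    means = _species_means(rng, n_species, n_fa, min_separation)
    rows, labels = [], []
    for s_idx, name in enumerate(species):
        z = np.log(means[s_idx])[None, :] + rng.normal(0.0, within_sd, size=(n_per_species, n_fa))
        rows.append(_softmax(z))
        labels.extend([name] * n_per_species)
    signatures = pd.DataFrame(np.vstack(rows), columns=fa)
    lib = PreyLibrary(signatures, pd.Series(labels), pd.Series(
        np.round(rng.uniform(2.0, 12.0, size=n_species), 1), index=species))
    cc = pd.Series(np.exp(rng.normal(0.0, 0.15, size=n_fa)).round(4), index=fa)

    base = pd.Series(rng.dirichlet(np.full(n_species, 2.0)), index=species)
    spec2 = GridSpec(base, np.full(n_species - 1, row_var), column_constant, residual_sd,
                     N=grid_rows, k=2, seed=seed)
    grid2 = build_population_grid(spec2)
    panel_balanced = grid2.sample_panel(n_predators, rng)

    k_wide = 4
    spec4 = spec2.replace(k=k_wide, seed=seed + 1)
    grid4 = build_population_grid(spec4)
    wide = grid4.sample_panel(n_predators, rng)
    if occupancy is None:
        occ = np.ones((n_predators, k_wide), dtype=bool)
        for i in range(n_predators):
            n_drop = i % 3  # k_i cycles 4, 3, 2
            if n_drop:
                occ[i, k_wide - n_drop:] = False
        occupancy = pd.DataFrame(occ, index=wide.predators, columns=wide.times)
    keep_rows = [
        (p, t) for p, t in wide.cell_ids() if bool(occupancy.loc[p, t])
    ]
    panel_unbalanced = DietPanel(wide.data.loc[keep_rows].copy())
    return Fixture(lib, cc, panel_balanced, panel_unbalanced, grid2)
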