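"""Pseudo-predators: simulated FA signatures with a known "true" diet.

A pseudo-predator signature is built by sampling the prey library
proportionately to a given diet: the diet is converted to FA-space mixture
weights ``w_s ∝ pi_s * fat_s`` (the inverse of the fat weighting applied by
diet estimation, so the generate→estimate round trip is centered on the true
diet), an integer number of prey individuals is allocated to species by
largest-remainder rounding, individuals are sampled with replacement, their
signatures are averaged with weights ``w_s``, and the result is mapped to
predator space by multiplying by the calibration coefficients and
renormalizing.  Re-estimating the diets of pseudo-predators is how QFASA
measurement error enters the bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .panel import DietPanel
from .qfasa import DietSolver, PreyLibrary

__all__ = ["PseudoPredatorConfig", "generate_pseudo_signature", "simulate_estimated_panel"]


@dataclass
class PseudoPredatorConfig:
    """Sampling intensity and options for pseudo-predator generation."""

    draws_per_predator: int = 30
    fat_weighted_sampling: bool = True

    def __post_init__(self) -> None:
        if self.draws_per_predator < 1:
            raise DomainError("draws_per_predator must be >= 1")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing exactly to ``total``; every species with
    positive weight and >= 0.5 expected draws receives at least one."""
    expected = weights * total
    base = np.floor(expected).astype(int)
    remainder = expected - base
    short = total - base.sum()
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    # deterministic top-up for under-served species
    need = np.flatnonzero((expected >= 0.5) & (base == 0))
    for s in need:
        donor = int(np.argmax(base))
        if base[donor] > 1:
            base[donor] -= 1
            base[s] += 1
    return base


def generate_pseudo_signature(
    true_diet: pd.Series,
    library: PreyLibrary,
    cc,
    config: PseudoPredatorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """One pseudo-predator FA signature for the given true diet.

    ``true_diet`` is a Series over species (a subset of the library's);
    deterministic given ``rng``'s state.
    """
    config = config or PseudoPredatorConfig()
    rng = rng if rng is not None else np.random.default_rng()
    missing = [s for s in true_diet.index if s not in library.species_list]
    if missing:
        raise KeyError(f"diet species absent from library: {missing}")
    pi = true_diet.to_numpy(dtype=float)
    if (pi < 0).any() or pi.sum() <= 0:
        raise DomainError("true diet must be a nonnegative vector with positive sum")
    pi = pi / pi.sum()
    fat = library.fat.loc[list(true_diet.index)].to_numpy(dtype=float)
    w = pi * fat if config.fat_weighted_sampling else pi.copy()
    w = w / w.sum()
    draws = _largest_remainder(w, config.draws_per_predator)
    cv = np.asarray(cc, dtype=float)
    fa = library.fa_labels
    sig = np.zeros(len(fa))
    for s_idx, species in enumerate(true_diet.index):
        if w[s_idx] <= 0:
            continue
        pool = library.individuals_of(species).to_numpy(dtype=float)
        n_draw = max(int(draws[s_idx]), 1)
        picks = rng.integers(0, pool.shape[0], size=n_draw)
        sig += w[s_idx] * pool[picks].mean(axis=0)
    sig = sig * cv  # prey space -> predator space (inverse of calibration)
    sig = sig / sig.sum()
    return pd.Series(sig, index=fa)


def simulate_estimated_panel(
    source_panel: DietPanel,
    library: PreyLibrary,
    cc,
    config: PseudoPredatorConfig | None = None,
    rng: np.random.Generator | None = None,
    solver: DietSolver | None = None,
) -> DietPanel:
    """Replace every observed diet by the QFASA estimate of a pseudo-predator
    whose true diet is that observation; structure (n, k_i, labels,
    missingness) is preserved exactly."""
    config = config or PseudoPredatorConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if solver is None:
        solver = DietSolver(library, cc)
    species = source_panel.species
    missing = [s for s in species if s not in library.species_list]
    if missing:
        raise KeyError(f"panel species absent from library: {missing}")
    out = np.empty((source_panel.n_obs, len(species)))
    data = source_panel.data
    for i in range(source_panel.n_obs):
        diet = data.iloc[i]
        sig = generate_pseudo_signature(diet, library, cc, config, rng)
        est = solver.solve(sig)
        out[i] = est.diet.reindex(species).to_numpy()
    return source_panel.with_values(out)
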