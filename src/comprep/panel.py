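"""Diet panels: predator x time grids of compositional diet estimates.

A :class:`DietPanel` holds one row per *observed* (predator, time) cell; a
missing cell is simply an absent row, never a row of zeros (a zero proportion
is an essential zero — an estimated absence of a prey species — and the two
must not be conflated).  Rows are compositions over a shared species list and
are renormalized to sum to one at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDesignError,
    DimensionError,
    DomainError,
    DuplicateObservationError,
    SchemaError,
)

__all__ = ["DietPanel"]

PREDATOR_LEVEL = "predator_id"
TIME_LEVEL = "time_label"


def _ordered_unique(values) -> list:
    """Unique values in order of first appearance (time labels are opaque)."""
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class DietPanel:
    """Predator x time grid of diet compositions with observed cells only.

    Parameters
    ----------
    data : pandas.DataFrame
        MultiIndex (predator_id, time_label) rows, one column per species,
        nonnegative entries.  Rows are renormalized to sum to 1.
    """

    data: pd.DataFrame
    _pred_order: list = field(init=False, repr=False)
    _time_order: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.nlevels != 2:
            raise SchemaError("panel index must be a (predator_id, time_label) MultiIndex")
        self.data.index = self.data.index.set_names([PREDATOR_LEVEL, TIME_LEVEL])
        if self.data.shape[1] < 2:
            raise SchemaError("panel needs at least 2 species columns")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateObservationError(f"duplicated (predator, time) cells: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise DomainError("panel contains non-finite proportions")
        if (values < 0).any():
            raise DomainError("panel contains negative proportions")
        sums = values.sum(axis=1)
        if (sums <= 0).any():
            bad = self.data.index[sums <= 0].tolist()
            raise DomainError(f"zero-sum diet rows: {bad}")
        self.data = pd.DataFrame(
            values / sums[:, None], index=self.data.index, columns=self.data.columns
        )
        self._pred_order = _ordered_unique(self.data.index.get_level_values(PREDATOR_LEVEL))
        self._time_order = _ordered_unique(self.data.index.get_level_values(TIME_LEVEL))

    # -- basic structure -------------------------------------------------
    @property
    def species(self) -> list:
        return list(self.data.columns)

    @property
    def predators(self) -> list:
        return list(self._pred_order)

    @property
    def times(self) -> list:
        return list(self._time_order)

    @property
    def n(self) -> int:
        """Number of predators."""
        return len(self._pred_order)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def k_values(self) -> pd.Series:
        """Observations per predator, in predator order (k_i)."""
        counts = self.data.groupby(level=PREDATOR_LEVEL, sort=False).size()
        return counts.reindex(self._pred_order)

    @property
    def is_balanced(self) -> bool:
        k = self.k_values.to_numpy()
        return bool((k == k[0]).all())

    @property
    def predator_labels(self) -> np.ndarray:
        return self.data.index.get_level_values(PREDATOR_LEVEL).to_numpy()

    @property
    def time_labels(self) -> np.ndarray:
        return self.data.index.get_level_values(TIME_LEVEL).to_numpy()

    def values(self) -> np.ndarray:
        """(n_obs, M) array of normalized diet compositions."""
        return self.data.to_numpy(dtype=float)

    def cell_ids(self) -> list[tuple]:
        """(predator, time) identity of each observation row, in row order."""
        return list(self.data.index)

    def occupancy(self) -> pd.DataFrame:
        """Boolean predator x time table of observed cells."""
        obs = pd.Series(True, index=self.data.index)
        table = obs.unstack(TIME_LEVEL, fill_value=False)
        return table.reindex(index=self._pred_order, columns=self._time_order, fill_value=False)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_arrays(cls, values, predator_ids, time_labels, species) -> "DietPanel":
        index = pd.MultiIndex.from_arrays(
            [list(predator_ids), list(time_labels)], names=[PREDATOR_LEVEL, TIME_LEVEL]
        )
        return cls(pd.DataFrame(np.asarray(values, dtype=float), index=index, columns=list(species)))

    # -- predator-level manipulation (cluster bootstrap / jackknife) ----
    def drop_predator(self, predator) -> "DietPanel":
        if predator not in self._pred_order:
            raise KeyError(f"unknown predator {predator!r}")
        if self.n < 3:
            raise DegenerateDesignError("cannot drop a predator from a panel with n < 3")
        keep = self.data[self.data.index.get_level_values(PREDATOR_LEVEL) != predator]
        return DietPanel(keep.copy())

    def select_predators(self, predators) -> "DietPanel":
        """Panel restricted to the given predators, in the given order.

        Repeats are allowed (cluster bootstrap): a predator sampled twice
        appears twice under fresh ids ``"<id>#<j>"`` carrying all its rows.
        """
        frames = []
        counts: dict = {}
        groups = {p: df for p, df in self.data.groupby(level=PREDATOR_LEVEL, sort=False)}
        for p in predators:
            if p not in groups:
                raise KeyError(f"unknown predator {p!r}")
            j = counts.get(p, 0)
            counts[p] = j + 1
            block = groups[p]
            new_id = p if j == 0 else f"{p}#{j}"
            idx = pd.MultiIndex.from_arrays(
                [[new_id] * len(block), block.index.get_level_values(TIME_LEVEL)],
                names=[PREDATOR_LEVEL, TIME_LEVEL],
            )
            frames.append(pd.DataFrame(block.to_numpy(), index=idx, columns=self.data.columns))
        return DietPanel(pd.concat(frames))

    def with_values(self, values: np.ndarray) -> "DietPanel":
        """Same structure (index, species, missingness) with replaced rows."""
        if values.shape != self.data.shape:
            raise DimensionError(f"value array shape {values.shape} != panel shape {self.data.shape}")
        return DietPanel(pd.DataFrame(values, index=self.data.index.copy(), columns=self.data.columns))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DietPanel):
            return NotImplemented
        return self.data.equals(other.data)
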