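"""Shared containers: the anterior-posterior axis grid and concentration profiles.

Conventions used throughout the package:

* the axis is discretized into ``n_points`` equally spaced positions with
  anterior = 0 % embryo length (e.l.) and spacing ``dx`` in micrometres;
* concentrations are in nM on a 0--C_max scale (C_max = 50 nM);
* a :class:`GradientSet` holds one profile per gene on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

import numpy as np
import pandas as pd

#: maximal absolute concentration, nM (shared by all genes)
C_MAX = 50.0

#: the four trunk gap genes, canonical order
GAP_GENES = ("Hb", "Kr", "Kni", "Gt")

#: maternal / stable inputs ("Hb_mat" is the maternal Hunchback profile used
#: as the Hb initial condition; "Cad" is derived from Bcd and then held fixed)
INPUT_GENES = ("Bcd", "Hb_mat", "Tll", "Cad")

# canonical output ordering for tables
_GENE_ORDER = INPUT_GENES + GAP_GENES


class GridMismatchError(ValueError):
    """Profiles defined on incompatible axis grids."""


@dataclass(frozen=True)
class AxisGrid:
    """Discretized anterior-posterior axis.

    Index ``i`` maps to position ``i * (100 / n_points)`` % e.l., so the
    default 100-point grid covers 0, 1, ..., 99 % e.l. with dx = 5 um.
    """

    n_points: int = 100
    dx: float = 5.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def x(self) -> np.ndarray:
        """Positions in % embryo length (anterior = 0)."""
        return np.arange(self.n_points) * (100.0 / self.n_points)

    @property
    def length_um(self) -> float:
        return self.n_points * self.dx

    def index_of(self, x_percent: float) -> int:
        """Nearest grid index to a position in % e.l."""
        return int(round(x_percent * self.n_points / 100.0))

    def mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask for positions within [lo, hi] % e.l."""
        x = self.x
        return (x >= lo) & (x <= hi)


@dataclass
class Profile:
    """One concentration field on an axis grid."""

    gene: str
    values: np.ndarray
    grid: AxisGrid = field(default_factory=AxisGrid)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise GridMismatchError(
                f"profile {self.gene!r} has {self.values.shape} values for a "
                f"{self.grid.n_points}-point grid"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"profile {self.gene!r} contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError(f"profile {self.gene!r} contains negative concentrations")


class GradientSet:
    """A named collection of concentration profiles on one grid.

    Behaves like a mapping from gene id to a value array; profiles are stored
    as plain float arrays to keep the simulation inner loop cheap.
    """

    def __init__(self, profiles: Mapping[str, np.ndarray] | None = None,
                 grid: AxisGrid | None = None):
        self.grid = grid or AxisGrid()
        self._data: Dict[str, np.ndarray] = {}
        if profiles:
            for gene, values in profiles.items():
                self.set(gene, values)

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, gene: str) -> np.ndarray:
        return self._data[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._data

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    @property
    def genes(self) -> tuple:
        return tuple(self._data)

    def set(self, gene: str, values: np.ndarray) -> None:
        self._data[gene] = Profile(gene, values, self.grid).values

    def profile(self, gene: str) -> Profile:
        return Profile(gene, self._data[gene].copy(), self.grid)

    def copy(self) -> "GradientSet":
        out = GradientSet(grid=self.grid)
        for gene, values in self._data.items():
            out._data[gene] = values.copy()
        return out

    def require(self, *genes: str) -> None:
        missing = [g for g in genes if g not in self._data]
        if missing:
            raise KeyError(f"missing input gene(s): {', '.join(missing)}")

    # -- interchange ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns gene, x_percent_el, conc_nM."""
        x = self.grid.x
        rows = []
        for gene in sorted(self._data, key=_gene_sort_key):
            rows.append(pd.DataFrame({
                "gene": gene,
                "x_percent_el": x,
                "conc_nM": self._data[gene],
            }))
        if not rows:
            return pd.DataFrame(columns=["gene", "x_percent_el", "conc_nM"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, grid: AxisGrid | None = None) -> "GradientSet":
        grid = grid or AxisGrid()
        out = cls(grid=grid)
        for gene, sub in frame.groupby("gene", sort=False):
            x_in = sub["x_percent_el"].to_numpy(dtype=float)
            y_in = sub["conc_nM"].to_numpy(dtype=float)
            order = np.argsort(x_in)
            out.set(str(gene), np.interp(grid.x, x_in[order], y_in[order]))
        return out

    def __repr__(self) -> str:
        return f"GradientSet(genes={list(self._data)}, n_points={self.grid.n_points})"


def _gene_sort_key(gene: str):
    try:
        return (0, _GENE_ORDER.index(gene))
    except ValueError:
        return (1, gene)
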