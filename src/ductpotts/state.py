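"""Simulation state: the label lattice plus the per-cell registry.

The registry is stored as flat numpy columns indexed by cell label (label 0,
the medium, occupies index 0 and is permanently "alive" with no statistics).
Volume, interface length and centroid sums are *caches*, updated
incrementally by the kernels on every accepted copy; ``recompute_stats`` and
``stats_oracle`` rebuild them from the lattice and back the oracle tests.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .biology import BiologyParams
from .energy import CellRecord, CellState, CellType, EnergyParams
from .lattice import Adjacency, Lattice, UsageError, interface_lengths_all

__all__ = ["SimState"]

_GROW = 64  # registry capacity increment


@dataclass
class SimState:
    lattice: Lattice
    energy: EnergyParams
    biology: BiologyParams = field(default_factory=BiologyParams)
    adjacency: Adjacency = Adjacency.MOORE8
    geometry: object | None = None
    n_labels: int = 1  # labels 0..n_labels-1 allocated

    # registry columns (allocated to capacity >= n_labels)
    cell_type: np.ndarray = None
    cell_state: np.ndarray = None
    volume: np.ndarray = None
    interface: np.ndarray = None
    target_volume: np.ndarray = None
    target_surface: np.ndarray = None
    crow_sum: np.ndarray = None
    ccol_sum: np.ndarray = None
    proliferative: np.ndarray = None
    pref_row: np.ndarray = None
    pref_col: np.ndarray = None

    def __post_init__(self) -> None:
        if self.cell_type is None:
            self._alloc(max(_GROW, self.n_labels))

    def _alloc(self, capacity: int) -> None:
        self.cell_type = np.zeros(capacity, dtype=np.int8)
        self.cell_state = np.zeros(capacity, dtype=np.int8)
        self.volume = np.zeros(capacity, dtype=np.int64)
        self.interface = np.zeros(capacity, dtype=np.int64)
        self.target_volume = np.zeros(capacity, dtype=np.float64)
        self.target_surface = np.zeros(capacity, dtype=np.float64)
        self.crow_sum = np.zeros(capacity, dtype=np.float64)
        self.ccol_sum = np.zeros(capacity, dtype=np.float64)
        self.proliferative = np.zeros(capacity, dtype=bool)
        self.pref_row = np.zeros(capacity, dtype=np.float64)
        self.pref_col = np.zeros(capacity, dtype=np.float64)

    # -- construction ------------------------------------------------------

    @classmethod
    def empty(cls, height: int, width: int,
              energy: EnergyParams | None = None,
              biology: BiologyParams | None = None,
              adjacency: Adjacency = Adjacency.MOORE8) -> "SimState":
        from .lattice import create_lattice
        return cls(lattice=create_lattice(height, width),
                   energy=energy or EnergyParams(),
                   biology=biology or BiologyParams(),
                   adjacency=adjacency)

    @classmethod
    def from_labels(cls, labels: np.ndarray, cell_types,
                    energy: EnergyParams | None = None,
                    biology: BiologyParams | None = None,
                    adjacency: Adjacency = Adjacency.MOORE8) -> "SimState":
        """Build a consistent state from an arbitrary label matrix.

        ``cell_types`` maps label -> CellType (dict or array); every label
        present on the lattice must be covered.  Target volumes/surfaces are
        initialized to the type's published values.
        """
        labels = np.ascontiguousarray(labels, dtype=np.int32)
        n = int(labels.max(initial=0)) + 1
        state = cls(lattice=Lattice(labels), energy=energy or EnergyParams(),
                    biology=biology or BiologyParams(), adjacency=adjacency,
                    n_labels=n)
        state._alloc(max(_GROW, n))
        for k in range(1, n):
            if isinstance(cell_types, dict):
                tau = cell_types.get(k, CellType.LUMINAL)
            else:
                tau = cell_types[k]
            state.cell_type[k] = int(tau)
            state.target_volume[k] = state.energy.V_t[int(tau)]
            state.target_surface[k] = state.energy.S_t[int(tau)]
        state.recompute_stats()
        return state

    # -- registry management ----------------------------------------------

    def _ensure_capacity(self, n: int) -> None:
        cap = self.cell_type.shape[0]
        if n <= cap:
            return
        new = max(n, cap + _GROW)
        for name in ("cell_type", "cell_state", "volume", "interface",
                     "target_volume", "target_surface", "crow_sum",
                     "ccol_sum", "proliferative", "pref_row", "pref_col"):
            old = getattr(self, name)
            grown = np.zeros(new, dtype=old.dtype)
            grown[:cap] = old
            setattr(self, name, grown)

    def add_cell(self, cell_type: CellType, proliferative: bool = False,
                 pref_dir: tuple[float, float] | None = None) -> int:
        """Allocate a fresh unique label; the caller paints its sites."""
        k = self.n_labels
        self._ensure_capacity(k + 1)
        self.n_labels = k + 1
        self.cell_type[k] = int(cell_type)
        self.cell_state[k] = int(CellState.ALIVE)
        self.target_volume[k] = self.energy.V_t[int(cell_type)]
        self.target_surface[k] = self.energy.S_t[int(cell_type)]
        self.proliferative[k] = proliferative
        if pref_dir is not None:
            self.pref_row[k], self.pref_col[k] = pref_dir
        return k

    # -- cached statistics -------------------------------------------------

    def stats_oracle(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Volume, interface, centroid sums recomputed from scratch."""
        n = self.n_labels
        lab = self.lattice.labels
        vol = np.bincount(lab.ravel(), minlength=n)[:n].astype(np.int64)
        vol[0] = 0
        iface = interface_lengths_all(lab, n, self.adjacency)
        rows, cols = np.indices(lab.shape)
        crow = np.bincount(lab.ravel(), weights=rows.ravel(), minlength=n)[:n]
        ccol = np.bincount(lab.ravel(), weights=cols.ravel(), minlength=n)[:n]
        crow[0] = ccol[0] = 0.0
        return vol, iface, crow, ccol

    def recompute_stats(self) -> None:
        vol, iface, crow, ccol = self.stats_oracle()
        n = self.n_labels
        self.volume[:n] = vol
        self.interface[:n] = iface
        self.crow_sum[:n] = crow
        self.ccol_sum[:n] = ccol
        gone = (vol == 0) & (np.arange(n) > 0)
        self.cell_state[:n][gone] = int(CellState.REMOVED)

    def check_consistency(self) -> None:
        """Raise if any cached statistic disagrees with the full recompute."""
        vol, iface, crow, ccol = self.stats_oracle()
        n = self.n_labels
        if not (np.array_equal(self.volume[:n], vol)
                and np.array_equal(self.interface[:n], iface)
                and np.allclose(self.crow_sum[:n], crow)
                and np.allclose(self.ccol_sum[:n], ccol)):
            raise AssertionError("cached cell statistics diverged from lattice")

    # -- views -------------------------------------------------------------

    def centroid_of(self, k: int) -> tuple[float, float]:
        v = self.volume[k]
        if v == 0:
            raise UsageError(f"cell {k} occupies no site")
        return float(self.crow_sum[k] / v), float(self.ccol_sum[k] / v)

    def cell(self, k: int) -> CellRecord:
        if not 1 <= k < self.n_labels:
            raise UsageError(f"no cell with label {k}")
        v = int(self.volume[k])
        centroid = (float("nan"), float("nan")) if v == 0 else self.centroid_of(k)
        return CellRecord(
            id=k, type=CellType(int(self.cell_type[k])),
            state=CellState(int(self.cell_state[k])),
            volume=v, interface=int(self.interface[k]),
            target_volume=float(self.target_volume[k]),
            target_surface=float(self.target_surface[k]),
            centroid=centroid,
            proliferative=bool(self.proliferative[k]))

    def cells(self, include_removed: bool = False) -> Iterator[CellRecord]:
        for k in range(1, self.n_labels):
            if include_removed or self.cell_state[k] != int(CellState.REMOVED):
                yield self.cell(k)

    def labels_of_type(self, cell_type: CellType,
                       include_removed: bool = False) -> np.ndarray:
        n = self.n_labels
        idx = np.arange(n)
        m = (self.cell_type[:n] == int(cell_type)) & (idx > 0)
        if not include_removed:
            m &= self.cell_state[:n] != int(CellState.REMOVED)
        return idx[m]

    def alive_labels(self) -> np.ndarray:
        n = self.n_labels
        idx = np.arange(n)
        return idx[(self.cell_state[:n] == int(CellState.ALIVE)) & (idx > 0)]

    def tumor_sites(self) -> int:
        """Sites occupied by luminal-type cells (alive or necrotic)."""
        n = self.n_labels
        m = ((self.cell_type[:n] == int(CellType.LUMINAL))
             & (self.cell_state[:n] != int(CellState.REMOVED)))
        m[0] = False
        return int(self.volume[:n][m].sum())

    def copy(self) -> "SimState":
        return _copy.deepcopy(self)

    # -- kernel plumbing ---------------------------------------------------

    def kernel_args(self) -> tuple:
        """Positional argument pack shared by all copy-attempt kernels."""
        return (self.lattice.labels, self.cell_type, self.cell_state,
                self.volume, self.interface, self.target_volume,
                self.target_surface, self.crow_sum, self.ccol_sum,
                self.pref_row, self.pref_col, self.energy.J,
                self.energy.lambda_V, self.energy.lambda_S,
                self.adjacency.offsets, self.energy.temperature,
                self.biology.anisotropy_bias)
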