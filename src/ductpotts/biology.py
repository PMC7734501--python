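"""DCIS cell behaviors layered on top of the CPM dynamics.

Four rules, applied between Monte Carlo sweeps:

* a fixed fraction (15%) of the luminal cells is flagged proliferative;
* proliferative cells ramp their target volume each sweep and split by a
  principal-axis bisection once they double the nominal cell size;
* a luminal cell with ten or more alive neighbors within 2.5 cell diameters
  of its centroid is overcrowded and may enter apoptosis (its sites revert
  to medium and it leaves the simulation);
* cells ten or more cell diameters inward from the duct's outer layer are
  starved of nutrients and become necrotic: frozen in place, still occupying
  space, no longer interacting energetically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .energy import CellState, CellType
from .lattice import Adjacency, ConfigurationError, UsageError

__all__ = [
    "BiologyParams",
    "DivisionEvent",
    "assign_proliferative",
    "grow_and_divide",
    "overpopulation_count",
    "apply_apoptosis",
    "apply_necrosis",
]


@dataclass
class BiologyParams:
    """Behavioral parameters, lengths in cell diameters unless noted.

    ``cell_diameter`` is the side of the initial 10x10 square domain, so the
    apoptosis radius (2.5 diameters) is 25 sites and the necrosis depth (10
    diameters) is 100 sites by default.  ``apoptosis_probability`` is per
    cell per sweep, read from the published 0-1% band (0.5% for the solid
    preset, 1% for cribriform).  ``anisotropy_bias`` is the energy offset
    beta subtracted from delta-H for attempts extending a cell along its
    preferred direction; 0 recovers the isotropic model.
    """

    proliferative_fraction: float = 0.15
    apoptosis_radius: float = 2.5
    apoptosis_neighbor_threshold: int = 10
    apoptosis_probability: float = 0.005
    necrosis_distance: float = 10.0
    cell_diameter: int = 10
    growth_rate: float = 1.0
    division_volume_factor: float = 2.0
    anisotropy_bias: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proliferative_fraction <= 1.0:
            raise ConfigurationError("proliferative_fraction must lie in [0, 1]")
        if not 0.0 <= self.apoptosis_probability <= 1.0:
            raise ConfigurationError("apoptosis_probability must lie in [0, 1]")
        if self.apoptosis_radius <= 0 or self.necrosis_distance <= 0:
            raise ConfigurationError("radii must be positive")
        if self.cell_diameter < 1:
            raise ConfigurationError("cell_diameter must be >= 1 site")
        if self.anisotropy_bias < 0:
            raise ConfigurationError("anisotropy_bias must be >= 0")

    @property
    def apoptosis_radius_sites(self) -> float:
        return self.apoptosis_radius * self.cell_diameter

    @property
    def necrosis_distance_sites(self) -> float:
        return self.necrosis_distance * self.cell_diameter

    @property
    def division_volume(self) -> float:
        """Absolute split threshold: factor x nominal initial cell size."""
        return self.division_volume_factor * self.cell_diameter ** 2


class DivisionEvent(NamedTuple):
    parent: int
    daughter: int
    parent_volume: int
    daughter_volume: int


def assign_proliferative(state, fraction: float | None = None,
                         rng: np.random.Generator | None = None) -> int:
    """Flag ``round(fraction x n_luminal)`` luminal cells, uniformly chosen.

    Myoepithelial cells are never flagged.  Returns the number assigned.
    """
    if fraction is None:
        fraction = state.biology.proliferative_fraction
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("proliferative fraction must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    luminal = state.labels_of_type(CellType.LUMINAL)
    k = int(round(fraction * luminal.size))
    chosen = rng.choice(luminal, size=k, replace=False)
    state.proliferative[chosen] = True
    return k


def _local_interface(labels: np.ndarray, coords: np.ndarray, label: int,
                     adjacency: Adjacency) -> int:
    """Interface length of ``label`` recomputed over its bounding window.

    The window is the coordinate bounding box expanded by one site, so every
    adjacent pair involving the cell is covered; sites outside the window
    never carry the label, so padding with medium gives the exact count.
    """
    r0 = max(int(coords[:, 0].min()) - 1, 0)
    c0 = max(int(coords[:, 1].min()) - 1, 0)
    r1 = min(int(coords[:, 0].max()) + 2, labels.shape[0])
    c1 = min(int(coords[:, 1].max()) + 2, labels.shape[1])
    mine = np.pad(labels[r0:r1, c0:c1] == label, 1, constant_values=False)
    total = 0
    for dr, dc in adjacency.forward_offsets:
        shifted = np.roll(np.roll(mine, -int(dr), axis=0), -int(dc), axis=1)
        total += int(np.count_nonzero(mine ^ shifted))
    return total


def _bisect_cell(state, k: int, rng: np.random.Generator) -> DivisionEvent | None:
    """Split cell ``k`` across the line through its centroid perpendicular to
    the principal axis; the smaller side receives a fresh label."""
    labels = state.lattice.labels
    coords = np.argwhere(labels == k)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]  # largest-variance direction
    proj = centered @ axis
    side = proj > 0.0
    n_pos = int(side.sum())
    if n_pos == 0 or n_pos == coords.shape[0]:
        return None  # degenerate split: defer to a later sweep
    daughter_coords = coords[side] if n_pos <= coords.shape[0] - n_pos else coords[~side]
    theta = rng.uniform(0.0, 2.0 * np.pi)
    tau = CellType(int(state.cell_type[k]))
    nk = state.add_cell(tau, proliferative=bool(state.proliferative[k]),
                        pref_dir=(np.cos(theta), np.sin(theta)))
    labels[daughter_coords[:, 0], daughter_coords[:, 1]] = nk
    # exact cache updates for both daughters; third cells are unaffected
    parent_coords = np.argwhere(labels == k)
    for lab, cc in ((k, parent_coords), (nk, daughter_coords)):
        state.volume[lab] = cc.shape[0]
        state.crow_sum[lab] = float(cc[:, 0].sum())
        state.ccol_sum[lab] = float(cc[:, 1].sum())
        state.interface[lab] = _local_interface(labels, coords, lab,
                                                state.adjacency)
        state.target_volume[lab] = state.energy.V_t[int(tau)]
    return DivisionEvent(parent=k, daughter=nk,
                         parent_volume=int(state.volume[k]),
                         daughter_volume=int(state.volume[nk]))


def grow_and_divide(state, rng: np.random.Generator) -> list[DivisionEvent]:
    """Ramp proliferative targets and perform mitosis on oversized cells."""
    n = state.n_labels
    growing = (state.proliferative[:n]
               & (state.cell_state[:n] == int(CellState.ALIVE)))
    growing[0] = False
    state.target_volume[:n][growing] += state.biology.growth_rate
    threshold = state.biology.division_volume
    idx = np.arange(n)
    big = idx[(state.cell_state[:n] == int(CellState.ALIVE)) & (idx > 0)
              & (state.volume[:n] >= threshold)]
    events = []
    for k in big:
        ev = _bisect_cell(state, int(k), rng)
        if ev is not None:
            events.append(ev)
    return events


def overpopulation_count(state, cell_id: int,
                         radius_sites: float | None = None) -> int:
    """Alive cells (other than ``cell_id``) with centroids within the radius."""
    if state.cell_state[cell_id] == int(CellState.REMOVED):
        raise UsageError(f"cell {cell_id} has been removed")
    if radius_sites is None:
        radius_sites = state.biology.apoptosis_radius_sites
    alive = state.alive_labels()
    alive = alive[alive != cell_id]
    if alive.size == 0:
        return 0
    v = state.volume[alive].astype(np.float64)
    cr = state.crow_sum[alive] / v
    cc = state.ccol_sum[alive] / v
    r0, c0 = state.centroid_of(cell_id)
    d2 = (cr - r0) ** 2 + (cc - c0) ** 2
    return int(np.count_nonzero(d2 <= radius_sites ** 2))


def apply_apoptosis(state, rng: np.random.Generator) -> list[int]:
    """Remove overcrowded luminal cells with the configured probability.

    Counts are taken simultaneously on the pre-phase state; each crowded
    cell then draws independently.  A dying cell's full site set reverts to
    medium atomically.
    """
    p = state.biology.apoptosis_probability
    threshold = state.biology.apoptosis_neighbor_threshold
    luminal = state.labels_of_type(CellType.LUMINAL)
    luminal = luminal[state.cell_state[luminal] == int(CellState.ALIVE)]
    crowded = [int(k) for k in luminal
               if overpopulation_count(state, int(k)) >= threshold]
    removed = []
    for k in crowded:
        if rng.random() < p:
            removed.append(k)
    labels = state.lattice.labels
    for k in removed:
        labels[labels == k] = 0
        state.volume[k] = 0
        state.interface[k] = 0
        state.crow_sum[k] = state.ccol_sum[k] = 0.0
        state.cell_state[k] = int(CellState.REMOVED)
    return removed


def apply_necrosis(state, geometry=None) -> list[int]:
    """Freeze nutrient-starved cells: those whose centroid lies ten or more
    cell diameters radially inward from the duct's outer-layer circle."""
    geometry = geometry if geometry is not None else state.geometry
    if geometry is None:
        return []
    depth = state.biology.necrosis_distance_sites
    newly = []
    for k in state.alive_labels():
        r, c = state.centroid_of(int(k))
        dist = np.hypot(r - geometry.center[0], c - geometry.center[1])
        if geometry.outer_radius - dist >= depth:
            state.cell_state[k] = int(CellState.NECROTIC)
            newly.append(int(k))
    return newly
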