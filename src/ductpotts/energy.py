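"""The CPM Hamiltonian: adhesion + volume elasticity + surface elasticity.

The energy of a configuration is

    H = sum_{adjacent site pairs, different cells} J(tau, tau')
      + sum_{alive cells} lambda_V(tau) (V - V_t)^2
      + sum_{alive cells} lambda_S(tau) (S - S_t)^2

where the adhesion sum runs over *unordered* adjacent site pairs (each
contact counted once), V and S are the cell's site count and heterologous
contact-pair count, and necrotic cells are frozen: pairs involving them
contribute no adhesion energy and they are excluded from the volume and
surface sums.

Everything in this module recomputes H from the full state.  It is the
testing oracle for the incremental delta-H used by the Monte Carlo kernels
(:func:`delta_h_for_copy` wraps that kernel so the dual-route check compares
genuinely independent code paths).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .lattice import Adjacency, ConfigurationError, Site, UsageError

__all__ = [
    "CellType",
    "CellState",
    "EnergyParams",
    "CellRecord",
    "adhesion_term",
    "volume_term",
    "surface_term",
    "total_hamiltonian",
    "delta_h_for_copy",
]


class CellType(enum.IntEnum):
    """Agent classes: the medium/ECM, luminal and myoepithelial epithelium."""

    MEDIUM = 0
    LUMINAL = 1
    MYOEPITHELIAL = 2


class CellState(enum.IntEnum):
    ALIVE = 0
    NECROTIC = 1
    REMOVED = 2


# Published parameterization (dimensionless lattice units).  The adhesion
# hierarchy J(L,L) < J(M,L) < J(M,M) keeps luminal cells cohesive inside a
# deformable myoepithelial annulus.
_DEFAULT_J = {
    (CellType.LUMINAL, CellType.LUMINAL): -20.0,
    (CellType.LUMINAL, CellType.MYOEPITHELIAL): -10.0,
    (CellType.MYOEPITHELIAL, CellType.MYOEPITHELIAL): -5.0,
}


@dataclass
class EnergyParams:
    """Hamiltonian parameters, indexed by :class:`CellType`.

    ``J`` is a symmetric 3x3 adhesion matrix; rows/cols follow the CellType
    order (MEDIUM, LUMINAL, MYOEPITHELIAL).  Contacts with the medium default
    to 0 energy (the published table has no medium rows).  ``elasticity_L``
    and ``elasticity_lambda`` store the published length-elasticity rows
    verbatim; no term of the Hamiltonian uses them (there is no length
    constraint), they are kept for configuration fidelity and reporting.

    The Metropolis temperature has no published value; the default ``10.0``
    is a package choice, logged once per run.
    """

    J: np.ndarray = field(default_factory=lambda: _default_J_matrix())
    lambda_V: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 78.0, 10.0]))
    lambda_S: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 31.0, 1.0]))
    V_t: np.ndarray = field(default_factory=lambda: np.array([0.0, 78.0, 5.0]))
    S_t: np.ndarray = field(default_factory=lambda: np.array([0.0, -31.0, 1.0]))
    temperature: float = 10.0
    elasticity_L: dict = field(default_factory=lambda: {
        "L,L": 8.0, "L,M": 8.0, "M,N": 5.0})
    elasticity_lambda: dict = field(default_factory=lambda: {
        "L,L": 50.0, "L,M": 5.0, "M,N": 50.0})

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.float64)
        self.lambda_V = np.asarray(self.lambda_V, dtype=np.float64)
        self.lambda_S = np.asarray(self.lambda_S, dtype=np.float64)
        self.V_t = np.asarray(self.V_t, dtype=np.float64)
        self.S_t = np.asarray(self.S_t, dtype=np.float64)
        if self.J.shape != (3, 3):
            raise ConfigurationError("J must be a 3x3 (CellType x CellType) matrix")
        if not np.allclose(self.J, self.J.T):
            raise ConfigurationError("adhesion matrix J must be symmetric")
        if self.temperature <= 0:
            raise ConfigurationError("temperature T_m must be > 0")

    def check_adhesion_hierarchy(self) -> bool:
        """J(L,L) < J(M,L) < J(M,M): the biologically contrasted ordering."""
        L, M = CellType.LUMINAL, CellType.MYOEPITHELIAL
        return bool(self.J[L, L] < self.J[M, L] < self.J[M, M])


def _default_J_matrix() -> np.ndarray:
    J = np.zeros((3, 3), dtype=np.float64)
    for (a, b), v in _DEFAULT_J.items():
        J[a, b] = v
        J[b, a] = v
    return J


@dataclass
class CellRecord:
    """Snapshot of one cell's registry entry.

    ``volume``/``interface`` are the cached site and contact-pair counts;
    ``target_volume`` ramps during proliferative growth while
    ``target_surface`` stays at the type's published value.
    """

    id: int
    type: CellType
    state: CellState
    volume: int
    interface: int
    target_volume: float
    target_surface: float
    centroid: tuple[float, float]
    proliferative: bool


# ---------------------------------------------------------------------------
# Full-state oracle terms.  ``state`` is a SimState (see ductpotts.state); we
# only touch its public arrays, so any object with the same attributes works.
# ---------------------------------------------------------------------------

def _check_registry(state) -> None:
    present = np.unique(state.lattice.labels)
    present = present[present > 0]
    if present.size and present.max() >= state.n_labels:
        raise UsageError(
            f"lattice references label {present.max()} absent from the registry")


def adhesion_term(state, params: EnergyParams | None = None,
                  adjacency: Adjacency | None = None) -> float:
    """Sum of J over unordered adjacent pairs belonging to different cells.

    Pairs involving necrotic cells contribute 0 (a necrotic cell no longer
    interacts with its neighbors).  Out-of-range partners are permanent
    medium.
    """
    params = params or state.energy
    adjacency = adjacency or state.adjacency
    _check_registry(state)
    pad = state.lattice.padded()
    # Per-label type and interaction weight (0 for necrotic cells).
    types = np.zeros(state.n_labels, dtype=np.int64)
    types[:] = state.cell_type[: state.n_labels]
    interacting = state.cell_state[: state.n_labels] != CellState.NECROTIC
    total = 0.0
    h, w = pad.shape
    for dr, dc in adjacency.forward_offsets:
        a = pad[max(dr, 0):h + min(dr, 0), max(dc, 0):w + min(dc, 0)]
        b = pad[max(-dr, 0):h + min(-dr, 0), max(-dc, 0):w + min(-dc, 0)]
        diff = a != b
        la, lb = a[diff], b[diff]
        jv = params.J[types[la], types[lb]]
        jv = jv * interacting[la] * interacting[lb]
        total += float(jv.sum())
    return total


def volume_term(state, params: EnergyParams | None = None) -> float:
    """sum over alive cells of lambda_V(tau) (V - V_t)^2."""
    params = params or state.energy
    n = state.n_labels
    alive = (state.cell_state[:n] == CellState.ALIVE) & (np.arange(n) > 0)
    tau = state.cell_type[:n][alive]
    dv = state.volume[:n][alive] - state.target_volume[:n][alive]
    return float(np.sum(params.lambda_V[tau] * dv * dv))


def surface_term(state, params: EnergyParams | None = None) -> float:
    """sum over alive cells of lambda_S(tau) (S - S_t)^2."""
    params = params or state.energy
    n = state.n_labels
    alive = (state.cell_state[:n] == CellState.ALIVE) & (np.arange(n) > 0)
    tau = state.cell_type[:n][alive]
    ds = state.interface[:n][alive] - state.target_surface[:n][alive]
    return float(np.sum(params.lambda_S[tau] * ds * ds))


def total_hamiltonian(state, params: EnergyParams | None = None,
                      adjacency: Adjacency | None = None) -> float:
    """Full-state H; the oracle against which incremental delta-H is tested."""
    return (adhesion_term(state, params, adjacency)
            + volume_term(state, params)
            + surface_term(state, params))


def delta_h_for_copy(state, focal: Site, source_label: int) -> float:
    """Energy change of relabeling ``focal`` to ``source_label``.

    Computed incrementally from the focal neighborhood and the two affected
    cells only (the Monte Carlo fast path); the state is left untouched.
    ``source_label`` must be the label of one of the focal site's adjacency
    partners and differ from the focal site's own label.
    """
    from . import kernels  # local import: numba compilation is lazy

    if not state.lattice.in_range(focal):
        raise UsageError(f"focal site {focal} out of range")
    old = state.lattice.label_at(*focal)
    if source_label == old:
        return 0.0
    nbr_labels = {state.lattice.label_at(focal[0] + int(dr), focal[1] + int(dc))
                  for dr, dc in state.adjacency.offsets}
    if source_label not in nbr_labels:
        raise UsageError(
            f"label {source_label} is not adjacent to focal site {focal}")
    return float(kernels.delta_h(
        state.lattice.labels, state.cell_type, state.cell_state,
        state.volume, state.interface, state.target_volume,
        state.target_surface, state.energy.J, state.energy.lambda_V,
        state.energy.lambda_S, state.adjacency.offsets,
        int(focal[0]), int(focal[1]), int(source_label)))
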