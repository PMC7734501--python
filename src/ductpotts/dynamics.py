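"""Metropolis copy-attempt dynamics and the simulation loop.

One *sweep* gives every lattice site exactly one copy attempt, each site at
most once (the serial engine realizes this as a uniformly random permutation;
the parallel engines realize it through the claim ledger).  A copy attempt
selects one adjacency partner uniformly at random and, with the Metropolis
probability

    P = exp(-dH / T_m)  if dH > 0,    P = 1  if dH <= 0,

the focal site adopts the neighbor's label (the neighbor invades).  Biology
phases (growth/division, apoptosis, necrosis) run between sweeps, identically
for every engine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_logger = logging.getLogger(__name__)

from .energy import CellState
from .lattice import Adjacency, ConfigurationError, Site, UsageError

__all__ = [
    "CopyAttempt",
    "RunConfig",
    "SweepStats",
    "RunResult",
    "acceptance_probability",
    "attempt_copy",
    "run_sweep_serial",
    "run_simulation",
]

ENGINES = ("serial", "ledger", "locked", "interleaved")


@dataclass(frozen=True)
class CopyAttempt:
    focal: Site
    old_label: int
    source_label: int
    delta_h: float
    probability: float
    accepted: bool


@dataclass
class SweepStats:
    attempts: int = 0
    accepted: int = 0
    forfeited: int = 0
    retries: int = 0
    audit: object = None  # focal-site log (flat indices) when requested

    def __iadd__(self, other: "SweepStats") -> "SweepStats":
        self.attempts += other.attempts
        self.accepted += other.accepted
        self.forfeited += other.forfeited
        self.retries += other.retries
        return self


@dataclass
class RunConfig:
    """Scheduling part of a simulation configuration."""

    sweeps: int = 100
    engine: str = "serial"
    n_tasks: int = 1
    master_seed: int = 0
    adjacency: Adjacency = Adjacency.MOORE8
    preset: str = "solid"
    snapshot_every: int = 0  # 0 = final snapshot only

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ConfigurationError(
                f"unknown engine {self.engine!r}; choose from {ENGINES}")
        if self.n_tasks < 1 or self.sweeps < 0:
            raise ConfigurationError("need n_tasks >= 1 and sweeps >= 0")
        if isinstance(self.adjacency, str):
            self.adjacency = Adjacency(self.adjacency)


def acceptance_probability(delta_h: float, temperature: float) -> float:
    """The Metropolis acceptance law: exactly 1 for dH <= 0, else exp(-dH/T)."""
    if temperature <= 0:
        raise ConfigurationError("temperature T_m must be > 0")
    if delta_h <= 0:
        return 1.0
    return math.exp(-delta_h / temperature)


def attempt_copy(state, focal: Site, rng: np.random.Generator) -> CopyAttempt:
    """One copy attempt at ``focal``: pick a neighbor, Metropolis-accept.

    Same-label selections are no-ops (dH = 0, trivially accepted, no state
    change); attempts touching a necrotic cell are rejected outright.  On
    acceptance the focal site is relabeled and both cells' cached statistics
    are updated incrementally.
    """
    from . import kernels

    if not state.lattice.in_range(focal):
        raise UsageError(f"focal site {focal} out of range")
    adjacency: Adjacency = state.adjacency
    i, j = int(focal[0]), int(focal[1])
    a = state.lattice.label_at(i, j)
    nbr_idx = int(rng.integers(adjacency.size))
    dr, dc = adjacency.offsets[nbr_idx]
    b = state.lattice.label_at(i + int(dr), j + int(dc))
    if b == a:
        return CopyAttempt(Site(i, j), a, b, 0.0, 1.0, True)
    if (state.cell_state[a] == int(CellState.NECROTIC)
            or state.cell_state[b] == int(CellState.NECROTIC)):
        return CopyAttempt(Site(i, j), a, b, math.inf, 0.0, False)
    args = state.kernel_args()
    dh = float(kernels.delta_h(*args[:7], args[11], args[12], args[13],
                               args[14], i, j, b))
    beta = state.biology.anisotropy_bias
    if beta > 0.0 and b > 0:
        vb = state.volume[b]
        disp = (i - state.crow_sum[b] / vb, j - state.ccol_sum[b] / vb)
        if disp[0] * state.pref_row[b] + disp[1] * state.pref_col[b] > 0.0:
            dh -= beta
    p = acceptance_probability(dh, state.energy.temperature)
    accepted = bool(rng.random() < p)
    if accepted:
        kernels.apply_flip(state.lattice.labels, state.cell_state,
                           state.volume, state.interface, state.crow_sum,
                           state.ccol_sum, adjacency.offsets, i, j, b)
    return CopyAttempt(Site(i, j), a, b, dh, p, accepted)


def run_sweep_serial(state, rng: np.random.Generator,
                     collect_audit: bool = False) -> SweepStats:
    """Visit every site exactly once in a uniformly random permutation."""
    from . import kernels

    n = state.lattice.height * state.lattice.width
    order = rng.permutation(n)
    nbr_idx = rng.integers(0, state.adjacency.size, size=n)
    us = rng.random(n)
    accepted = int(kernels.run_attempts(*state.kernel_args(),
                                        order, nbr_idx, us))
    stats = SweepStats(attempts=n, accepted=accepted)
    if collect_audit:
        stats.audit = order
    return stats


@dataclass
class RunResult:
    state: object
    series: pd.DataFrame
    snapshots: list = field(default_factory=list)
    config: object | None = None


def _series_row(state, sweep: int, stats: SweepStats,
                lumen_mask: np.ndarray | None, n_removed: int) -> dict:
    n = state.n_labels
    cs = state.cell_state[1:n]
    row = {
        "sweep": sweep,
        "n_alive": int(np.count_nonzero(cs == int(CellState.ALIVE))),
        "n_necrotic": int(np.count_nonzero(cs == int(CellState.NECROTIC))),
        "n_removed_cumulative": n_removed,
        "tumor_sites": state.tumor_sites(),
        "lumen_fill_fraction": float("nan"),
        "accepted_attempts": stats.accepted,
        "forfeits": stats.forfeited,
    }
    if lumen_mask is not None:
        inside = state.lattice.labels[lumen_mask]
        row["lumen_fill_fraction"] = float(
            np.count_nonzero(inside) / inside.size)
    return row


def run_simulation(config, state=None, collect_audit: bool = False) -> RunResult:
    """Run a full simulation from a :class:`ductpotts.geometry.SimulationConfig`.

    Per sweep: (1) one dynamics sweep through the configured engine, (2)
    growth and division, (3) apoptosis, (4) necrosis, (5) a time-series row.
    Passing an explicit ``state`` (e.g. a prebuilt duct) skips construction.
    """
    from . import biology, engines, geometry

    run: RunConfig = config.run
    _logger.info(
        "Metropolis temperature T_m = %g (no published value; package "
        "default, configurable)", config.energy.temperature)
    _logger.info(
        "elasticity parameter rows are stored for fidelity but unused: the "
        "Hamiltonian has no length term")
    ss = np.random.SeedSequence(run.master_seed)
    ss_build, ss_bio, ss_dyn = ss.spawn(3)
    if state is None:
        state = geometry.build_initial_state(
            config, np.random.default_rng(ss_build))
    bio_rng = np.random.default_rng(ss_bio)
    biology.assign_proliferative(state, rng=bio_rng)

    lumen_mask = None
    if state.geometry is not None:
        g = state.geometry
        rows, cols = np.indices(state.lattice.labels.shape)
        lumen_mask = (np.hypot(rows - g.center[0], cols - g.center[1])
                      < g.lumen_radius)

    engine = engines.get_engine(run.engine)
    removed_total = 0
    records = [_series_row(state, 0, SweepStats(), lumen_mask, 0)]
    snapshots = []
    if run.snapshot_every:
        snapshots.append((0, state.lattice.labels.copy()))
    for sweep in range(1, run.sweeps + 1):
        stats = engine(state, ss_dyn.spawn(1)[0], run.n_tasks,
                       collect_audit=collect_audit)
        biology.grow_and_divide(state, bio_rng)
        removed_total += len(biology.apply_apoptosis(state, bio_rng))
        biology.apply_necrosis(state)
        records.append(_series_row(state, sweep, stats, lumen_mask,
                                   removed_total))
        if run.snapshot_every and sweep % run.snapshot_every == 0:
            snapshots.append((sweep, state.lattice.labels.copy()))
    if not snapshots or snapshots[-1][0] != run.sweeps:
        snapshots.append((run.sweeps, state.lattice.labels.copy()))
    series = pd.DataFrame.from_records(records)
    return RunResult(state=state, series=series, snapshots=snapshots,
                     config=config)
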