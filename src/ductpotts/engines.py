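"""Sweep engines: serial, lock-free ledger, lock-based, and interleaved.

The parallel scheme keeps a single shared label lattice and a shared
*processed-node ledger*: the set of sites that have already had their copy
attempt this sweep.  Each worker repeatedly draws a uniformly random site and
tries to claim it; the claim is the only synchronization point.  A failed
claim is the optimistic-concurrency roll-back: the worker simply redraws
(bounded by ``retry_limit``, then the slot is forfeited so sweeps always
terminate).  Successful claimants run their copy attempts against the shared
lattice; neighbor reads may be concurrently stale — only focal-site
exclusivity is guaranteed, which is the scheme's stated safety condition.

Realization notes.  Workers are Python threads over the shared numpy label
buffer.  The lock-free claim is ``dict.setdefault`` with a unique token: a
single C-level operation, atomic under the interpreter lock and therefore
linearizable.  Claimed sites are processed in small batches through a
``nogil`` JIT kernel so threads overlap in the numerical work; batching
amortizes interpreter overhead only — every claim is still individual and
atomic.  The ``interleaved`` engine drives the *same* per-task generator code
single-threaded in round-robin, giving deterministic exact replay.
"""

from __future__ import annotations

import itertools
import math
import threading
from dataclasses import dataclass

import numpy as np

from . import kernels
from .dynamics import SweepStats, run_sweep_serial
from .lattice import Site, UsageError

__all__ = [
    "ProcessedLedger",
    "LockedLedger",
    "TaskPlan",
    "ledger_claim",
    "ledger_reset",
    "evolve_task",
    "run_sweep_parallel",
    "run_sweep_locked",
    "run_sweep_interleaved",
    "get_engine",
]

DEFAULT_RETRY_LIMIT = 100
DEFAULT_BATCH = 64


class ProcessedLedger:
    """The shared set of already-claimed sites, with an atomic lock-free claim.

    For any site within one sweep, exactly one ``claim`` call returns True
    (linearizable): concurrent claimants race on a single atomic
    ``dict.setdefault`` insertion keyed by flat site index.
    """

    def __init__(self, height: int, width: int):
        self.height = height
        self.width = width
        self._claimed: dict[int, int] = {}
        self._tokens = itertools.count()
        self._active = 0
        self._guard = threading.Lock()

    @property
    def capacity(self) -> int:
        return self.height * self.width

    def claim(self, flat_site: int) -> bool:
        """True iff this call claimed the site (first claimant this sweep)."""
        token = next(self._tokens)
        return self._claimed.setdefault(flat_site, token) == token

    def claimed_count(self) -> int:
        return len(self._claimed)

    def reset(self) -> None:
        with self._guard:
            if self._active:
                raise UsageError("cannot reset the ledger during an active sweep")
            self._claimed.clear()

    def _begin_task(self) -> None:
        with self._guard:
            self._active += 1

    def _end_task(self) -> None:
        with self._guard:
            self._active -= 1


class LockedLedger(ProcessedLedger):
    """Same contract, but claims serialize through a mutual-exclusion lock.

    Exists as the comparison engine's mechanism; correctness properties are
    identical, only the synchronization cost differs.
    """

    def __init__(self, height: int, width: int):
        super().__init__(height, width)
        self._lock = threading.Lock()
        self._set: set[int] = set()

    def claim(self, flat_site: int) -> bool:
        with self._lock:
            if flat_site in self._set:
                return False
            self._set.add(flat_site)
            self._claimed[flat_site] = 0  # keep claimed_count consistent
            return True

    def reset(self) -> None:
        super().reset()
        with self._lock:
            self._set.clear()


def ledger_claim(ledger: ProcessedLedger, site: Site | int) -> bool:
    """Claim a site (``Site`` or flat index); out-of-range sites are invalid."""
    if isinstance(site, tuple):
        if not (0 <= site[0] < ledger.height and 0 <= site[1] < ledger.width):
            raise UsageError(f"site {site} out of range")
        site = site[0] * ledger.width + site[1]
    return ledger.claim(int(site))


def ledger_reset(ledger: ProcessedLedger) -> None:
    ledger.reset()


@dataclass
class TaskPlan:
    n_tasks: int
    attempts_per_task: int
    retry_limit: int = DEFAULT_RETRY_LIMIT
    batch_size: int = DEFAULT_BATCH


class _SiteDrawer:
    """Buffered uniform site draws from one task's private generator."""

    def __init__(self, rng: np.random.Generator, n_sites: int, chunk: int = 4096):
        self.rng = rng
        self.n = n_sites
        self.chunk = chunk
        self._buf = rng.integers(0, n_sites, size=chunk)
        self._pos = 0

    def draw(self) -> int:
        if self._pos >= self._buf.shape[0]:
            self._buf = self.rng.integers(0, self.n, size=self.chunk)
            self._pos = 0
        v = int(self._buf[self._pos])
        self._pos += 1
        return v


def _task_steps(state, ledger: ProcessedLedger, plan: TaskPlan,
                rng: np.random.Generator, stats: SweepStats,
                audit: list | None):
    """Generator form of one task's sweep work; yields once per batch.

    Threads drain it straight through; the interleaved engine round-robins
    between tasks' generators, so both engines share this exact code path.
    """
    args = state.kernel_args()
    drawer = _SiteDrawer(rng, state.lattice.height * state.lattice.width)
    n_adj = state.adjacency.size
    buf: list[int] = []

    def flush() -> None:
        if not buf:
            return
        sites = np.asarray(buf, dtype=np.int64)
        nbr = rng.integers(0, n_adj, size=sites.shape[0])
        us = rng.random(sites.shape[0])
        accepted = kernels.run_attempts(*args, sites, nbr, us)
        stats.attempts += sites.shape[0]
        stats.accepted += int(accepted)
        if audit is not None:
            audit.extend(buf)
        buf.clear()

    for _slot in range(plan.attempts_per_task):
        site = -1
        for _draw in range(plan.retry_limit + 1):
            s = drawer.draw()
            if ledger.claim(s):
                site = s
                break
            stats.retries += 1  # roll-back: redraw with a fresh site
        if site >= 0:
            buf.append(site)
            if len(buf) >= plan.batch_size:
                flush()
                yield
        else:
            stats.forfeited += 1
    flush()
    yield


def evolve_task(state, plan: TaskPlan, task_index: int,
                rng: np.random.Generator, ledger: ProcessedLedger,
                audit: list | None = None) -> SweepStats:
    """Run one task's share of a sweep to completion (serial driver)."""
    stats = SweepStats()
    ledger._begin_task()
    try:
        for _ in _task_steps(state, ledger, plan, rng, stats, audit):
            pass
    finally:
        ledger._end_task()
    return stats


def _run_threaded(state, n_tasks: int, seed, ledger: ProcessedLedger,
                  collect_audit: bool, retry_limit: int,
                  batch_size: int) -> SweepStats:
    n_sites = state.lattice.height * state.lattice.width
    plan = TaskPlan(n_tasks=n_tasks,
                    attempts_per_task=math.ceil(n_sites / n_tasks),
                    retry_limit=retry_limit, batch_size=batch_size)
    seedseq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = seedseq.spawn(n_tasks)
    per_stats = [SweepStats() for _ in range(n_tasks)]
    audits: list[list[int] | None] = [
        [] if collect_audit else None for _ in range(n_tasks)]
    errors: list[BaseException] = []

    def work(t: int) -> None:
        try:
            rng = np.random.default_rng(children[t])
            ledger._begin_task()
            try:
                for _ in _task_steps(state, ledger, plan, rng,
                                     per_stats[t], audits[t]):
                    pass
            finally:
                ledger._end_task()
        except BaseException as exc:  # noqa: BLE001 - reported to the caller
            errors.append(exc)

    threads = [threading.Thread(target=work, args=(t,), name=f"cpm-task-{t}")
               for t in range(n_tasks)]
    for th in threads:
        th.start()
    for th in threads:
        th.join()
    if errors:
        raise RuntimeError(f"{len(errors)} worker(s) failed") from errors[0]
    total = SweepStats()
    for s in per_stats:
        total += s
    if collect_audit:
        total.audit = np.concatenate(
            [np.asarray(a, dtype=np.int64) for a in audits]) \
            if any(audits) else np.empty(0, dtype=np.int64)
    return total


def run_sweep_parallel(state, seed, n_tasks: int,
                       collect_audit: bool = False,
                       retry_limit: int = DEFAULT_RETRY_LIMIT,
                       batch_size: int = DEFAULT_BATCH) -> SweepStats:
    """One sweep through the lock-free transactional-claim ledger."""
    ledger = ProcessedLedger(state.lattice.height, state.lattice.width)
    return _run_threaded(state, n_tasks, seed, ledger, collect_audit,
                         retry_limit, batch_size)


def run_sweep_locked(state, seed, n_tasks: int,
                     collect_audit: bool = False,
                     retry_limit: int = DEFAULT_RETRY_LIMIT,
                     batch_size: int = DEFAULT_BATCH) -> SweepStats:
    """One sweep with claims serialized by a mutual-exclusion lock."""
    ledger = LockedLedger(state.lattice.height, state.lattice.width)
    return _run_threaded(state, n_tasks, seed, ledger, collect_audit,
                         retry_limit, batch_size)


def run_sweep_interleaved(state, seed, n_tasks: int,
                          collect_audit: bool = False,
                          retry_limit: int = DEFAULT_RETRY_LIMIT) -> SweepStats:
    """Deterministic single-thread round-robin interleaving of the tasks.

    Same task code, same per-task streams, batch size one: a fixed seed
    replays the identical attempt sequence, which threads cannot promise.
    """
    n_sites = state.lattice.height * state.lattice.width
    plan = TaskPlan(n_tasks=n_tasks,
                    attempts_per_task=math.ceil(n_sites / n_tasks),
                    retry_limit=retry_limit, batch_size=1)
    seedseq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = seedseq.spawn(n_tasks)
    ledger = ProcessedLedger(state.lattice.height, state.lattice.width)
    per_stats = [SweepStats() for _ in range(n_tasks)]
    audits = [[] if collect_audit else None for _ in range(n_tasks)]
    gens = []
    for t in range(n_tasks):
        ledger._begin_task()
        gens.append(_task_steps(state, ledger, plan,
                                np.random.default_rng(children[t]),
                                per_stats[t], audits[t]))
    live = list(range(n_tasks))
    while live:
        still = []
        for t in live:
            try:
                next(gens[t])
                still.append(t)
            except StopIteration:
                ledger._end_task()
        live = still
    total = SweepStats()
    for s in per_stats:
        total += s
    if collect_audit:
        total.audit = np.concatenate(
            [np.asarray(a, dtype=np.int64) for a in audits]) \
            if any(audits) else np.empty(0, dtype=np.int64)
    return total


# -- engine registry for run_simulation -------------------------------------

def _serial_engine(state, seed, n_tasks, collect_audit=False):
    rng = np.random.default_rng(seed)
    return run_sweep_serial(state, rng, collect_audit=collect_audit)


def _ledger_engine(state, seed, n_tasks, collect_audit=False):
    return run_sweep_parallel(state, seed, n_tasks, collect_audit=collect_audit)


def _locked_engine(state, seed, n_tasks, collect_audit=False):
    return run_sweep_locked(state, seed, n_tasks, collect_audit=collect_audit)


def _interleaved_engine(state, seed, n_tasks, collect_audit=False):
    return run_sweep_interleaved(state, seed, n_tasks,
                                 collect_audit=collect_audit)


_ENGINES = {
    "serial": _serial_engine,
    "ledger": _ledger_engine,
    "locked": _locked_engine,
    "interleaved": _interleaved_engine,
}


def get_engine(name: str):
    try:
        return _ENGINES[name]
    except KeyError:
        raise UsageError(f"unknown engine {name!r}; choose from "
                         f"{tuple(_ENGINES)}") from None
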