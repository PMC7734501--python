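"""Programmatic fixtures: small random lattices for tests and benchmarks."""

from __future__ import annotations

import numpy as np

from .biology import BiologyParams
from .energy import CellType, EnergyParams
from .state import SimState

__all__ = ["random_blob_state", "random_label_noise_state"]


def random_blob_state(height: int, width: int, n_cells: int,
                      rng: np.random.Generator,
                      mean_size: int = 30,
                      energy: EnergyParams | None = None,
                      biology: BiologyParams | None = None) -> SimState:
    """Cells grown as random connected blobs from scattered seeds.

    Each cell starts at a random free site and accretes adjacent free sites
    at random until it reaches a geometric-ish target size; types alternate
    luminal / myoepithelial.  Statistics are recomputed exactly, so the
    result is a consistent state for energy and dynamics tests.
    """
    labels = np.zeros((height, width), dtype=np.int32)
    types = {}
    for k in range(1, n_cells + 1):
        free = np.argwhere(labels == 0)
        if free.size == 0:
            break
        seed = free[rng.integers(free.shape[0])]
        labels[seed[0], seed[1]] = k
        frontier = [tuple(seed)]
        target = max(1, int(rng.geometric(1.0 / mean_size)))
        size = 1
        while size < target and frontier:
            i = int(rng.integers(len(frontier)))
            r, c = frontier[i]
            opts = [(r + dr, c + dc)
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                    if 0 <= r + dr < height and 0 <= c + dc < width
                    and labels[r + dr, c + dc] == 0]
            if not opts:
                frontier.pop(i)
                continue
            nr, nc = opts[int(rng.integers(len(opts)))]
            labels[nr, nc] = k
            frontier.append((nr, nc))
            size += 1
        types[k] = CellType.LUMINAL if k % 2 else CellType.MYOEPITHELIAL
    return SimState.from_labels(labels, types, energy=energy, biology=biology)


def random_label_noise_state(height: int, width: int, n_cells: int,
                             rng: np.random.Generator,
                             fill: float = 0.6,
                             energy: EnergyParams | None = None) -> SimState:
    """Uniform random site labels (fragmented cells): a stress fixture for
    the incremental-versus-oracle energy checks."""
    labels = np.where(rng.random((height, width)) < fill,
                      rng.integers(1, n_cells + 1, size=(height, width)),
                      0).astype(np.int32)
    types = {k: CellType.LUMINAL if k % 2 else CellType.MYOEPITHELIAL
             for k in range(1, n_cells + 1)}
    return SimState.from_labels(labels, types, energy=energy)
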