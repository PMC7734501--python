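"""The simulation grid and exact geometric bookkeeping.

A Cellular Potts Model lattice is a 2-D array of non-negative integer labels:
label 0 is the medium (extracellular matrix / lumen), and every positive label
names one biological cell, i.e. the set of all sites carrying that label.
Sites outside the array behave as permanent medium (a "null" boundary): they
are valid adjacency partners but can never be the focal site of a copy
attempt.

All region measurements here are *full recomputations* from the label matrix.
They serve as the independent oracle for the incremental caches maintained by
the dynamics kernels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Adjacency",
    "Site",
    "Lattice",
    "ConfigurationError",
    "UsageError",
    "create_lattice",
    "neighbors",
    "region_volume",
    "region_interface_length",
    "region_centroid",
    "connected_components",
    "interface_lengths_all",
]


class ConfigurationError(ValueError):
    """Invalid configuration value (bad dimension, parameter out of range)."""


class UsageError(ValueError):
    """An operation was called outside its contract (e.g. out-of-range site)."""


class Site(NamedTuple):
    """A lattice coordinate, 0-based, row 0 at the top."""

    row: int
    col: int


class Adjacency(enum.Enum):
    """Neighborhood used for adhesion, interface length and copy sources.

    ``MOORE8`` (the 8 surrounding sites) is the default, standard CPM
    practice; ``VONNEUMANN4`` (the 4 axial sites) is available for
    comparison.  The choice is recorded in all run metadata.
    """

    MOORE8 = "moore8"
    VONNEUMANN4 = "vonneumann4"

    @property
    def offsets(self) -> np.ndarray:
        """(n, 2) array of fixed, symmetric neighbor offsets."""
        if self is Adjacency.MOORE8:
            offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                    (0, 1), (1, -1), (1, 0), (1, 1)]
        else:
            offs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
        return np.array(offs, dtype=np.int64)

    @property
    def forward_offsets(self) -> np.ndarray:
        """Half of the offsets, covering each unordered site pair once."""
        if self is Adjacency.MOORE8:
            offs = [(0, 1), (1, -1), (1, 0), (1, 1)]
        else:
            offs = [(0, 1), (1, 0)]
        return np.array(offs, dtype=np.int64)

    @property
    def size(self) -> int:
        return 8 if self is Adjacency.MOORE8 else 4

    @property
    def structure(self) -> np.ndarray:
        """Connectivity structuring element for ``scipy.ndimage.label``."""
        if self is Adjacency.MOORE8:
            return np.ones((3, 3), dtype=bool)
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Lattice:
    """The grid of cell labels.

    ``labels`` is an ``int32`` array of shape ``(height, width)``; every
    in-range site carries exactly one label.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ConfigurationError("lattice must be two-dimensional")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def in_range(self, site: Site) -> bool:
        return 0 <= site[0] < self.height and 0 <= site[1] < self.width

    def label_at(self, row: int, col: int) -> int:
        """Label at (row, col); out-of-range sites are permanent medium."""
        if 0 <= row < self.height and 0 <= col < self.width:
            return int(self.labels[row, col])
        return 0

    def padded(self) -> np.ndarray:
        """Labels with a one-site ring of permanent medium around them."""
        return np.pad(self.labels, 1, mode="constant", constant_values=0)


def create_lattice(height: int, width: int) -> Lattice:
    """A fresh all-medium lattice of the given shape."""
    if height < 1 or width < 1:
        raise ConfigurationError(
            f"lattice dimensions must be positive, got {height}x{width}")
    return Lattice(np.zeros((height, width), dtype=np.int32))


def neighbors(lattice: Lattice, site: Site,
              adjacency: Adjacency = Adjacency.MOORE8) -> list[tuple[Site, int]]:
    """The adjacency partners of ``site`` with their labels.

    Always returns exactly 8 (moore8) or 4 (vonneumann4) entries; partners
    outside the grid report the permanent medium label 0.
    """
    if not lattice.in_range(site):
        raise UsageError(f"focal site {site} out of range")
    out = []
    for dr, dc in adjacency.offsets:
        r, c = site[0] + int(dr), site[1] + int(dc)
        out.append((Site(r, c), lattice.label_at(r, c)))
    return out


def region_volume(lattice: Lattice, label: int) -> int:
    """Exact count of sites carrying ``label`` (0 if absent)."""
    if label < 1:
        raise UsageError("region_volume is defined for cell labels >= 1")
    return int(np.count_nonzero(lattice.labels == label))


def region_interface_length(lattice: Lattice, label: int,
                            adjacency: Adjacency = Adjacency.MOORE8) -> int:
    """Number of unordered adjacent site pairs with exactly one member in the cell.

    Pairs with out-of-range (permanent medium) partners count, so a single
    isolated site has interface 8 under moore8 even in a corner.
    """
    if label < 1:
        raise UsageError("interface length is defined for cell labels >= 1")
    pad = lattice.padded()
    mine = pad == label
    total = 0
    for dr, dc in adjacency.forward_offsets:
        shifted = np.roll(np.roll(mine, -int(dr), axis=0), -int(dc), axis=1)
        total += int(np.count_nonzero(mine ^ shifted))
    # np.roll wraps; the pad ring is medium so wrapped pairs pair medium with
    # medium except along the single wrapped border row/col, which pairs the
    # two opposite pad rings (both medium).  Hence no correction is needed for
    # a 1-wide pad and offsets of radius 1.
    return total


def interface_lengths_all(labels: np.ndarray, n_labels: int,
                          adjacency: Adjacency = Adjacency.MOORE8) -> np.ndarray:
    """Interface length of every label 0..n_labels-1 in one vectorized pass."""
    pad = np.pad(labels, 1, mode="constant", constant_values=0)
    counts = np.zeros(n_labels, dtype=np.int64)
    h, w = pad.shape
    for dr, dc in adjacency.forward_offsets:
        a = pad[max(dr, 0):h + min(dr, 0), max(dc, 0):w + min(dc, 0)]
        b = pad[max(-dr, 0):h + min(-dr, 0), max(-dc, 0):w + min(-dc, 0)]
        diff = a != b
        counts += np.bincount(a[diff], minlength=n_labels)[:n_labels]
        counts += np.bincount(b[diff], minlength=n_labels)[:n_labels]
    counts[0] = 0  # the medium is not a cell
    return counts


def region_centroid(lattice: Lattice, label: int) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the cell's sites."""
    rows, cols = np.nonzero(lattice.labels == label)
    if rows.size == 0:
        raise UsageError(f"label {label} occupies no site (empty region)")
    return float(rows.mean()), float(cols.mean())


def connected_components(
    lattice: Lattice,
    site_predicate: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    adjacency: Adjacency = Adjacency.MOORE8,
) -> tuple[np.ndarray, np.ndarray]:
    """Flood-fill partition of predicate-true sites.

    ``site_predicate`` is either a boolean mask of the lattice shape or a
    callable mapping the label matrix to such a mask.  Returns
    ``(component_map, areas)`` where ``component_map`` assigns 1..n to the
    predicate-true sites (0 elsewhere) and ``areas[i]`` is the site count of
    component ``i + 1``.
    """
    if callable(site_predicate):
        mask = np.asarray(site_predicate(lattice.labels), dtype=bool)
    else:
        mask = np.asarray(site_predicate, dtype=bool)
    if mask.shape != lattice.labels.shape:
        raise UsageError("predicate mask shape does not match the lattice")
    comp, n = ndimage.label(mask, structure=adjacency.structure)
    areas = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1)).astype(np.int64)
    return comp, areas
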