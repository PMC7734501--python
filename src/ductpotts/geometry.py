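"""Initial duct cross-section and the named experiment presets.

A mammary duct in cross section is modeled as two concentric rings of 10x10
square cells: an inner ring of ~50 luminal cells around the medium-filled
lumen, wrapped by a contiguous ring of myoepithelial cells, all embedded in
medium (stroma).  The published description fixes the cell size and the
luminal count; the lumen radius and myoepithelial count are derived so both
rings close (arc spacing of one cell diameter between square centers).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .biology import BiologyParams
from .dynamics import RunConfig
from .energy import CellType, EnergyParams
from .lattice import Adjacency, ConfigurationError, UsageError, create_lattice
from .state import SimState

__all__ = [
    "DuctGeometry",
    "GeometryConfig",
    "SimulationConfig",
    "build_duct",
    "build_initial_state",
    "preset",
    "PRESETS",
]

logger = logging.getLogger(__name__)

PRESETS = ("solid", "cribriform")


@dataclass(frozen=True)
class DuctGeometry:
    """Reference frame of the duct: fixed for the whole run.

    ``outer_radius`` is the outer edge of the myoepithelial ring; necrosis
    depth and the morphometric measures are taken relative to this circle.
    """

    center: tuple[float, float]
    lumen_radius: float
    outer_radius: float
    cell_diameter: int
    n_luminal: int
    n_myoepithelial: int

    def validate(self, height: int, width: int) -> None:
        if not 0 < self.lumen_radius < self.outer_radius:
            raise ConfigurationError("need 0 < lumen_radius < outer_radius")
        if self.outer_radius >= min(height, width) / 2:
            raise ConfigurationError(
                "duct does not fit: outer radius exceeds half the lattice")


@dataclass
class GeometryConfig:
    """User-facing geometry knobs; ``lumen_radius=None`` derives the radius
    that closes the luminal ring for the requested cell count."""

    n_luminal: int = 50
    cell_diameter: int = 10
    lumen_radius: float | None = None


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run."""

    height: int = 900
    width: int = 900
    energy: EnergyParams = field(default_factory=EnergyParams)
    biology: BiologyParams = field(default_factory=BiologyParams)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    run: RunConfig = field(default_factory=RunConfig)


def _paint_square(labels: np.ndarray, label: int, center_r: float,
                  center_c: float, d: int) -> None:
    """Paint a d x d square, first-writer-wins against earlier cells."""
    top = int(round(center_r - (d - 1) / 2))
    left = int(round(center_c - (d - 1) / 2))
    h, w = labels.shape
    r0, r1 = max(top, 0), min(top + d, h)
    c0, c1 = max(left, 0), min(left + d, w)
    block = labels[r0:r1, c0:c1]
    block[block == 0] = label


def _ring_centers(center: tuple[float, float], radius: float, n: int,
                  ) -> list[tuple[float, float]]:
    return [(center[0] + radius * math.sin(2 * math.pi * i / n),
             center[1] + radius * math.cos(2 * math.pi * i / n))
            for i in range(n)]


def build_duct(height: int, width: int,
               config: GeometryConfig | None = None,
               rng: np.random.Generator | None = None,
               energy: EnergyParams | None = None,
               biology: BiologyParams | None = None,
               adjacency: Adjacency = Adjacency.MOORE8) -> SimState:
    """Construct the initial duct state on a fresh lattice.

    Luminal squares are centered at equal angles on the circle of radius
    ``lumen_radius + d/2`` (overlaps resolved first-writer-wins in angular
    order), the myoepithelial ring immediately outside at ``lumen_radius +
    1.5 d``.  Every cell gets a random preferred growth direction (used only
    under anisotropic presets).  The returned state carries the
    :class:`DuctGeometry` reference frame.
    """
    config = config or GeometryConfig()
    rng = rng or np.random.default_rng()
    d = config.cell_diameter
    n_lum = config.n_luminal
    if config.lumen_radius is None:
        lumen_radius = n_lum * d / (2 * math.pi) - d / 2
    else:
        lumen_radius = float(config.lumen_radius)
    if lumen_radius <= 0:
        raise ConfigurationError(
            f"luminal ring with {n_lum} cells of diameter {d} has no lumen")
    r_lum = lumen_radius + d / 2
    r_myo = lumen_radius + 1.5 * d
    n_myo = math.ceil(2 * math.pi * r_myo / d)
    outer_radius = lumen_radius + 2 * d
    min_side = math.ceil(2 * (outer_radius + d))
    if min(height, width) < min_side:
        raise ConfigurationError(
            f"lattice {height}x{width} too small for this duct; "
            f"need at least {min_side}x{min_side}")

    state = SimState.empty(height, width, energy=energy, biology=biology,
                           adjacency=adjacency)
    center = ((height - 1) / 2, (width - 1) / 2)
    labels = state.lattice.labels
    for kind, radius, count in ((CellType.LUMINAL, r_lum, n_lum),
                                (CellType.MYOEPITHELIAL, r_myo, n_myo)):
        for cr, cc in _ring_centers(center, radius, count):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            k = state.add_cell(kind, pref_dir=(math.sin(theta),
                                               math.cos(theta)))
            _paint_square(labels, k, cr, cc, d)
    state.recompute_stats()
    # The recorded lumen radius is the realized clearance: the distance from
    # the center to the nearest occupied site, so the lumen interior is
    # strictly medium at sweep 0 even after integer square placement.
    rows, cols = np.nonzero(labels)
    clearance = float(np.hypot(rows - center[0], cols - center[1]).min())
    geometry = DuctGeometry(center=center,
                            lumen_radius=min(lumen_radius, clearance),
                            outer_radius=outer_radius, cell_diameter=d,
                            n_luminal=n_lum, n_myoepithelial=n_myo)
    geometry.validate(height, width)
    state.geometry = geometry
    if np.any(state.volume[1:state.n_labels] == 0):
        raise ConfigurationError("a placed cell was fully clipped away")
    logger.info(
        "duct built: %d luminal + %d myoepithelial cells, lumen radius %.1f, "
        "outer radius %.1f (derived; not part of the published table)",
        n_lum, n_myo, lumen_radius, outer_radius)
    return state


def _scaled_n_luminal(size: int) -> int:
    # Desk scaling: the full experiment uses 50 cells on 900x900; smaller
    # lattices take one luminal cell per 12 rows (25 at 300, 12 at 150).
    return 50 if size >= 600 else int(round(size / 12))


def preset(name: str, size: int = 900, master_seed: int = 0) -> SimulationConfig:
    """Named experiment configurations.

    ``solid``: published energy table, apoptosis probability 0.5%, isotropic
    growth — the duct fills completely.  ``cribriform``: apoptosis
    probability 1% and accentuated growth directions (anisotropy bias 2),
    forming crypt-like holes.  ``size`` scales the lattice (and the luminal
    cell count) for desk-scale runs.
    """
    if name not in PRESETS:
        raise UsageError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESETS)}")
    biology = BiologyParams(apoptosis_probability=0.005, anisotropy_bias=0.0)
    if name == "cribriform":
        biology = replace(biology, apoptosis_probability=0.01,
                          anisotropy_bias=2.0)
    return SimulationConfig(
        height=size, width=size,
        energy=EnergyParams(),
        biology=biology,
        geometry=GeometryConfig(n_luminal=_scaled_n_luminal(size)),
        run=RunConfig(preset=name, master_seed=master_seed))


def build_initial_state(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> SimState:
    return build_duct(config.height, config.width, config.geometry, rng,
                      energy=config.energy, biology=config.biology,
                      adjacency=config.run.adjacency)
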