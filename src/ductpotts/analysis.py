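"""Morphometric validation measures for simulated duct histology.

Three readouts compare a simulated end state with the histological picture:
the *lumen fill fraction* (solid DCIS ends with the duct light completely
invaded), the *crypt count* (cribriform DCIS shows sieve-like medium holes
inside the duct), and the *specific growth-rate trend* (tumor growth should
decelerate, i.e. the per-capita growth rate declines with time, as in
Gompertzian kinetics).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import DuctGeometry
from .lattice import Adjacency, UsageError

__all__ = ["lumen_fill_fraction", "count_crypts", "specific_growth_trend"]


def lumen_fill_fraction(lattice, geometry: DuctGeometry) -> float:
    """Fraction of sites strictly inside the initial lumen circle that carry
    a non-medium label (0 at sweep 0; 1 when the lumen is fully invaded)."""
    if geometry.lumen_radius <= 0:
        raise UsageError("degenerate geometry: non-positive lumen radius")
    rows, cols = np.indices(lattice.labels.shape)
    mask = np.hypot(rows - geometry.center[0],
                    cols - geometry.center[1]) < geometry.lumen_radius
    if not mask.any():
        raise UsageError("lumen circle contains no lattice site")
    inside = lattice.labels[mask]
    return float(np.count_nonzero(inside) / inside.size)


def count_crypts(lattice, geometry: DuctGeometry, min_area: int = 20) -> int:
    """Number of 4-connected medium holes of at least ``min_area`` sites
    lying strictly inside the duct's outer cell layer.

    Medium components are labeled over the whole lattice, so a cavity that
    connects to the exterior stroma through a gap in the ring is not a crypt.
    A component counts when all its sites fall inside the inner edge of the
    outer ring (outer radius minus one cell diameter).
    """
    medium = lattice.labels == 0
    comp, n = ndimage.label(medium, structure=Adjacency.VONNEUMANN4.structure)
    if n == 0:
        return 0
    rows, cols = np.indices(lattice.labels.shape)
    dist = np.hypot(rows - geometry.center[0], cols - geometry.center[1])
    inner_limit = geometry.outer_radius - geometry.cell_diameter
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(medium, comp, index=idx)
    max_dist = ndimage.maximum(dist, labels=comp, index=idx)
    return int(np.count_nonzero((areas >= min_area)
                                & (max_dist < inner_limit)))


def specific_growth_trend(series: pd.DataFrame, lag: int = 10,
                          smooth: int = 10) -> float:
    """Rank correlation of the specific growth rate with time.

    The tumor site count N(t) is smoothed with a centered rolling mean, the
    per-capita rate g(t) = (N(t+lag) - N(t)) / (lag * N(t)) is formed, and
    Spearman's rho between g and t is returned.  Exponential growth gives a
    rate independent of time (rho near 0); decelerating, Gompertz-like
    growth gives rho < 0.
    """
    if "tumor_sites" not in series:
        raise UsageError("series lacks a tumor_sites column")
    n = series["tumor_sites"].to_numpy(dtype=float)
    t = series["sweep"].to_numpy(dtype=float)
    if np.count_nonzero(n > 0) < 10:
        raise UsageError("need at least 10 rows with tumor_sites > 0")
    smoothed = pd.Series(n).rolling(smooth, center=True, min_periods=1).mean()
    smoothed = smoothed.to_numpy()
    if len(smoothed) <= lag:
        raise UsageError("series shorter than the growth-rate lag")
    base = smoothed[:-lag]
    if np.any(base <= 0):
        raise UsageError("specific growth rate undefined where N(t) <= 0")
    g = (smoothed[lag:] - base) / (lag * base)
    if np.allclose(g, g[0]):
        raise UsageError("constant specific growth rate: trend undefined")
    rho, _ = stats.spearmanr(t[:-lag], g)
    return float(rho)
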