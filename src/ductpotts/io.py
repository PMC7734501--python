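"""Snapshots, configuration files, manifests and rendering.

Snapshots are plain text: a small ``#``-prefixed header with one JSON
metadata line, followed by the label matrix as comma-separated integers, one
row per line.  Configurations and manifests round-trip through YAML/JSON so
a serial run is bit-identically replayable from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .biology import BiologyParams
from .dynamics import RunConfig
from .energy import EnergyParams
from .geometry import DuctGeometry, GeometryConfig, SimulationConfig
from .lattice import Adjacency

__all__ = [
    "Snapshot",
    "SnapshotFormatError",
    "write_snapshot",
    "read_snapshot",
    "snapshot_from_state",
    "render_snapshot",
    "config_to_dict",
    "config_from_dict",
    "dump_config",
    "load_config",
    "config_hash",
    "write_manifest",
]

_MAGIC = "# ductpotts-snapshot v1"


class SnapshotFormatError(ValueError):
    """Malformed snapshot file; the message carries the offending line."""


@dataclass
class Snapshot:
    sweep: int
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)


def snapshot_from_state(state, sweep: int,
                        config: SimulationConfig | None = None) -> Snapshot:
    """Bundle the current lattice with enough metadata to analyze it later."""
    meta: dict = {
        "adjacency": state.adjacency.value,
        "cells": {str(k): [int(state.cell_type[k]), int(state.cell_state[k])]
                  for k in range(1, state.n_labels)},
    }
    if state.geometry is not None:
        g = state.geometry
        meta["geometry"] = {
            "center": list(g.center), "lumen_radius": g.lumen_radius,
            "outer_radius": g.outer_radius, "cell_diameter": g.cell_diameter,
            "n_luminal": g.n_luminal, "n_myoepithelial": g.n_myoepithelial,
        }
    if config is not None:
        meta["config_hash"] = config_hash(config)
        meta["seed"] = config.run.master_seed
        meta["engine"] = config.run.engine
    return Snapshot(sweep=sweep, labels=state.lattice.labels.copy(),
                    metadata=meta)


def write_snapshot(snapshot: Snapshot, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"# sweep: {snapshot.sweep}\n")
        fh.write("# meta: " + json.dumps(snapshot.metadata,
                                         separators=(",", ":")) + "\n")
        for row in snapshot.labels:
            fh.write(",".join(map(str, row)) + "\n")


def read_snapshot(path: str | Path) -> Snapshot:
    path = Path(path)
    sweep = 0
    metadata: dict = {}
    rows: list[list[int]] = []
    width = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1:
                if line != _MAGIC:
                    raise SnapshotFormatError(
                        f"{path}:1: not a ductpotts snapshot")
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sweep:"):
                    sweep = int(body.split(":", 1)[1])
                elif body.startswith("meta:"):
                    try:
                        metadata = json.loads(body.split(":", 1)[1])
                    except json.JSONDecodeError as exc:
                        raise SnapshotFormatError(
                            f"{path}:{lineno}: bad metadata JSON") from exc
                continue
            try:
                row = [int(tok) for tok in line.split(",")]
            except ValueError as exc:
                raise SnapshotFormatError(
                    f"{path}:{lineno}: non-integer label") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise SnapshotFormatError(
                    f"{path}:{lineno}: ragged row ({len(row)} != {width})")
            rows.append(row)
    if not rows:
        raise SnapshotFormatError(f"{path}: snapshot has no data rows")
    return Snapshot(sweep=sweep, labels=np.array(rows, dtype=np.int32),
                    metadata=metadata)


def geometry_from_metadata(meta: dict) -> DuctGeometry | None:
    g = meta.get("geometry")
    if not g:
        return None
    return DuctGeometry(center=tuple(g["center"]),
                        lumen_radius=g["lumen_radius"],
                        outer_radius=g["outer_radius"],
                        cell_diameter=g["cell_diameter"],
                        n_luminal=g.get("n_luminal", 0),
                        n_myoepithelial=g.get("n_myoepithelial", 0))


def render_snapshot(snapshot: Snapshot, path: str | Path) -> None:
    """Rasterize to PNG: one base color per cell type, shade varying with
    cell id, necrotic cells darkened, medium white."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = snapshot.labels
    cells = snapshot.metadata.get("cells", {})
    n = int(labels.max(initial=0)) + 1
    lut = np.ones((n, 3))
    rng = np.random.default_rng(0)  # fixed palette
    shades = 0.45 + 0.5 * rng.random(n)
    base = {0: (1.0, 1.0, 1.0), 1: (0.85, 0.25, 0.25), 2: (0.25, 0.35, 0.85)}
    for k in range(1, n):
        tau, cstate = cells.get(str(k), [1, 0])
        r, g, b = base.get(tau, (0.5, 0.5, 0.5))
        s = shades[k]
        lut[k] = (r * s, g * s, b * s)
        if cstate == 1:  # necrotic: dark gray
            lut[k] = (0.25, 0.25, 0.25)
    img = lut[labels]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# -- configuration -----------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    e, b, g, r = config.energy, config.biology, config.geometry, config.run
    return {
        "height": config.height,
        "width": config.width,
        "energy": {
            "J": e.J.tolist(),
            "lambda_V": e.lambda_V.tolist(),
            "lambda_S": e.lambda_S.tolist(),
            "V_t": e.V_t.tolist(),
            "S_t": e.S_t.tolist(),
            "temperature": e.temperature,
            "elasticity_L": dict(e.elasticity_L),
            "elasticity_lambda": dict(e.elasticity_lambda),
        },
        "biology": dataclasses.asdict(b),
        "geometry": dataclasses.asdict(g),
        "run": {
            "sweeps": r.sweeps, "engine": r.engine, "n_tasks": r.n_tasks,
            "master_seed": r.master_seed, "adjacency": r.adjacency.value,
            "preset": r.preset, "snapshot_every": r.snapshot_every,
        },
    }


def config_from_dict(d: dict) -> SimulationConfig:
    e = d.get("energy", {})
    run = dict(d.get("run", {}))
    if "adjacency" in run:
        run["adjacency"] = Adjacency(run["adjacency"])
    return SimulationConfig(
        height=d.get("height", 900),
        width=d.get("width", 900),
        energy=EnergyParams(**e) if e else EnergyParams(),
        biology=BiologyParams(**d.get("biology", {})),
        geometry=GeometryConfig(**d.get("geometry", {})),
        run=RunConfig(**run),
    )


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config),
                                         sort_keys=False))


def load_config(path: str | Path) -> SimulationConfig:
    with Path(path).open() as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: SimulationConfig,
                   extra: dict | None = None) -> None:
    """Reproducibility manifest: full config, seed, code version."""
    from . import __version__

    doc = {"config": config_to_dict(config),
           "config_hash": config_hash(config),
           "master_seed": config.run.master_seed,
           "version": __version__}
    doc.update(extra or {})
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
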