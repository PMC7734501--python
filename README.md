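# ductpotts

A Cellular Potts Model (CPM / Glazier–Graner–Hogeweg) simulator of ductal
carcinoma *in situ* (DCIS) in a 2-D cross-section of a mammary duct, with a
**lock-free parallel sweep scheduler** built on an atomically claimed
*processed-node ledger*, alongside a serial reference engine and a lock-based
comparison engine.

## Who this is for

Computational biologists studying early ductal tumor growth with lattice
models, and systems programmers interested in optimistic-concurrency
scheduling of Monte Carlo lattice updates. The package is a library plus a
small CLI (`ductpotts`).

## The model

Each biological cell is the set of lattice sites carrying one integer label
(label 0 is the medium). The energy of a configuration is

```
H =  Σ_pairs  J(τ, τ′) (1 − δ_labels)          adhesion between different cells
  +  Σ_cells λ_V(τ) (V − V_t)²                 volume elasticity
  +  Σ_cells λ_S(τ) (S − S_t)²                 surface elasticity
```

where the first sum runs over unordered adjacent site pairs (Moore
neighborhood by default), `V`/`S` are a cell's site count and heterologous
contact-pair count, and `τ` is the cell type (luminal, myoepithelial or
medium). Dynamics are Metropolis copy attempts: a site adopts a random
neighbor's label with probability `exp(−ΔH/T_m)` if `ΔH > 0` and `1`
otherwise. One **sweep** gives every site exactly one attempt.

DCIS biology runs between sweeps: 15% of luminal cells proliferate (target
volume ramp plus principal-axis mitosis); a luminal cell with ≥ 10 alive
neighbors within 2.5 cell diameters may enter apoptosis (0–1% per sweep);
cells ≥ 10 cell diameters inward of the duct's outer layer become necrotic
(frozen, still occupying space). Two presets, `solid` and `cribriform`,
differ in apoptosis probability (0.5% vs 1%) and growth anisotropy.

The parallel engine keeps one shared lattice plus a shared ledger Ξ of
already-attempted sites. Workers draw random sites and race on an atomic
claim; a failed claim simply redraws (the optimistic roll-back). Only
focal-site exclusivity is guaranteed — neighbor reads may be stale — which is
the scheme's stated safety condition. A deterministic single-thread
interleaving engine replays the same task code exactly for testing.

## Worked example

```
$ ductpotts run --preset solid --size 300 --sweeps 500 --seed 1 --out solid_demo
run complete: sweep 500, tumor sites 2726, lumen fill 0.061

$ ductpotts analyze solid_demo/snapshot_000500.csv --series solid_demo/series.csv
lumen_fill_fraction: 0.0608
crypt_count: 0
specific_growth_trend: +0.5610
```

This simulates the desk-scale solid-DCIS duct (300×300 lattice, 25 luminal
cells) for 500 sweeps. `tumor sites` is the area occupied by luminal-type
cells; `lumen_fill_fraction` is the fraction of the initial lumen now
occupied by cells (0.06: with the published energy table growth is slow — see
the methods note); `crypt_count` is the number of enclosed medium cavities
inside the duct; `specific_growth_trend` is the rank correlation of the
per-capita growth rate with time (positive: growth still accelerating at
this horizon).

Engine comparison:

```
$ ductpotts compare-engines --size 150 --sweeps 100 --replicates 20 --tasks 4
serial: mean final tumor sites ...
ledger: mean final tumor sites ...
KS serial vs ledger: D=... p=...
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the default duct initial condition from scratch on the full
900×900 benchmark lattice and reports the number of distinct luminal cell
labels the initializer creates, as a machine-readable JSON file.

## Layout

- `src/ductpotts/lattice.py` — grid, adjacency, exact region bookkeeping
- `src/ductpotts/energy.py` — Hamiltonian terms and the full-state oracle
- `src/ductpotts/kernels.py` — JIT incremental ΔH and attempt loops
- `src/ductpotts/dynamics.py` — Metropolis attempts, sweeps, run loop
- `src/ductpotts/biology.py` — proliferation, mitosis, apoptosis, necrosis
- `src/ductpotts/geometry.py` — duct construction, presets
- `src/ductpotts/engines.py` — ledger / locked / interleaved engines
- `src/ductpotts/analysis.py` — lumen fill, crypt count, growth trend
- `src/ductpotts/io.py`, `src/ductpotts/cli.py` — snapshots, configs, CLI
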