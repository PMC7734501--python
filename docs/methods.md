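# Methods

## Model definition

The simulator is a two-dimensional Cellular Potts Model. The lattice ζ holds
one non-negative integer label per site; a cell is the (not necessarily
connected) set of sites with one label, and label 0 is the medium. Sites
outside the lattice behave as permanent medium ("null" boundary): they are
valid adjacency partners but never focal sites.

The Hamiltonian has three terms:

* **Adhesion** — over *unordered* adjacent site pairs with different labels,
  `J(τ, τ′)` indexed by cell type. The double-indexed adhesion sum in the
  standard CPM formula is ambiguous between ordered and unordered counting;
  we count each contact once, which preserves the published adhesion
  hierarchy `J(L,L) < J(M,L) < J(M,M)`. Contacts with the medium carry zero
  energy by default (the published table has no medium rows); this is
  configurable.
* **Volume elasticity** — `λ_V(τ)(V − V_t)²` over alive cells.
* **Surface elasticity** — `λ_S(τ)(S − S_t)²` over alive cells, where `S` is
  the cell's heterologous contact-pair count (so an isolated site has S = 8
  in the Moore neighborhood, boundary pads included).

The published parameter table is adopted verbatim, including `S_t,L = −31`
(algebraically admissible: the quadratic penalty stays well-defined) and
`V_t,L = 78` against the 100-site initial cells. The table's elasticity rows
(`L`, `λ_L`) are parsed, stored and serialized but contribute no energy: the
Hamiltonian has no length-constraint term. Both oddities are logged once per
run.

Dynamics follow the Metropolis rule: probability `1` when `ΔH ≤ 0`, else
`exp(−ΔH/T_m)`. Acceptance is `u < p` with `u ~ Uniform[0,1)` (equivalent to
the ≥ convention up to a measure-zero event). The copy direction is
*invasion*: the focal site adopts the randomly chosen neighbor's label.
Cells may fragment — there is no connectivity constraint — and fragments
keep their cell id. A cell whose volume reaches zero becomes `removed` and
drops out of the volume/surface sums.

### Temperature

The Metropolis temperature has no published value. The package default is
`T_m = 10`, prominently configurable and logged at the start of every run.
Because the default energy scales (λ_V = 78, λ_S = 31) put typical ΔH in the
10²–10⁴ range, dynamics at T_m = 10 are effectively downhill-only; the
temperature only matters for rescaled parameterizations.

## Units of time

One *sweep* gives every lattice site exactly one copy attempt (each site at
most once per sweep). The serial engine realizes this as a uniformly random
permutation of all sites; the parallel engines realize it through the claim
ledger, which is the fixed point of the original skip-if-claimed rule. Run
lengths are configured in sweeps.

## Biology phases

Biology runs between sweeps (never interleaved with attempts), keeping all
engines comparable:

1. **Growth and mitosis.** Each alive proliferative cell's target volume
   increases by `growth_rate` (default 1 site/sweep). Any alive cell whose
   volume reaches `division_volume_factor × cell_diameter²` (default 2 ×
   100 = 200 sites) is bisected by the line through its centroid
   perpendicular to its principal axis; the smaller side receives a fresh
   label, daughters inherit type and proliferative flag, and both targets
   reset to the type's `V_t`. The growth mechanism itself is not specified
   by the source model description; the target-ramp-plus-bisection scheme is
   standard CPM practice.
2. **Apoptosis.** Overcrowding counts, taken simultaneously on the pre-phase
   state, are the number of *other* alive cells whose centroids lie within
   `2.5 × cell_diameter = 25` sites. Each alive luminal cell at or above the
   10-neighbor threshold dies independently with `apoptosis_probability`
   (0.5% per sweep for the solid preset, 1% for cribriform — the published
   0–1% band). Death reverts the cell's full site set to medium atomically.
   Apoptosis is restricted to luminal cells (the overcrowding rule is framed
   around luminal overgrowth); whether it should also cover myoepithelium is
   an open reading.
3. **Necrosis.** Cells whose centroid lies `10 × cell_diameter = 100` sites
   or more radially inward from the duct's outer-layer circle become
   necrotic: frozen (never relabeled, never copy sources), excluded from the
   bulk energy terms, adhesion pairs involving them carry zero energy, and
   they keep occupying space. Necrosis is absorbing. The outer layer is the
   *initial* geometry's circle — the duct frame does not move — which is a
   documented simplification. At desk scales (outer radius < 100 sites)
   necrosis is geometrically unreachable and therefore inert.

### Anisotropic (cribriform) growth

The cribriform variant's "accentuated growth directions" have no stated
mechanism. The package realizes them as an acceptance bias: every cell draws
a uniformly random preferred unit direction at creation, and any copy
attempt that extends a cell along it (positive dot product of the focal
displacement from the cell centroid with the preferred direction) has ΔH
reduced by `anisotropy_bias` β before the Metropolis rule. β = 0 (solid)
recovers the isotropic model; the cribriform preset uses β = 2. At the
default energy scales β = 2 is a weak perturbation; it is retained as the
documented stand-in rather than tuned.

## Duct construction

The duct is two concentric rings of 10 × 10-site square cells around a
medium lumen. The luminal count (default 50) and the cell size are
published; the lumen radius and myoepithelial count are not, so they are
derived so both rings close: luminal squares are centered at equal angles on
the circle of radius `n_luminal·d/2π` (arc spacing exactly one cell
diameter), the myoepithelial ring sits immediately outside at
`lumen_radius + 1.5 d` with `⌈2π r/d⌉` cells, and overlaps from integer
placement are resolved first-writer-wins in angular order. The recorded
lumen radius is the *realized clearance* — the distance from the duct center
to the nearest occupied site — so the lumen interior is strictly medium at
sweep 0. Desk scaling uses one luminal cell per 12 lattice rows below a 600
side (25 cells at 300 × 300, 12 at 150 × 150); the full benchmark lattice is
900 × 900 with 50 cells.

## Engines and the claim ledger

All engines guarantee per-sweep focal-site exclusivity; none guarantees more
(concurrent neighbor reads may be stale, by design).

* **serial** — random permutation of all sites; bit-identical replay from a
  seed.
* **ledger** — Python threads over the shared label buffer. The lock-free
  claim is a single atomic `dict.setdefault` insertion keyed by flat site
  index with a unique token (linearizable under the interpreter lock). A
  failed claim is the optimistic roll-back: the worker redraws, up to
  `retry_limit` (default 100) before forfeiting the slot, which guarantees
  sweep termination; forfeits are reported in the per-sweep statistics.
  Claimed sites are processed in small batches (default 64) through a
  `nogil` JIT kernel so threads overlap in the numerical work; batching
  amortizes interpreter overhead only — each claim remains individual and
  atomic, so the contract is unchanged.
* **locked** — identical scheduling with claims serialized through a mutex;
  exists for relative benchmarking.
* **interleaved** — the same per-task generator code driven single-threaded
  in round-robin with batch size one: deterministic exact replay of a
  task-interleaved sweep.

The ledger stores sites only; the occupying label is recoverable from the
lattice and redundant for the claim decision. The ledger is reset (fresh)
every sweep: "already attempted" is a per-sweep property. Biology phases run
once per sweep after all workers join and are never parallelized.

## Randomness

A single master seed feeds a `SeedSequence`; independent child streams are
spawned for duct construction, biology, and each sweep (and, inside parallel
sweeps, each task). Serial and interleaved runs replay exactly; threaded
runs are reproducible only in distribution.

## Numerical choices

* Energies are float64 throughout; with the default integer-valued
  parameters every ΔH is integer-valued, so the antisymmetry
  ΔH(A→B) = −ΔH(B→A) holds exactly, and the incremental ΔH is tested
  against the full-Hamiltonian recompute at 10⁻⁹ absolute tolerance.
* Volume, interface length and centroid sums are incremental caches,
  validated against full recomputation (`SimState.check_consistency`).
* Division ties (sites projecting exactly onto the split line) go to the
  parent side; a split that would empty one side is deferred a sweep.
* The crypt counter labels medium 4-connectedly over the whole lattice and
  counts components of ≥ 20 sites whose every site lies inside the outer
  ring's inner edge, so cavities open to the stroma are not crypts.
* The specific growth rate uses a centered 10-sweep rolling mean and a
  10-sweep lag; exact exponential series give a flat trend, Gompertz series
  a negative one.

## What the synthetic world does and does not establish

Runs start from the idealized two-ring duct, not from histology; medium is
passive (no nutrient field — necrosis uses a distance proxy); there is no
basement membrane object, so containment relies on the myoepithelial ring's
energetics. A green morphology test therefore establishes internal
consistency of the stated model, not histological realism.

## Known limitations (measured, not tuned away)

With the published table adopted verbatim, the surface stiffness of luminal
cells (λ_S = 31 against S_t = −31) prices one extra boundary contact pair at
roughly `31·2·(S+31)·2 ≈ 1.6×10⁴`, which downhill-only dynamics overcome
only once a cell's volume trails its target by ~100 sites. Proliferative
cells therefore lag their ramped targets by ~110 sites, and the
post-division target reset to `V_t = 78` re-opens that dead zone every
generation (~230 sweeps per generation measured). Consequences at desk
scale, 500 sweeps: the lumen fill fraction reaches ~0.06–0.09 rather than
near-complete invasion, and the growth trend is still positive
(pre-saturation). The corresponding two acceptance-level morphology tests
fail and are intentionally left failing; no parameter was adjusted toward
passing them. Separately, the myoepithelial target volume of 5 causes the
outer ring to shrink to beads and the cells to evaporate by fluctuation
(removal is energetically favorable once a cell is small), so long runs lose
the myoepithelial layer — again a property of the published table.
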