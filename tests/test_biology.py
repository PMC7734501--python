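"""Proliferation, mitosis, overcrowding apoptosis, nutrient necrosis."""

import math

import numpy as np
import pytest

import ductpotts as dp
from ductpotts.biology import (BiologyParams, apply_apoptosis, apply_necrosis,
                               assign_proliferative, grow_and_divide,
                               overpopulation_count)
from ductpotts.energy import CellState, CellType
from ductpotts.geometry import DuctGeometry
from ductpotts.lattice import ConfigurationError, UsageError
from ductpotts.state import SimState


def make_luminal_grid(n_cells, spacing=10, size=None):
    """Single-site luminal cells on a square grid (centroids = positions)."""
    rows = math.ceil(math.sqrt(n_cells))
    size = size or (rows * spacing + 2)
    labels = np.zeros((size, size), dtype=np.int32)
    types = {}
    k = 0
    for idx in range(n_cells):
        k += 1
        r = 1 + (idx // rows) * spacing
        c = 1 + (idx % rows) * spacing
        labels[r, c] = k
        types[k] = CellType.LUMINAL
    return SimState.from_labels(labels, types)


class TestParams:
    @pytest.mark.parametrize("kw", [
        {"proliferative_fraction": 1.5},
        {"apoptosis_probability": -0.1},
        {"apoptosis_radius": 0.0},
        {"anisotropy_bias": -1.0},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            BiologyParams(**kw)

    def test_derived_site_distances(self):
        p = BiologyParams()
        assert p.apoptosis_radius_sites == 25.0
        assert p.necrosis_distance_sites == 100.0
        assert p.division_volume == 200.0


class TestAssignProliferative:
    def test_fifty_luminal_at_default_fraction_gives_eight(self, rng):
        state = make_luminal_grid(50)
        assert assign_proliferative(state, 0.15, rng) == 8  # round(7.5)
        assert int(state.proliferative.sum()) == 8

    def test_zero_fraction_flags_none(self, rng):
        state = make_luminal_grid(10)
        assert assign_proliferative(state, 0.0, rng) == 0

    def test_full_fraction_spares_myoepithelium(self, rng):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[1, 1], labels[1, 15], labels[15, 1] = 1, 2, 3
        state = SimState.from_labels(labels, {1: CellType.LUMINAL,
                                              2: CellType.LUMINAL,
                                              3: CellType.MYOEPITHELIAL})
        assert assign_proliferative(state, 1.0, rng) == 2
        assert not state.proliferative[3]

    def test_fraction_out_of_range_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            assign_proliferative(make_luminal_grid(5), 1.2, rng)


class TestGrowAndDivide:
    def test_no_proliferative_cells_is_a_noop(self, rng):
        state = make_luminal_grid(5)
        before = state.lattice.labels.copy()
        assert grow_and_divide(state, rng) == []
        assert np.array_equal(state.lattice.labels, before)

    def test_rectangle_bisects_across_long_axis(self, rng):
        labels = np.zeros((20, 30), dtype=np.int32)
        labels[4:14, 4:24] = 1  # 10 x 20 = 200 sites: at the split threshold
        state = SimState.from_labels(labels, {1: CellType.LUMINAL})
        events = grow_and_divide(state, rng)
        assert len(events) == 1
        ev = events[0]
        assert ev.parent_volume == ev.daughter_volume == 100
        assert ev.daughter != ev.parent
        # each daughter is a 10x10 half of the rectangle
        for k in (ev.parent, ev.daughter):
            coords = np.argwhere(state.lattice.labels == k)
            assert coords.shape[0] == 100
            assert np.ptp(coords[:, 1]) == 9  # columns split, rows kept
        state.check_consistency()

    def test_division_conserves_sites_and_resets_targets(self, rng):
        labels = np.zeros((20, 30), dtype=np.int32)
        labels[4:14, 4:25] = 1  # 210 sites, odd split
        state = SimState.from_labels(labels, {1: CellType.LUMINAL})
        state.proliferative[1] = True
        occupied_before = int(np.count_nonzero(state.lattice.labels))
        events = grow_and_divide(state, rng)
        assert len(events) == 1
        assert int(np.count_nonzero(state.lattice.labels)) == occupied_before
        ev = events[0]
        assert ev.daughter_volume <= ev.parent_volume  # smaller side is new
        assert state.target_volume[ev.parent] == state.energy.V_t[1]
        assert state.target_volume[ev.daughter] == state.energy.V_t[1]
        assert state.proliferative[ev.daughter]

    def test_growth_ramps_target_volume(self, rng):
        state = make_luminal_grid(4)
        state.proliferative[2] = True
        t0 = state.target_volume[2]
        grow_and_divide(state, rng)
        assert state.target_volume[2] == t0 + state.biology.growth_rate
        assert state.target_volume[1] == state.energy.V_t[1]  # unflagged


class TestOverpopulation:
    def test_isolated_cell_counts_zero(self):
        state = make_luminal_grid(1, size=60)
        assert overpopulation_count(state, 1, 25.0) == 0

    def test_ring_of_twelve_within_radius(self):
        """12 single-site cells on a circle of radius 20 around the focal
        centroid all fall inside the 25-site apoptosis radius."""
        size = 101
        labels = np.zeros((size, size), dtype=np.int32)
        center = size // 2
        labels[center, center] = 1
        types = {1: CellType.LUMINAL}
        for m in range(12):
            ang = 2 * math.pi * m / 12
            r = center + int(round(20 * math.sin(ang)))
            c = center + int(round(20 * math.cos(ang)))
            labels[r, c] = m + 2
            types[m + 2] = CellType.LUMINAL
        state = SimState.from_labels(labels, types)
        assert overpopulation_count(state, 1, 25.0) == 12

    def test_counting_is_symmetric(self):
        """At equal radii, b is counted for a iff a is counted for b."""
        state = make_luminal_grid(9, spacing=7)
        radius = 8.0
        counted = {(a, b): math.dist(state.centroid_of(a),
                                     state.centroid_of(b)) <= radius
                   for a in range(1, 10) for b in range(1, 10) if a != b}
        assert all(counted[a, b] == counted[b, a] for a, b in counted)
        for a in range(1, 10):
            assert overpopulation_count(state, a, radius) == sum(
                counted[a, b] for b in range(1, 10) if b != a)

    def test_removed_cell_rejected(self):
        state = make_luminal_grid(2)
        state.cell_state[2] = int(CellState.REMOVED)
        with pytest.raises(UsageError):
            overpopulation_count(state, 2, 25.0)


class TestApoptosis:
    def _crowded_state(self, p):
        state = make_luminal_grid(25, spacing=5)
        state.biology = BiologyParams(apoptosis_probability=p)
        return state

    def test_zero_probability_never_removes(self, rng):
        state = self._crowded_state(0.0)
        for _ in range(20):
            assert apply_apoptosis(state, rng) == []

    def test_certain_apoptosis_removes_crowded_cell(self, rng):
        state = self._crowded_state(1.0)
        removed = apply_apoptosis(state, rng)
        assert removed  # the dense grid is overcrowded
        for k in removed:
            assert state.cell_state[k] == int(CellState.REMOVED)
            assert not (state.lattice.labels == k).any()
        state.check_consistency()

    def test_removal_rate_matches_bernoulli_probability(self, rng):
        """~10^4 independent draws at p = 0.01: removal rate within 3 SE."""
        p = 0.01
        draws = removals = 0
        base = self._crowded_state(p)
        while draws < 10_000:
            state = base.copy()
            dead = apply_apoptosis(state, rng)
            draws += 25  # every cell in the dense grid is overcrowded
            removals += len(dead)
        se = math.sqrt(p * (1 - p) / draws)
        assert abs(removals / draws - p) < 3 * se


class TestNecrosis:
    def test_default_duct_cannot_necrose(self, desk_duct):
        # outer radius < 100 sites: the necrosis depth is out of reach
        assert desk_duct.geometry.outer_radius < 100
        assert apply_necrosis(desk_duct.copy()) == []

    def test_deep_cell_in_wide_duct_necroses(self):
        state = make_luminal_grid(1, size=99)  # single cell near the center
        geom = DuctGeometry(center=state.centroid_of(1), lumen_radius=120.0,
                            outer_radius=150.0, cell_diameter=10,
                            n_luminal=1, n_myoepithelial=0)
        assert apply_necrosis(state, geom) == [1]
        assert state.cell_state[1] == int(CellState.NECROTIC)

    def test_necrotic_cell_is_frozen(self, rng):
        """Volume of a necrotic cell is untouched by 100 further sweeps."""
        from ductpotts.dynamics import run_sweep_serial
        from ductpotts.testing import random_blob_state

        state = random_blob_state(20, 20, n_cells=5, rng=rng)
        state.cell_state[1] = int(CellState.NECROTIC)
        v0 = int(state.volume[1])
        mask0 = state.lattice.labels == 1
        for _ in range(100):
            run_sweep_serial(state, rng)
        assert int(state.volume[1]) == v0
        assert np.array_equal(state.lattice.labels == 1, mask0)
        # absorbing: still necrotic
        assert state.cell_state[1] == int(CellState.NECROTIC)
        state.check_consistency()
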