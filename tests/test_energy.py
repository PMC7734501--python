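"""Hamiltonian terms, the incremental delta-H, and their oracles."""

import numpy as np
import pytest

from conftest import random_focal_with_neighbor
from ductpotts import kernels
from ductpotts.energy import (CellState, CellType, EnergyParams,
                              adhesion_term, delta_h_for_copy, surface_term,
                              total_hamiltonian, volume_term)
from ductpotts.lattice import ConfigurationError, Site, UsageError
from ductpotts.state import SimState
from ductpotts.testing import random_blob_state, random_label_noise_state


def brute_adhesion(state):
    """Double loop over every site and offset: each unordered pair counted
    once, J looked up by cell type, zero for same-label or necrotic pairs."""
    labels = state.lattice.labels
    h, w = labels.shape
    J = state.energy.J
    total = 0.0
    seen = set()
    for i in range(h):
        for j in range(w):
            for dr, dc in state.adjacency.offsets:
                r, c = i + dr, j + dc
                a = labels[i, j]
                b = labels[r, c] if 0 <= r < h and 0 <= c < w else 0
                key = frozenset([(i, j), (r, c)])
                if key in seen or a == b:
                    continue
                seen.add(key)
                if (state.cell_state[a] == int(CellState.NECROTIC)
                        or state.cell_state[b] == int(CellState.NECROTIC)):
                    continue
                total += J[state.cell_type[a], state.cell_type[b]]
    return total


class TestParams:
    def test_default_hierarchy_holds(self):
        assert EnergyParams().check_adhesion_hierarchy()

    def test_asymmetric_j_rejected(self):
        J = np.zeros((3, 3))
        J[1, 2] = 5.0
        with pytest.raises(ConfigurationError):
            EnergyParams(J=J)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ConfigurationError):
            EnergyParams(temperature=0.0)


class TestTerms:
    def test_uniform_lattice_has_no_adhesion(self):
        labels = np.full((6, 6), 1, dtype=np.int32)
        state = SimState.from_labels(labels, {1: CellType.LUMINAL})
        assert adhesion_term(state) == 0.0

    def test_two_diagonal_luminal_singletons(self):
        # one heterologous L-L contact at the published value; medium J = 0
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[2, 2] = 1
        labels[3, 3] = 2
        state = SimState.from_labels(labels, {1: CellType.LUMINAL,
                                              2: CellType.LUMINAL})
        assert adhesion_term(state) == pytest.approx(-20.0)
        assert adhesion_term(state) == pytest.approx(brute_adhesion(state))

    def test_adhesion_matches_brute_force(self, rng):
        state = random_label_noise_state(9, 9, n_cells=4, rng=rng)
        assert adhesion_term(state) == pytest.approx(brute_adhesion(state))

    def test_volume_term_off_target_luminal(self):
        # one luminal cell of 100 sites against target 78: 78 * 22^2
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[1:11, 1:11] = 1
        state = SimState.from_labels(labels, {1: CellType.LUMINAL})
        assert volume_term(state) == pytest.approx(78 * 22 ** 2)

    def test_terms_vanish_at_target_and_for_removed(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:4, 2:4] = 1
        state = SimState.from_labels(labels, {1: CellType.LUMINAL})
        state.target_volume[1] = state.volume[1]
        state.target_surface[1] = state.interface[1]
        assert volume_term(state) == 0.0
        assert surface_term(state) == 0.0
        state.lattice.labels[:] = 0
        state.recompute_stats()  # volume 0 -> removed, drops out of H
        assert volume_term(state) == 0.0 and surface_term(state) == 0.0

    def test_surface_term_single_site_myoepithelial(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[2, 2] = 1
        state = SimState.from_labels(labels, {1: CellType.MYOEPITHELIAL})
        # S = 8 under moore8, published target 1 and stiffness 1
        assert surface_term(state) == pytest.approx((8 - 1) ** 2)

    def test_total_is_sum_of_terms(self, blob_state):
        assert total_hamiltonian(blob_state) == pytest.approx(
            adhesion_term(blob_state) + volume_term(blob_state)
            + surface_term(blob_state))

    def test_total_invariant_under_relabeling_within_type(self, rng):
        state = random_label_noise_state(10, 10, n_cells=4, rng=rng)
        h0 = total_hamiltonian(state)
        # swap two same-type labels (1 and 3 are both luminal)
        labels = state.lattice.labels
        one, three = labels == 1, labels == 3
        labels[one], labels[three] = 3, 1
        state.recompute_stats()
        assert total_hamiltonian(state) == pytest.approx(h0)

    def test_reduces_to_contact_count_when_only_adhesion(self, rng):
        # lambda_V = lambda_S = 0, one J for all cell contacts:
        # H = J * number of heterologous contacts
        params = EnergyParams(J=np.full((3, 3), 2.5),
                              lambda_V=np.zeros(3), lambda_S=np.zeros(3))
        state = random_label_noise_state(9, 9, n_cells=3, rng=rng,
                                         energy=params)
        pad = state.lattice.padded()
        contacts = 0
        for dr, dc in state.adjacency.forward_offsets:
            a = np.roll(np.roll(pad, -dr, axis=0), -dc, axis=1)
            contacts += int(np.count_nonzero((pad != a)))
        assert total_hamiltonian(state) == pytest.approx(2.5 * contacts)

    def test_necrosis_removes_cell_from_bulk_terms(self, blob_state):
        others_v = volume_term(blob_state)
        others_s = surface_term(blob_state)
        blob_state.cell_state[1] = int(CellState.NECROTIC)
        dv = (blob_state.volume[1] - blob_state.target_volume[1]) ** 2
        ds = (blob_state.interface[1] - blob_state.target_surface[1]) ** 2
        lam_v = blob_state.energy.lambda_V[blob_state.cell_type[1]]
        lam_s = blob_state.energy.lambda_S[blob_state.cell_type[1]]
        assert volume_term(blob_state) == pytest.approx(others_v - lam_v * dv)
        assert surface_term(blob_state) == pytest.approx(others_s - lam_s * ds)
        assert adhesion_term(blob_state) == pytest.approx(
            brute_adhesion(blob_state))


class TestDeltaH:
    def test_non_adjacent_source_rejected(self, blob_state):
        with pytest.raises(UsageError):
            delta_h_for_copy(blob_state, Site(0, 0), 10**6)

    def test_matches_full_recompute(self, rng):
        """Incremental delta-H equals H(after) - H(before) on random attempts."""
        state = random_blob_state(20, 20, n_cells=6, rng=rng)
        for _ in range(100):
            focal, src = random_focal_with_neighbor(state, rng)
            before = total_hamiltonian(state)
            dh = delta_h_for_copy(state, focal, src)
            kernels.apply_flip(state.lattice.labels, state.cell_state,
                               state.volume, state.interface, state.crow_sum,
                               state.ccol_sum, state.adjacency.offsets,
                               focal.row, focal.col, src)
            assert total_hamiltonian(state) - before == pytest.approx(
                dh, abs=1e-9)
            state.check_consistency()

    def test_antisymmetry_exact(self, rng):
        state = random_blob_state(15, 15, n_cells=5, rng=rng)
        for _ in range(50):
            focal, src = random_focal_with_neighbor(state, rng)
            old = state.lattice.label_at(*focal)
            dh_fwd = delta_h_for_copy(state, focal, src)
            kernels.apply_flip(state.lattice.labels, state.cell_state,
                               state.volume, state.interface, state.crow_sum,
                               state.ccol_sum, state.adjacency.offsets,
                               focal.row, focal.col, src)
            nbr_labels = {state.lattice.label_at(focal.row + int(dr),
                                                 focal.col + int(dc))
                          for dr, dc in state.adjacency.offsets}
            if (state.cell_state[old] == int(CellState.REMOVED)
                    or old not in nbr_labels):
                continue  # inverse copy is not a legal attempt anymore
            dh_back = delta_h_for_copy(state, focal, old)
            assert dh_back == -dh_fwd  # integer-valued arithmetic: exact
            kernels.apply_flip(state.lattice.labels, state.cell_state,
                               state.volume, state.interface, state.crow_sum,
                               state.ccol_sum, state.adjacency.offsets,
                               focal.row, focal.col, old)
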