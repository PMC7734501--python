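"""JIT-compiled hot paths: incremental delta-H and copy-attempt loops.

These kernels operate on the flat numpy arrays held by ``SimState`` (label
matrix plus per-label registry columns).  ``nogil=True`` lets the threaded
parallel engines overlap attempt processing while Python-level ledger claims
serialize on the interpreter lock.

Cell state codes: 0 = alive, 1 = necrotic (frozen), 2 = removed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["delta_h", "apply_flip", "attempt_site", "run_attempts"]

_JIT = dict(cache=True, nogil=True)


@njit(**_JIT)
def delta_h(labels, ctype, cstate, volume, interface, target_volume,
            target_surface, J, lambda_V, lambda_S, offs, i, j, b):
    """H(after relabeling site (i,j) to b) - H(before), computed locally.

    Adhesion pairs involving necrotic cells carry zero energy; a cell whose
    volume would reach zero drops out of the volume/surface sums (it becomes
    removed).  Out-of-range neighbors are permanent medium (label 0).
    """
    H, W = labels.shape
    a = labels[i, j]
    nh = offs.shape[0]
    n_a = 0
    n_b = 0
    dJ = 0.0
    for k in range(nh):
        r = i + offs[k, 0]
        c = j + offs[k, 1]
        if r < 0 or r >= H or c < 0 or c >= W:
            l = 0
        else:
            l = labels[r, c]
        if l == a:
            n_a += 1
        if l == b:
            n_b += 1
        if l != a and cstate[a] != 1 and cstate[l] != 1:
            dJ -= J[ctype[a], ctype[l]]
        if l != b and cstate[b] != 1 and cstate[l] != 1:
            dJ += J[ctype[b], ctype[l]]
    dH = dJ
    if a > 0 and cstate[a] == 0:
        Va = volume[a]
        Sa = interface[a]
        dSa = n_a - (nh - n_a)
        dv = Va - target_volume[a]
        ds = Sa - target_surface[a]
        dH -= lambda_V[ctype[a]] * dv * dv + lambda_S[ctype[a]] * ds * ds
        if Va - 1 > 0:
            dv = (Va - 1) - target_volume[a]
            ds = (Sa + dSa) - target_surface[a]
            dH += lambda_V[ctype[a]] * dv * dv + lambda_S[ctype[a]] * ds * ds
    if b > 0 and cstate[b] == 0:
        Vb = volume[b]
        Sb = interface[b]
        dSb = (nh - n_b) - n_b
        dv = Vb - target_volume[b]
        ds = Sb - target_surface[b]
        dH -= lambda_V[ctype[b]] * dv * dv + lambda_S[ctype[b]] * ds * ds
        dv = (Vb + 1) - target_volume[b]
        ds = (Sb + dSb) - target_surface[b]
        dH += lambda_V[ctype[b]] * dv * dv + lambda_S[ctype[b]] * ds * ds
    return dH


@njit(**_JIT)
def apply_flip(labels, cstate, volume, interface, crow_sum, ccol_sum,
               offs, i, j, b):
    """Relabel site (i,j) to b and update both cells' cached statistics.

    Interfaces of third cells are unaffected: a pair (focal, neighbor) stays
    heterologous with respect to any cell that is neither the old nor the new
    label.
    """
    H, W = labels.shape
    a = labels[i, j]
    nh = offs.shape[0]
    n_a = 0
    n_b = 0
    for k in range(nh):
        r = i + offs[k, 0]
        c = j + offs[k, 1]
        if r < 0 or r >= H or c < 0 or c >= W:
            l = 0
        else:
            l = labels[r, c]
        if l == a:
            n_a += 1
        if l == b:
            n_b += 1
    labels[i, j] = b
    if a > 0:
        volume[a] -= 1
        interface[a] += n_a - (nh - n_a)
        crow_sum[a] -= i
        ccol_sum[a] -= j
        if volume[a] == 0:
            cstate[a] = 2  # removed
            interface[a] = 0
    if b > 0:
        volume[b] += 1
        interface[b] += (nh - n_b) - n_b
        crow_sum[b] += i
        ccol_sum[b] += j


@njit(**_JIT)
def attempt_site(labels, ctype, cstate, volume, interface, target_volume,
                 target_surface, crow_sum, ccol_sum, pref_row, pref_col,
                 J, lambda_V, lambda_S, offs, temperature, beta,
                 i, j, nbr_idx, u):
    """One Metropolis copy attempt at focal site (i, j).

    The neighbor at ``offs[nbr_idx]`` is the copy source: on acceptance the
    focal site adopts its label (the neighbor invades).  Returns 1 on
    acceptance (including same-label no-ops), 0 on rejection.  ``beta`` > 0
    lowers delta-H for attempts that extend the source cell along its
    per-cell preferred direction (anisotropic growth).
    """
    H, W = labels.shape
    a = labels[i, j]
    r = i + offs[nbr_idx, 0]
    c = j + offs[nbr_idx, 1]
    if r < 0 or r >= H or c < 0 or c >= W:
        b = 0
    else:
        b = labels[r, c]
    if b == a:
        return 1  # no-op: delta-H is zero, nothing changes
    if cstate[a] == 1 or cstate[b] == 1:
        return 0  # necrotic cells are frozen in place
    dH = delta_h(labels, ctype, cstate, volume, interface, target_volume,
                 target_surface, J, lambda_V, lambda_S, offs, i, j, b)
    if beta > 0.0 and b > 0:
        vb = volume[b]
        disp_r = i - crow_sum[b] / vb
        disp_c = j - ccol_sum[b] / vb
        if disp_r * pref_row[b] + disp_c * pref_col[b] > 0.0:
            dH -= beta
    if dH <= 0.0:
        p = 1.0
    else:
        p = np.exp(-dH / temperature)
    if u < p:
        apply_flip(labels, cstate, volume, interface, crow_sum, ccol_sum,
                   offs, i, j, b)
        return 1
    return 0


@njit(**_JIT)
def run_attempts(labels, ctype, cstate, volume, interface, target_volume,
                 target_surface, crow_sum, ccol_sum, pref_row, pref_col,
                 J, lambda_V, lambda_S, offs, temperature, beta,
                 sites, nbr_idx, us):
    """Process a sequence of copy attempts at flat site indices ``sites``.

    Used both for full serial sweeps (``sites`` = a permutation of all sites)
    and for the claimed batches of the parallel engines.  Returns the number
    of accepted attempts.
    """
    W = labels.shape[1]
    accepted = 0
    for t in range(sites.shape[0]):
        s = sites[t]
        i = s // W
        j = s % W
        accepted += attempt_site(
            labels, ctype, cstate, volume, interface, target_volume,
            target_surface, crow_sum, ccol_sum, pref_row, pref_col,
            J, lambda_V, lambda_S, offs, temperature, beta,
            i, j, nbr_idx[t], us[t])
    return accepted
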