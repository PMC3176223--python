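"""Numba kernels for the Monte Carlo sweep.

Randomness is pre-drawn by the caller (one flat array each of change-site
indices, neighbour choices and acceptance uniforms per sweep) so that the
kernel is deterministic given its inputs and exactly reproducible by the
pure-Python reference implementation in :mod:`vasculogen.cpm`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["NEIGHBOR_OFFSETS", "mcs_kernel"]

#: neighbourhood offsets by order: 1 = von Neumann (4), 2 = Moore (8)
NEIGHBOR_OFFSETS = {
    1: np.array([(-1, 0), (0, -1), (0, 1), (1, 0)], dtype=np.int64),
    2: np.array(
        [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
        dtype=np.int64,
    ),
}


@njit(cache=True)
def _pair_energy(a, b, J_cc, J_cm):
    if a == b:
        return 0.0
    if a == 0 or b == 0:
        return J_cm
    return J_cc


@njit(cache=True)
def delta_h_site(
    sigma, areas, s, b, ty, tx, sy, sx, offsets,
    J_cc, J_cm, lam, A_target, mu_b, mu_s,
):
    """Energy change for copying the state at (sy,sx) into (ty,tx).

    Local adhesion/area terms plus the chemotactic bias
    ``-mu_b*(b[t]-b[src]) - mu_s*(s[t]-s[src])``.  Sites outside the lattice
    count as medium for the boundary energy.
    """
    ls = sigma.shape[0]
    si = sigma[sy, sx]
    ti = sigma[ty, tx]
    d_adh = 0.0
    for k in range(offsets.shape[0]):
        ny = ty + offsets[k, 0]
        nx = tx + offsets[k, 1]
        if 0 <= ny < ls and 0 <= nx < ls:
            nn = sigma[ny, nx]
        else:
            nn = 0  # outside the lattice counts as medium
        d_adh += _pair_energy(si, nn, J_cc, J_cm) - _pair_energy(ti, nn, J_cc, J_cm)
    d_area = 0.0
    if ti > 0:
        a = float(areas[ti])
        d_area += lam * ((a - 1.0 - A_target) ** 2 - (a - A_target) ** 2)
    if si > 0:
        a = float(areas[si])
        d_area += lam * ((a + 1.0 - A_target) ** 2 - (a - A_target) ** 2)
    d_chem = -mu_b * (b[ty, tx] - b[sy, sx]) - mu_s * (s[ty, tx] - s[sy, sx])
    return d_adh + d_area + d_chem


@njit(cache=True)
def mcs_kernel(
    sigma, areas, s, b, targets, nbr_choice, uniforms, offsets,
    J_cc, J_cm, lam, A_target, mu_b, mu_s, T,
):
    """One Monte Carlo sweep (len(targets) copy attempts), in place.

    Returns the number of accepted copies.  A copy that would reduce a cell
    to zero area is rejected outright, keeping the cell count fixed.
    """
    ls = sigma.shape[0]
    accepted = 0
    for k in range(targets.shape[0]):
        t = targets[k]
        ty = t // ls
        tx = t - ty * ls
        sy = ty + offsets[nbr_choice[k], 0]
        sx = tx + offsets[nbr_choice[k], 1]
        if sy < 0 or sy >= ls or sx < 0 or sx >= ls:
            continue  # copies from outside the lattice are never attempted
        si = sigma[sy, sx]
        ti = sigma[ty, tx]
        if si == ti:
            continue
        if ti > 0 and areas[ti] == 1:
            continue  # would annihilate a cell: rejected
        dH = delta_h_site(
            sigma, areas, s, b, ty, tx, sy, sx, offsets,
            J_cc, J_cm, lam, A_target, mu_b, mu_s,
        )
        if dH <= 0.0:
            ok = True
        elif T > 0.0:
            ok = uniforms[k] < np.exp(-dH / T)
        else:
            ok = False
        if ok:
            sigma[ty, tx] = si
            if ti > 0:
                areas[ti] -= 1
            if si > 0:
                areas[si] += 1
            accepted += 1
    return accepted
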