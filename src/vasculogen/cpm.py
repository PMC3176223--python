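"""Cellular Potts dynamics: Hamiltonian, energy changes, Metropolis sweeps.

The Hamiltonian is

    H = sum_{neighbour pairs} J(type_i, type_j) * [sigma_i != sigma_j]
      + lambda_area * sum_{cells} (area - A_target)^2

with boundary energies ``J_cc`` between two different cells and ``J_cm``
between a cell and the medium; sites outside the lattice count as medium.
A copy attempt is biased up-gradient of VEGF by adding
``-mu_b*(b(target)-b(source)) - mu_s*(s(target)-s(source))`` to the local
energy change, where the target is the site being overwritten; the bias acts
on extensions and retractions with the same signed formula, which produces
coherent up-gradient motion.  Attempts are accepted with probability 1 when
they lower the energy and ``exp(-dH/T)`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import NEIGHBOR_OFFSETS, delta_h_site, mcs_kernel
from .params import ModelParams
from .state import FieldState, SimulationState

__all__ = [
    "CopyAttempt",
    "hamiltonian",
    "delta_H",
    "acceptance_probability",
    "monte_carlo_step",
    "draw_sweep_randoms",
]


@dataclass(frozen=True)
class CopyAttempt:
    """A proposed copy of the state at ``source_site`` into ``target_site``.

    ``target_site`` is the randomly chosen site whose state may change;
    ``source_site`` is one of its lattice neighbours, whose index would be
    copied in.  The attempt is a no-op when the indices are equal.
    """

    source_site: tuple[int, int]
    target_site: tuple[int, int]

    def __post_init__(self) -> None:
        dy = abs(self.source_site[0] - self.target_site[0])
        dx = abs(self.source_site[1] - self.target_site[1])
        if (dy, dx) == (0, 0) or max(dy, dx) > 1:
            raise ValueError("source and target must be distinct Moore neighbours")


def _pair_energy(a: int, b: int, params: ModelParams) -> float:
    if a == b:
        return 0.0
    if a == 0 or b == 0:
        return params.J_cm
    return params.J_cc


def hamiltonian(state: SimulationState, params: ModelParams) -> float:
    """Total boundary + area energy of a configuration.

    Each unordered neighbour pair is counted once; pairs between a lattice
    site and a virtual outside site (medium) are included once as well.
    """
    sigma = state.sigma
    ls = sigma.shape[0]
    offsets = NEIGHBOR_OFFSETS[params.neighbor_order]
    padded = np.zeros((ls + 2, ls + 2), dtype=sigma.dtype)
    padded[1:-1, 1:-1] = sigma
    h_adh = 0.0
    for dy, dx in offsets:
        nb = padded[1 + dy : 1 + dy + ls, 1 + dx : 1 + dx + ls]
        diff = sigma != nb
        both_cell = (sigma > 0) & (nb > 0) & diff
        one_medium = diff & ~both_cell
        # neighbour lies outside the lattice: counted once (weight 1), the
        # in-lattice pairs are enumerated twice over the offset loop (weight ½)
        oy = np.arange(ls) + dy
        ox = np.arange(ls) + dx
        outside = ((oy < 0) | (oy >= ls))[:, None] | ((ox < 0) | (ox >= ls))[None, :]
        w = np.where(outside, 1.0, 0.5)
        h_adh += params.J_cc * (both_cell * w).sum() + params.J_cm * (one_medium * w).sum()
    areas = state.areas[1:].astype(float)
    h_area = params.lambda_area * ((areas - params.A_target) ** 2).sum()
    return float(h_adh + h_area)


def delta_H(
    state: SimulationState,
    fields: FieldState,
    attempt: CopyAttempt,
    params: ModelParams,
) -> float:
    """Energy change of a copy attempt (local evaluation).

    Equals ``hamiltonian(after) - hamiltonian(before)`` plus the chemotactic
    bias term, which is not part of the Hamiltonian.
    """
    (sy, sx), (ty, tx) = attempt.source_site, attempt.target_site
    return float(
        delta_h_site(
            state.sigma, state.areas, fields.s, fields.b,
            ty, tx, sy, sx, NEIGHBOR_OFFSETS[params.neighbor_order],
            params.J_cc, params.J_cm, params.lambda_area, params.A_target,
            params.mu_b, params.mu_s,
        )
    )


def acceptance_probability(dH: float, T_fluct: float) -> float:
    """Metropolis acceptance: 1 if ``dH <= 0``, else ``exp(-dH/T)``.

    ``T_fluct = 0`` takes the limit: accept iff ``dH <= 0``.
    """
    if T_fluct < 0:
        raise ValueError("T_fluct must be >= 0")
    if dH <= 0:
        return 1.0
    if T_fluct == 0:
        return 0.0
    return math.exp(-dH / T_fluct)


def draw_sweep_randoms(
    rng: np.random.Generator,
    n_sites: int,
    n_neighbors: int,
    n_attempts: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-draw the randomness of one Monte Carlo sweep.

    Documented draw order: (1) change-site indices, (2) neighbour choices,
    (3) acceptance uniforms — one of each per attempt, the uniform being
    consumed whether or not the attempt reaches the acceptance test.  One MCS
    makes as many attempts as there are lattice sites.
    """
    if n_attempts is None:
        n_attempts = n_sites
    targets = rng.integers(0, n_sites, size=n_attempts, dtype=np.int64)
    nbr = rng.integers(0, n_neighbors, size=n_attempts, dtype=np.int64)
    uniforms = rng.random(n_attempts)
    return targets, nbr, uniforms


def monte_carlo_step(
    state: SimulationState,
    fields: FieldState,
    params: ModelParams,
    rng: np.random.Generator,
    diagnostics: dict | None = None,
) -> SimulationState:
    """One Monte Carlo step: ``lattice_side**2`` copy attempts, in place.

    Each attempt picks a random site and a random neighbour, evaluates the
    local energy change and applies the Metropolis rule; per-cell areas are
    updated incrementally and ``mcs_elapsed`` advances by one.
    """
    ls = params.lattice_side
    offsets = NEIGHBOR_OFFSETS[params.neighbor_order]
    targets, nbr, uniforms = draw_sweep_randoms(rng, ls * ls, len(offsets))
    accepted = mcs_kernel(
        state.sigma, state.areas, fields.s, fields.b,
        targets, nbr, uniforms, offsets,
        params.J_cc, params.J_cm, params.lambda_area, params.A_target,
        params.mu_b, params.mu_s, params.T_fluct,
    )
    state.mcs_elapsed += 1
    if diagnostics is not None:
        diagnostics["attempts"] = ls * ls
        diagnostics["accepted"] = int(accepted)
    return state


def _monte_carlo_step_python(
    state: SimulationState,
    fields: FieldState,
    params: ModelParams,
    targets: np.ndarray,
    nbr: np.ndarray,
    uniforms: np.ndarray,
) -> int:
    """Pure-Python reference sweep over pre-drawn randoms (test oracle)."""
    sigma, areas = state.sigma, state.areas
    s, b = fields.s, fields.b
    ls = sigma.shape[0]
    offsets = NEIGHBOR_OFFSETS[params.neighbor_order]
    accepted = 0
    for k in range(len(targets)):
        ty, tx = divmod(int(targets[k]), ls)
        dy, dx = offsets[nbr[k]]
        sy, sx = ty + int(dy), tx + int(dx)
        if not (0 <= sy < ls and 0 <= sx < ls):
            continue
        si, ti = int(sigma[sy, sx]), int(sigma[ty, tx])
        if si == ti:
            continue
        if ti > 0 and areas[ti] == 1:
            continue
        dH = delta_H(
            state, fields, CopyAttempt((sy, sx), (ty, tx)), params
        )
        if dH <= 0.0:
            ok = True
        elif params.T_fluct > 0.0:
            ok = uniforms[k] < np.exp(-dH / params.T_fluct)
        else:
            ok = False
        if ok:
            sigma[ty, tx] = si
            if ti > 0:
                areas[ti] -= 1
            if si > 0:
                areas[si] += 1
            accepted += 1
    state.mcs_elapsed += 1
    return accepted
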