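"""Reaction-diffusion dynamics of VEGF and ECM binding sites.

The concentration fields obey, per lattice site,

    ds/dt = D * laplacian(s) + alpha_V - k_bind*s*e - gamma_s*s
    de/dt = alpha_E * mask   - k_bind*s*e
    db/dt = k_bind*s*e

where ``mask`` is 1 at cell-occupied sites.  Only soluble VEGF diffuses;
free binding sites and bound VEGF are immobile, and bound VEGF is never
degraded.  Integration is forward Euler with operator splitting (reaction
then diffusion in each substep) and zero-flux (reflecting) boundaries, which
conserve diffusing mass exactly.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .params import ModelParams
from .state import BinaryPattern, FieldState

__all__ = ["reaction_step", "diffusion_step", "well_mix", "integrate_fields"]

log = logging.getLogger(__name__)

#: dt * k_bind * max(concentration) above which the explicit mass-action
#: update may drive a field negative
_POSITIVITY_LIMIT = 1.0
#: target headroom used when auto-substepping inside integrate_fields
_POSITIVITY_TARGET = 0.5


def _binding_number(fields: FieldState, params: ModelParams, dt: float) -> float:
    m = max(float(fields.e.max(initial=0.0)), float(fields.s.max(initial=0.0)))
    return dt * params.k_bind * m


def reaction_step(
    fields: FieldState,
    mask: BinaryPattern | np.ndarray,
    params: ModelParams,
    dt: float,
) -> FieldState:
    """One forward-Euler reaction update (in place; the fields are returned).

    Raises ``ValueError`` when the positivity heuristic
    ``dt*k_bind*max(e or s) >= 1`` indicates the explicit update could
    overshoot below zero; negative excursions that still occur are clipped to
    zero with a logged warning.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if _binding_number(fields, params, dt) >= _POSITIVITY_LIMIT:
        needed = int(np.ceil(_binding_number(fields, params, dt) / _POSITIVITY_TARGET))
        raise ValueError(
            f"dt*k_bind*max(e,s) = {_binding_number(fields, params, dt):.3g} >= 1; "
            f"split this step into at least {needed} substeps"
        )
    m = mask.grid if isinstance(mask, BinaryPattern) else np.asarray(mask)
    s, e, b = fields.s, fields.e, fields.b
    r = params.k_bind * s * e
    s += dt * (params.alpha_V - r - params.gamma_s * s)
    e += dt * (params.alpha_E * m - r)
    b += dt * r
    for name, arr in (("s", s), ("e", e)):
        neg = arr < 0
        if neg.any():
            log.warning(
                "reaction_step: clipped %d negative %s values (min %.3g)",
                int(neg.sum()), name, float(arr.min()),
            )
            arr[neg] = 0.0
    return fields


def diffusion_step(
    s_grid: np.ndarray, params: ModelParams, dt: float
) -> np.ndarray:
    """One forward-Euler diffusion update of the soluble field (in place).

    5-point Laplacian with zero-flux (reflecting) boundaries; conserves total
    mass.  Raises ``ValueError`` when ``dt`` violates the explicit stability
    bound ``dt <= pixel_size**2 / (4 D)``.
    """
    if params.D == 0 or dt == 0:
        return s_grid
    if dt > params.stable_dt * (1 + 1e-12):
        needed = int(np.ceil(dt / params.stable_dt))
        raise ValueError(
            f"diffusion dt = {dt:g} s exceeds stability bound "
            f"{params.stable_dt:g} s; split into at least {needed} substeps"
        )
    lap = ndimage.laplace(s_grid, mode="nearest")
    s_grid += params.D_lattice * dt * lap
    return s_grid


def well_mix(s_grid: np.ndarray) -> np.ndarray:
    """Redistribute the field homogeneously (in place), preserving total mass."""
    s_grid[...] = s_grid.mean()
    return s_grid


def integrate_fields(
    fields: FieldState,
    mask: BinaryPattern | np.ndarray,
    params: ModelParams,
    duration: float | None = None,
    mode: str = "normal",
) -> FieldState:
    """Integrate the field equations over ``duration`` seconds (one MCS).

    ``mode`` selects the diffusion treatment used in the robustness analysis:
    ``'normal'`` alternates reaction and diffusion substeps, ``'no_diffusion'``
    performs reaction only, and ``'well_mixed'`` redistributes the total
    soluble VEGF homogeneously after every reaction substep.

    The configured ``pde_substeps`` is raised automatically when either the
    diffusion stability bound or the binding positivity heuristic requires a
    smaller ``dt`` (e.g. when free binding sites accumulate under strong ECM
    overproduction).
    """
    if mode not in ("normal", "no_diffusion", "well_mixed"):
        raise ValueError(f"unknown field mode {mode!r}")
    if duration is None:
        duration = params.mcs_seconds
    n = params.pde_substeps
    if mode == "normal":
        n = max(n, params.min_substeps)
    # binding positivity: dt*k*max(e,s) must stay below the safety target
    bn = _binding_number(fields, params, duration)
    if bn > 0:
        n = max(n, int(np.ceil(bn / _POSITIVITY_TARGET)))
    dt = duration / n
    for _ in range(n):
        reaction_step(fields, mask, params, dt)
        if mode == "normal":
            diffusion_step(fields.s, params, dt)
        elif mode == "well_mixed":
            well_mix(fields.s)
    return fields
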