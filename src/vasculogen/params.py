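"""Model parameters and presets.

All parameters of the coupled cellular-Potts / reaction-diffusion model live
in a single :class:`ModelParams` record.  Physical units are µm and seconds at
the configuration surface; the PDE solver works in lattice units internally
(``pixel_size`` µm per lattice site, ``mcs_seconds`` seconds per Monte Carlo
step).

Concentrations of soluble VEGF (s), free ECM binding sites (e) and
matrix-bound VEGF (b) are in arbitrary units (a.u.); only ratios of the
chemotaxis strengths times concentration differences against the fluctuation
energy ``T_fluct`` are meaningful.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

__all__ = ["ModelParams", "load_preset", "available_presets"]

_REL_TOL = 1e-9


@dataclass
class ModelParams:
    """Parameters of the hybrid vasculogenesis model.

    Attributes
    ----------
    D:
        VEGF diffusion coefficient, µm²/s.  Only soluble VEGF diffuses.
    alpha_V:
        Soluble VEGF production rate (a.u./s), applied uniformly over the
        whole domain (paracrine source from the adjacent endoderm, projected
        onto the 2D plane).
    alpha_E:
        Production rate of ECM molecules with free VEGF-binding domains
        (a.u./s), applied only at cell-occupied lattice sites.
    k_bind:
        Effective second-order binding rate of soluble VEGF to free ECM
        binding sites, 1/(a.u.·s).
    gamma_s:
        First-order degradation rate of soluble VEGF, 1/s.  Bound VEGF is
        never degraded (heparan-sulphate binding protects the growth factor).
    T_fluct:
        Fluctuation energy (membrane-fluctuation analogue of temperature);
        a proxy for cell motility.
    A_target:
        Cell target area, lattice sites.
    lambda_area:
        Area-constraint stiffness, energy per squared pixel of deviation.
    J_cc, J_cm:
        Boundary binding energy per lattice interface for cell-cell and
        cell-medium contacts.  ``J_cm > J_cc / 2`` gives a positive
        cell-medium surface tension ``J_cm - J_cc/2`` so that cell-cell
        contacts, once formed, are energetically preferred.
    mu_total:
        Total chemotaxis strength (energy per unit concentration difference).
    mu_b, mu_s:
        Chemotaxis strengths toward bound and soluble VEGF;
        ``mu_b + mu_s == mu_total``.  Constructed from ``bound_fraction`` if
        left unset.
    bound_fraction:
        Convenience knob: ``mu_b = bound_fraction * mu_total``.
    neighbor_order:
        Neighbourhood order for boundary-energy summation and copy attempts
        (1 = von Neumann, 2 = Moore).
    lattice_side:
        Side length of the square lattice, pixels.
    pixel_size:
        Physical side length of one lattice site, µm.
    mcs_seconds:
        Physical seconds represented by one Monte Carlo step.
    pde_substeps:
        Number of PDE integration substeps per MCS.
    seed:
        RNG seed for the simulation.
    """

    # --- PDE ---
    D: float = 10.0
    alpha_V: float = 0.003
    alpha_E: float = 0.003
    k_bind: float = 0.5
    gamma_s: float = 0.001
    # --- CPM ---
    T_fluct: float = 40.0
    A_target: float = 100.0
    lambda_area: float = 50.0
    J_cc: float = 40.0
    J_cm: float = 30.0
    mu_total: float = 350.0
    mu_b: float | None = None
    mu_s: float | None = None
    bound_fraction: float = 0.8
    neighbor_order: int = 2
    # --- lattice / scheduling ---
    lattice_side: int = 400
    pixel_size: float = 2.0
    mcs_seconds: float = 1.0
    pde_substeps: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_b is None and self.mu_s is None:
            self.mu_b = self.bound_fraction * self.mu_total
            self.mu_s = self.mu_total - self.mu_b
        elif self.mu_b is None:
            self.mu_b = self.mu_total - self.mu_s
        elif self.mu_s is None:
            self.mu_s = self.mu_total - self.mu_b
        self.bound_fraction = (
            self.mu_b / self.mu_total if self.mu_total else self.bound_fraction
        )
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check invariants; raise ``ValueError`` naming the offending key."""
        nonneg = (
            "D", "alpha_V", "alpha_E", "k_bind", "gamma_s", "T_fluct",
            "A_target", "lambda_area", "mu_total", "pixel_size",
            "mcs_seconds",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.lattice_side < 8:
            raise ValueError(f"lattice_side must be >= 8, got {self.lattice_side}")
        if self.pde_substeps < 1:
            raise ValueError("pde_substeps must be >= 1")
        if self.neighbor_order not in (1, 2):
            raise ValueError("neighbor_order must be 1 (von Neumann) or 2 (Moore)")
        tot = self.mu_b + self.mu_s
        if not math.isclose(tot, self.mu_total, rel_tol=_REL_TOL, abs_tol=1e-9):
            raise ValueError(
                f"mu_b + mu_s = {tot} must equal mu_total = {self.mu_total}"
            )
        if self.D > 0 and self.dt > self.stable_dt * (1 + _REL_TOL):
            raise ValueError(
                f"pde_substeps: dt = {self.dt:g} s violates the explicit "
                f"diffusion stability bound {self.stable_dt:g} s; use at least "
                f"{self.min_substeps} substeps"
            )

    # ------------------------------------------------------------------
    @property
    def D_lattice(self) -> float:
        """Diffusion coefficient in px²/s."""
        return self.D / self.pixel_size**2

    @property
    def dt(self) -> float:
        """PDE substep length in seconds."""
        return self.mcs_seconds / self.pde_substeps

    @property
    def stable_dt(self) -> float:
        """Explicit-diffusion stability bound dt <= h²/(4D)."""
        if self.D == 0:
            return math.inf
        return self.pixel_size**2 / (4.0 * self.D)

    @property
    def min_substeps(self) -> int:
        if self.D == 0:
            return 1
        return max(1, math.ceil(self.mcs_seconds / self.stable_dt))

    @property
    def isotropic_diameter(self) -> float:
        """Diameter (px) of an isotropic cell of the target area."""
        return 2.0 * math.sqrt(self.A_target / math.pi)

    # ------------------------------------------------------------------
    def replace(self, **kwargs: Any) -> "ModelParams":
        """Return a copy with fields replaced (re-validated)."""
        if ("mu_total" in kwargs or "bound_fraction" in kwargs) and not (
            "mu_b" in kwargs or "mu_s" in kwargs
        ):
            # re-derive the split from the (possibly new) total and fraction
            kwargs.setdefault("mu_b", None)
            kwargs.setdefault("mu_s", None)
        return dataclasses.replace(self, **kwargs)

    def with_chemotaxis_ratio(self, bound_fraction: float) -> "ModelParams":
        """Split ``mu_total`` as ``mu_b = f*mu_total``, ``mu_s = (1-f)*mu_total``."""
        if not 0.0 <= bound_fraction <= 1.0:
            raise ValueError("bound_fraction must lie in [0, 1]")
        return dataclasses.replace(
            self,
            mu_b=bound_fraction * self.mu_total,
            mu_s=(1.0 - bound_fraction) * self.mu_total,
            bound_fraction=bound_fraction,
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ----------------------------------------------------------------------
def _preset_dir():
    return resources.files("vasculogen") / "presets"


def available_presets() -> list[str]:
    return sorted(p.name[:-5] for p in _preset_dir().iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> tuple[ModelParams, dict[str, Any]]:
    """Load a named scenario preset.

    Returns ``(params, scenario)`` where ``scenario`` holds the non-parameter
    run settings (``n_cells``, ``init_mode``, ``total_mcs``, ...).
    """
    path = _preset_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ValueError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    doc = yaml.safe_load(text)
    params = ModelParams.from_dict(doc.get("params", {}))
    scenario = doc.get("scenario", {})
    return params, scenario
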