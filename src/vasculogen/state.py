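"""Simulation state: cell lattice, concentration fields, binary patterns.

The cellular Potts configuration is an integer lattice ``sigma`` where 0
labels the medium and 1..N label the N angioblasts.  Per-cell areas are kept
incrementally in ``areas`` (index 0 is unused) and can always be re-derived
from ``sigma`` with :meth:`SimulationState.recount_areas`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "BinaryPattern",
    "FieldState",
    "SimulationState",
    "initialize_cells",
    "cell_mask",
]


@dataclass
class BinaryPattern:
    """A 2D binary mask (1 = vascular, 0 = avascular) with a pixel size in µm."""

    grid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryPattern grid must contain only 0 and 1")
        if g.ndim != 2:
            raise ValueError("BinaryPattern grid must be 2D")
        self.grid = g.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class FieldState:
    """Co-registered scalar grids: soluble VEGF ``s``, free ECM binding sites
    ``e`` and matrix-bound VEGF ``b``."""

    s: np.ndarray
    e: np.ndarray
    b: np.ndarray

    @classmethod
    def zeros(cls, lattice_side: int) -> "FieldState":
        shape = (lattice_side, lattice_side)
        return cls(
            s=np.zeros(shape), e=np.zeros(shape), b=np.zeros(shape)
        )

    def copy(self) -> "FieldState":
        return FieldState(self.s.copy(), self.e.copy(), self.b.copy())

    def totals(self) -> dict[str, float]:
        return {"s": float(self.s.sum()), "e": float(self.e.sum()),
                "b": float(self.b.sum())}


@dataclass
class SimulationState:
    """Cellular Potts configuration plus per-cell bookkeeping."""

    sigma: np.ndarray
    areas: np.ndarray  # int64, length n_cells + 1; index 0 (medium) unused
    mcs_elapsed: int = 0
    pixel_size: float = 1.0

    @property
    def n_cells(self) -> int:
        return len(self.areas) - 1

    @property
    def cells(self) -> pd.DataFrame:
        """Per-cell table (index, type, current area in pixels)."""
        idx = np.arange(1, self.n_cells + 1)
        return pd.DataFrame(
            {"type": "angioblast", "current_area": self.areas[1:]},
            index=pd.Index(idx, name="cell"),
        )

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.sigma.copy(), self.areas.copy(), self.mcs_elapsed,
            self.pixel_size,
        )

    def recount_areas(self) -> np.ndarray:
        """From-scratch recount of per-cell areas (bookkeeping oracle)."""
        return np.bincount(self.sigma.ravel(), minlength=self.n_cells + 1).astype(
            np.int64
        )

    def check_consistency(self) -> None:
        recount = self.recount_areas()
        # index 0 (medium) is not tracked incrementally
        if not np.array_equal(recount[1:], self.areas[1:]):
            raise AssertionError("per-cell area bookkeeping is out of sync")
        present = np.unique(self.sigma)
        if present.size and present.max() > self.n_cells:
            raise AssertionError("sigma contains an index with no cell record")


def cell_mask(state: SimulationState) -> BinaryPattern:
    """Binary mask of cell-occupied sites (1 where ``sigma > 0``)."""
    return BinaryPattern((state.sigma > 0).astype(np.uint8), state.pixel_size)


# ----------------------------------------------------------------------
class OvercrowdingError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


def _patch_side(A_target: float) -> int:
    """Side of the square seed patch whose area is nearest to A_target."""
    return max(1, round(math.sqrt(A_target)))


def initialize_cells(
    n_cells: int,
    mode: str,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> SimulationState:
    """Seed ``n_cells`` compact square cells on the lattice.

    ``mode='regular'`` places cell centres on a uniform grid; ``'semi_random'``
    additionally displaces each centre by an integer offset drawn uniformly
    with magnitude smaller than one isotropic cell diameter
    ``2*sqrt(A_target/pi)``.  Patches are clipped at the lattice edge and must
    be pairwise disjoint; colliding semi-random placements are re-drawn up to
    ``max_retries`` times before failing.
    """
    if mode not in ("regular", "semi_random"):
        raise ValueError(f"unknown init mode {mode!r}")
    ls = params.lattice_side
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells * params.A_target > ls * ls:
        raise OvercrowdingError(
            f"{n_cells} cells of target area {params.A_target} exceed the "
            f"{ls}x{ls} lattice"
        )
    sigma = np.zeros((ls, ls), dtype=np.int32)
    areas = np.zeros(n_cells + 1, dtype=np.int64)
    state = SimulationState(sigma, areas, 0, params.pixel_size)
    if n_cells == 0:
        return state
    if rng is None:
        rng = np.random.default_rng(params.seed)

    side = _patch_side(params.A_target)
    half = side // 2
    # uniform grid of centres
    n_rows = math.ceil(math.sqrt(n_cells))
    n_cols = math.ceil(n_cells / n_rows)
    ys = (np.arange(n_rows) + 0.5) * ls / n_rows
    xs = (np.arange(n_cols) + 0.5) * ls / n_cols
    centres = [
        (int(ys[i]), int(xs[j]))
        for i in range(n_rows)
        for j in range(n_cols)
    ][:n_cells]

    d_max = params.isotropic_diameter  # displacement magnitude bound
    occupied = np.zeros((ls, ls), dtype=bool)

    def patch_slices(cy: int, cx: int) -> tuple[slice, slice]:
        y0, x0 = max(0, cy - half), max(0, cx - half)
        y1, x1 = min(ls, cy - half + side), min(ls, cx - half + side)
        return slice(y0, y1), slice(x0, x1)

    for idx, (gy, gx) in enumerate(centres, start=1):
        for attempt in range(max_retries + 1):
            if mode == "regular":
                cy, cx = gy, gx
            else:
                while True:
                    dy = int(rng.integers(-math.floor(d_max), math.floor(d_max) + 1))
                    dx = int(rng.integers(-math.floor(d_max), math.floor(d_max) + 1))
                    if math.hypot(dy, dx) < d_max:
                        break
                cy, cx = gy + dy, gx + dx
            sy, sx = patch_slices(cy, cx)
            if (sy.stop - sy.start) <= 0 or (sx.stop - sx.start) <= 0:
                continue  # fully off-lattice; redraw
            if not occupied[sy, sx].any():
                sigma[sy, sx] = idx
                occupied[sy, sx] = True
                areas[idx] = (sy.stop - sy.start) * (sx.stop - sx.start)
                break
            if mode == "regular":
                raise OvercrowdingError(
                    f"regular placement of cell {idx} at ({gy},{gx}) overlaps "
                    f"an earlier cell; lower n_cells or A_target"
                )
        else:
            raise OvercrowdingError(
                f"could not place cell {idx} after {max_retries} semi-random "
                f"displacement re-draws; lower n_cells or A_target"
            )
    return state
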