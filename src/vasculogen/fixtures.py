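"""Binary test patterns of known topology and geometry.

Every generator returns a :class:`~vasculogen.state.BinaryPattern` together
with (or derivable from) construction-time ground truth, so the morphometric
operations can be validated without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .state import BinaryPattern

__all__ = ["grid_network", "primitive", "random_mask", "GridTruth"]


@dataclass(frozen=True)
class GridTruth:
    """Construction ground truth of a grid network fixture."""

    n_components: int
    n_lacunae: int
    coverage: float
    percolative: bool
    n_nodes: int
    strut_half_width: float


def grid_network(
    holes_per_side: int,
    hole_size: int = 8,
    strut_width: int = 3,
    margin: int = 0,
) -> tuple[BinaryPattern, GridTruth]:
    """Rectangular lattice of struts enclosing ``holes_per_side**2`` holes.

    By construction β0 = 1, β1 = holes_per_side², and the pattern is
    percolative when ``margin == 0``.  Junction nodes after merging are the
    T- and +-crossings: ``(holes_per_side+1)**2 - 4`` (the four outer corners
    are degree-2 bends, not branch points).
    """
    m = holes_per_side
    if m < 1 or hole_size < 1 or strut_width < 1 or margin < 0:
        raise ValueError("grid geometry must be positive")
    core = m * hole_size + (m + 1) * strut_width
    side = core + 2 * margin
    g = np.zeros((side, side), dtype=np.uint8)
    g[margin : margin + core, margin : margin + core] = 1
    pitch = hole_size + strut_width
    for i in range(m):
        for j in range(m):
            y0 = margin + strut_width + i * pitch
            x0 = margin + strut_width + j * pitch
            g[y0 : y0 + hole_size, x0 : x0 + hole_size] = 0
    cov = 1.0 - (m * m * hole_size**2) / (side * side)
    truth = GridTruth(
        n_components=1,
        n_lacunae=m * m,
        coverage=cov,
        percolative=(margin == 0),
        n_nodes=(m + 1) ** 2 - 4,
        strut_half_width=math.ceil(strut_width / 2),
    )
    return BinaryPattern(g), truth


def primitive(kind: str, size: int = 64, **geom) -> BinaryPattern:
    """Rasterized primitive with analytically known properties.

    Kinds: ``disk`` (radius), ``square`` (side), ``bar`` (length, width),
    ``cross`` (arm, width), ``ring`` (radius, width).  A pixel is foreground
    when its centre satisfies the shape predicate.
    """
    g = np.zeros((size, size), dtype=np.uint8)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    if kind == "disk":
        r = geom.get("radius", size // 4)
        g[(yy - c) ** 2 + (xx - c) ** 2 <= r * r] = 1
    elif kind == "square":
        s = geom.get("side", size // 2)
        y0 = (size - s) // 2
        g[y0 : y0 + s, y0 : y0 + s] = 1
    elif kind == "bar":
        length = geom.get("length", size - 8)
        width = geom.get("width", 3)
        y0 = (size - width) // 2
        x0 = (size - length) // 2
        g[y0 : y0 + width, x0 : x0 + length] = 1
    elif kind == "cross":
        arm = geom.get("arm", size // 2 - 4)
        width = geom.get("width", 1)
        y0 = (size - width) // 2
        x0 = (size - 2 * arm - width) // 2
        span = 2 * arm + width
        g[y0 : y0 + width, x0 : x0 + span] = 1
        g[x0 : x0 + span, y0 : y0 + width] = 1
    elif kind == "ring":
        r = geom.get("radius", size // 3)
        w = geom.get("width", 3)
        d2 = (yy - c) ** 2 + (xx - c) ** 2
        g[(d2 <= r * r) & (d2 >= (r - w) ** 2)] = 1
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")
    return BinaryPattern(g)


def random_mask(
    density: float,
    smoothing: float = 2.0,
    rng: np.random.Generator | None = None,
    size: int = 200,
) -> BinaryPattern:
    """Thresholded smoothed noise with realized coverage ≈ ``density``.

    Gaussian-filtered white noise thresholded at the (1-density) quantile, a
    generic correlated random pattern for oracle-equivalence property tests.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    if density == 0.0:
        return BinaryPattern(np.zeros((size, size), dtype=np.uint8))
    if density == 1.0:
        return BinaryPattern(np.ones((size, size), dtype=np.uint8))
    noise = rng.standard_normal((size, size))
    if smoothing > 0:
        noise = ndimage.gaussian_filter(noise, smoothing)
    thr = np.quantile(noise, 1.0 - density)
    return BinaryPattern((noise > thr).astype(np.uint8))
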