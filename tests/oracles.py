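"""Independent reference implementations used as test oracles.

Deliberately written in the most transparent way possible (explicit loops,
breadth-first search, direct cell-complex counting) so they share no code or
algorithmic shortcuts with the package implementations they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_VON_NEUMANN = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def pair_energy(a: int, b: int, J_cc: float, J_cm: float) -> float:
    if a == b:
        return 0.0
    if a == 0 or b == 0:
        return J_cm
    return J_cc


def hamiltonian_bruteforce(sigma, areas, params) -> float:
    """Direct double-loop Hamiltonian; outside-lattice sites are medium."""
    ls = sigma.shape[0]
    offsets = _VON_NEUMANN if params.neighbor_order == 1 else _MOORE
    h = 0.0
    for y in range(ls):
        for x in range(ls):
            for dy, dx in offsets:
                ny, nx = y + dy, x + dx
                if 0 <= ny < ls and 0 <= nx < ls:
                    # in-lattice unordered pair: count each once
                    if (ny, nx) > (y, x):
                        h += pair_energy(
                            int(sigma[y, x]), int(sigma[ny, nx]),
                            params.J_cc, params.J_cm,
                        )
                else:
                    h += pair_energy(int(sigma[y, x]), 0, params.J_cc, params.J_cm)
    for a in areas[1:]:
        h += params.lambda_area * (float(a) - params.A_target) ** 2
    return h


def flood_fill_count(grid, value: int, connectivity: int) -> int:
    """Number of connected components of ``grid == value`` by BFS."""
    nbrs = _MOORE if connectivity == 8 else _VON_NEUMANN
    h, w = grid.shape
    seen = np.zeros((h, w), dtype=bool)
    count = 0
    for y0 in range(h):
        for x0 in range(w):
            if grid[y0, x0] != value or seen[y0, x0]:
                continue
            count += 1
            q = deque([(y0, x0)])
            seen[y0, x0] = True
            while q:
                y, x = q.popleft()
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if (
                        0 <= ny < h and 0 <= nx < w
                        and grid[ny, nx] == value and not seen[ny, nx]
                    ):
                        seen[ny, nx] = True
                        q.append((ny, nx))
    return count


def betti_flood_fill(grid) -> tuple[int, int]:
    """(β0, β1): 8-connected foreground components and enclosed 4-connected
    background components, by BFS flood fill."""
    b0 = flood_fill_count(grid, 1, 8)
    # background components, then subtract the ones that touch the border
    h, w = grid.shape
    nbrs = _VON_NEUMANN
    seen = np.zeros((h, w), dtype=bool)
    b1 = 0
    for y0 in range(h):
        for x0 in range(w):
            if grid[y0, x0] != 0 or seen[y0, x0]:
                continue
            q = deque([(y0, x0)])
            seen[y0, x0] = True
            touches = y0 in (0, h - 1) or x0 in (0, w - 1)
            while q:
                y, x = q.popleft()
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w:
                        if grid[ny, nx] == 0 and not seen[ny, nx]:
                            seen[ny, nx] = True
                            if ny in (0, h - 1) or nx in (0, w - 1):
                                touches = True
                            q.append((ny, nx))
            if not touches:
                b1 += 1
    return b0, b1


def euler_characteristic(grid) -> int:
    """χ = V − E + F of the union of closed unit squares over the foreground.

    For that union, components are exactly the 8-connected foreground
    components (diagonally touching squares share a corner vertex) and holes
    are the enclosed 4-connected background components, so χ = β0 − β1.
    """
    ys, xs = np.nonzero(np.asarray(grid))
    F = len(ys)
    vertices = set()
    edges = set()
    for y, x in zip(ys.tolist(), xs.tolist()):
        corners = [(y, x), (y, x + 1), (y + 1, x), (y + 1, x + 1)]
        vertices.update(corners)
        edges.add(frozenset([(y, x), (y, x + 1)]))
        edges.add(frozenset([(y + 1, x), (y + 1, x + 1)]))
        edges.add(frozenset([(y, x), (y + 1, x)]))
        edges.add(frozenset([(y, x + 1), (y + 1, x + 1)]))
    return len(vertices) - len(edges) + F
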