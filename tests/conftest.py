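from __future__ import annotations

import numpy as np
import pytest

from vasculogen import ModelParams


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_params() -> ModelParams:
    """Default model on a small lattice, fast enough for unit tests."""
    return ModelParams(lattice_side=40)


def random_state(params, n_cells: int, rng: np.random.Generator):
    """A random (not necessarily connected-cell) CPM configuration."""
    from vasculogen.state import SimulationState

    ls = params.lattice_side
    sigma = rng.integers(0, n_cells + 1, size=(ls, ls)).astype(np.int32)
    areas = np.bincount(sigma.ravel(), minlength=n_cells + 1).astype(np.int64)
    # guarantee every cell exists (area >= 1)
    for c in range(1, n_cells + 1):
        if areas[c] == 0:
            y, x = rng.integers(0, ls, size=2)
            old = int(sigma[y, x])
            sigma[y, x] = c
            areas[old] -= 1
            areas[c] += 1
    return SimulationState(sigma, areas, 0, params.pixel_size)
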