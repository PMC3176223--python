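"""Coupled CPM/PDE simulation driver and in-silico experiment suites.

Each Monte Carlo step (1 s of simulated time) performs one Metropolis sweep
of the cellular Potts model followed by integration of the VEGF/ECM fields
over the same interval using the current cell mask as the ECM production
domain.  On top of the single-run driver sit the experiment suites:
replicate runs, parameter sensitivity, diffusivity robustness, chemotaxis
ratio and cell-density sweeps, and time-resolved network dynamics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import morphometrics as mm
from .cpm import monte_carlo_step
from .fields import integrate_fields
from .params import ModelParams
from .state import BinaryPattern, FieldState, SimulationState, cell_mask, initialize_cells

__all__ = [
    "Snapshot",
    "Trajectory",
    "run_simulation",
    "run_repetitions",
    "RepetitionResult",
    "sweep_sensitivity",
    "sweep_diffusivity",
    "sweep_chemotaxis_ratio",
    "sweep_density",
    "track_dynamics",
    "occupancy_map",
    "time_to_closure",
    "density_per_mm2",
]

log = logging.getLogger(__name__)


@dataclass
class Snapshot:
    mcs: int
    state: SimulationState
    fields: FieldState | None = None


@dataclass
class Trajectory:
    """Stored snapshots of one simulation run."""

    params: ModelParams
    field_mode: str
    seed: int
    snapshots: list[Snapshot] = field(default_factory=list)
    diagnostics: pd.DataFrame | None = None

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]

    def final_mask(self) -> BinaryPattern:
        return cell_mask(self.final.state)


def density_per_mm2(n_cells: int, params: ModelParams) -> float:
    """Cell density in cells/mm² for the configured tissue size."""
    side_mm = params.lattice_side * params.pixel_size / 1000.0
    return n_cells / side_mm**2


def cells_for_density(density_mm2: float, params: ModelParams) -> int:
    side_mm = params.lattice_side * params.pixel_size / 1000.0
    return round(density_mm2 * side_mm**2)


# ----------------------------------------------------------------------
def run_simulation(
    params: ModelParams,
    n_cells: int,
    init_mode: str = "regular",
    total_mcs: int = 3000,
    field_mode: str = "normal",
    snapshot_stride: int | None = None,
    store_fields: bool = False,
    seed: int | None = None,
    collect_diagnostics: bool = False,
) -> Trajectory:
    """Run the coupled model and return a trajectory of snapshots.

    Fully reproducible from the seed: the same seed yields bitwise-identical
    cell lattices.  Snapshots are stored at MCS 0, every ``snapshot_stride``
    steps (default: only first and last) and at the final step.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    state = initialize_cells(n_cells, init_mode, params, rng)
    fields = FieldState.zeros(params.lattice_side)
    traj = Trajectory(params=params, field_mode=field_mode, seed=seed)

    def snap(mcs: int) -> None:
        traj.snapshots.append(
            Snapshot(mcs, state.copy(), fields.copy() if store_fields else None)
        )

    snap(0)
    diag_rows = []
    diag: dict | None = {} if collect_diagnostics else None
    for mcs in range(1, total_mcs + 1):
        monte_carlo_step(state, fields, params, rng, diagnostics=diag)
        integrate_fields(fields, cell_mask(state), params, params.mcs_seconds,
                         mode=field_mode)
        if diag is not None:
            diag_rows.append(
                {"mcs": mcs,
                 "acceptance_rate": diag["accepted"] / diag["attempts"],
                 **{f"total_{k}": v for k, v in fields.totals().items()}}
            )
        if snapshot_stride and mcs % snapshot_stride == 0 and mcs != total_mcs:
            snap(mcs)
    if total_mcs > 0:
        snap(total_mcs)
    if diag_rows:
        traj.diagnostics = pd.DataFrame(diag_rows)
    return traj


# ----------------------------------------------------------------------
@dataclass
class RepetitionResult:
    """Replicate morphometrics with mean/SD summary."""

    records: list[mm.MorphometricRecord]
    table: pd.DataFrame  # one summary row per replicate, indexed by seed
    mean: pd.Series
    sd: pd.Series


def _default_seeds(base_seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def run_repetitions(
    params: ModelParams,
    n_cells: int,
    total_mcs: int = 3000,
    n_reps: int = 10,
    seeds: list[int] | None = None,
    init_mode: str = "regular",
    field_mode: str = "normal",
) -> RepetitionResult:
    """Independent replicates with different seeds; final masks analysed."""
    if seeds is None:
        seeds = _default_seeds(params.seed, n_reps)
    records, rows = [], []
    for s in seeds:
        traj = run_simulation(
            params, n_cells, init_mode, total_mcs, field_mode, seed=s
        )
        rec = mm.analyze(traj.final_mask(), traj.final.state, params)
        records.append(rec)
        rows.append(rec.summary())
    table = pd.DataFrame(rows, index=pd.Index(seeds, name="seed"))
    sd = table.std(ddof=1) if len(seeds) > 1 else table.iloc[0] * 0.0
    return RepetitionResult(records, table, table.mean(), sd)


# ----------------------------------------------------------------------
def sweep_sensitivity(
    params: ModelParams,
    n_cells: int,
    total_mcs: int = 3000,
    rates: tuple[str, ...] = ("k_bind", "alpha_V", "alpha_E", "gamma_s"),
    factors: tuple[float, ...] = (0.1, 10.0),
    n_reps: int = 3,
    seeds: list[int] | None = None,
    init_mode: str = "regular",
) -> pd.DataFrame:
    """Vary each PDE rate by the given factors; morphometric deltas vs reference.

    All conditions reuse the same replicate seeds, so a factor of 1.0
    reproduces the reference row identically.
    """
    if seeds is None:
        seeds = _default_seeds(params.seed, n_reps)
    rows = []

    def add(label: str, rate: str | None, factor: float, p: ModelParams) -> pd.Series:
        rep = run_repetitions(p, n_cells, total_mcs, seeds=seeds,
                              init_mode=init_mode)
        row = pd.concat([rep.mean.add_suffix("_mean"), rep.sd.add_suffix("_sd")])
        row["condition"], row["rate"], row["factor"] = label, rate, factor
        rows.append(row)
        return rep.mean

    ref_mean = add("reference", None, 1.0, params)
    for rate in rates:
        for f in factors:
            p = params.replace(**{rate: getattr(params, rate) * f})
            add(f"{rate} x{f:g}", rate, f, p)
    df = pd.DataFrame(rows).set_index("condition")
    for col in ref_mean.index:
        df[f"delta_{col}"] = df[f"{col}_mean"] - ref_mean[col]
    return df


def sweep_diffusivity(
    params: ModelParams,
    n_cells: int,
    total_mcs: int = 3000,
    n_reps: int = 3,
    seeds: list[int] | None = None,
    init_mode: str = "regular",
) -> pd.DataFrame:
    """Morphometrics under no-diffusion, normal and well-mixed VEGF transport."""
    if seeds is None:
        seeds = _default_seeds(params.seed, n_reps)
    rows = []
    for mode in ("no_diffusion", "normal", "well_mixed"):
        rep = run_repetitions(params, n_cells, total_mcs, seeds=seeds,
                              init_mode=init_mode, field_mode=mode)
        row = pd.concat([rep.mean.add_suffix("_mean"), rep.sd.add_suffix("_sd")])
        row["mode"] = mode
        row["all_percolative"] = bool((rep.table["percolative"] == 1).all())
        rows.append(row)
    return pd.DataFrame(rows).set_index("mode")


def sweep_chemotaxis_ratio(
    params: ModelParams,
    n_cells: int,
    ratios: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    total_mcs: int = 3000,
    n_reps: int = 3,
    seeds: list[int] | None = None,
    init_mode: str = "regular",
) -> pd.DataFrame:
    """Sweep the bound fraction mu_b/mu_total at fixed total strength."""
    if seeds is None:
        seeds = _default_seeds(params.seed, n_reps)
    rows = []
    for ratio in ratios:
        p = params.with_chemotaxis_ratio(ratio)
        assert math.isclose(p.mu_b + p.mu_s, p.mu_total)
        rep = run_repetitions(p, n_cells, total_mcs, seeds=seeds,
                              init_mode=init_mode)
        row = pd.concat([rep.mean.add_suffix("_mean"), rep.sd.add_suffix("_sd")])
        row["ratio"] = ratio
        row["all_percolative"] = bool((rep.table["percolative"] == 1).all())
        rows.append(row)
    return pd.DataFrame(rows).set_index("ratio")


def sweep_density(
    params: ModelParams,
    cell_counts: tuple[int, ...],
    total_mcs: int = 3000,
    n_reps: int = 10,
    seeds: list[int] | None = None,
    init_mode: str = "regular",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Morphometrics vs cell density at fixed tissue size.

    Returns the per-density table plus detected critical points: the lowest
    density with (majority) percolation, estimated as the midpoint between
    the last failing and first passing densities, and the densities
    maximizing the replicate-averaged node and lacunae counts.
    """
    if seeds is None:
        seeds = _default_seeds(params.seed, n_reps)
    rows = []
    for n in sorted(cell_counts):
        rep = run_repetitions(params, n, total_mcs, seeds=seeds,
                              init_mode=init_mode)
        row = pd.concat([rep.mean.add_suffix("_mean"), rep.sd.add_suffix("_sd")])
        row["n_cells"] = n
        row["density_mm2"] = density_per_mm2(n, params)
        row["percolation_fraction"] = float(rep.table["percolative"].mean())
        rows.append(row)
    df = pd.DataFrame(rows).set_index("n_cells")

    dens = df["density_mm2"].to_numpy()
    perc = df["percolation_fraction"].to_numpy() > 0.5
    onset = math.nan
    for i, ok in enumerate(perc):
        if ok:
            onset = dens[i] if i == 0 else 0.5 * (dens[i - 1] + dens[i])
            break
    crit = {
        "percolation_onset_density": onset,
        "node_max_density": float(dens[np.argmax(df["n_nodes_mean"].to_numpy())]),
        "lacunae_max_density": float(dens[np.argmax(df["n_lacunae_mean"].to_numpy())]),
    }
    return df, crit


# ----------------------------------------------------------------------
def track_dynamics(
    trajectory: Trajectory, with_cell_lengths: bool = True
) -> pd.DataFrame:
    """Per-snapshot time series of β0, β1, percolation and cell lengths."""
    rows = []
    for snap in trajectory.snapshots:
        mask = cell_mask(snap.state)
        row: dict = {
            "mcs": snap.mcs,
            "n_components": mm.count_components(mask),
            "n_lacunae": mm.count_lacunae(mask),
            "percolative": mm.is_percolative(mask),
        }
        if with_cell_lengths:
            row["cell_lengths"] = mm.cell_length_distribution(
                snap.state, trajectory.params
            )
        rows.append(row)
    return pd.DataFrame(rows)


def occupancy_map(trajectory: Trajectory, mcs_from: int, mcs_to: int) -> np.ndarray:
    """Mean of binary cell masks over the snapshots in a time window."""
    masks = [
        cell_mask(s.state).grid.astype(float)
        for s in trajectory.snapshots
        if mcs_from <= s.mcs <= mcs_to
    ]
    if not masks:
        raise ValueError("no snapshots in the requested window")
    return np.mean(masks, axis=0)


def time_to_closure(trajectory: Trajectory) -> float:
    """First snapshot time at which the cell pattern is a single 8-connected
    component and percolative (network closure); NaN if never reached."""
    for snap in trajectory.snapshots:
        mask = cell_mask(snap.state)
        if mm.count_components(mask) == 1 and mm.is_percolative(mask):
            return float(snap.mcs)
    return math.nan
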