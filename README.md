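# vasculogen

Hybrid cellular Potts / reaction–diffusion simulation of embryonic
vasculogenesis under matrix-bound paracrine VEGF signalling, with a full
morphometric toolkit and in-silico experiment suites.

## Scientific problem

In the early embryo, dispersed endothelial precursor cells (angioblasts)
coalesce within about an hour into a polygonal primary vascular plexus — a
connected network of cellular cords enclosing avascular lacunae. The VEGF
that guides them is produced *paracrinely* (by an adjacent tissue layer,
roughly uniformly in space), so a classic autocrine chemoattraction
mechanism cannot explain the patterning. The hypothesis implemented here:
cells secrete extracellular-matrix components bearing VEGF-binding sites,
so matrix-bound VEGF accumulates preferentially where cells are or have
been; chemotaxis up gradients of this *bound* VEGF lets cells follow and
reinforce each other's trails, stabilizing contacts and driving network
formation.

## Model

Two coupled layers on one square lattice (default 400×400 px at 2 µm/px,
1 s per Monte Carlo step):

- **Cellular Potts model** (Glazier–Graner–Hogeweg): cells are lattice
  domains evolving by modified-Metropolis copy attempts under adhesion
  energies, an area constraint, membrane fluctuation amplitude `T`, and a
  chemotactic bias `ΔH_chem = −μ_b Δb − μ_s Δs` toward bound (`b`) and
  soluble (`s`) VEGF.
- **Reaction–diffusion fields**: soluble VEGF `s` (diffusing, uniform
  paracrine production, decaying), free ECM binding sites `e` (produced
  under cells), and immobile bound VEGF `b` formed by mass-action binding
  `k·s·e`. Alternative transport modes (`no_diffusion`, `well_mixed`)
  probe robustness to the soluble transport regime.

See [docs/methods.md](docs/methods.md) for equations, numerics, the full
default parameter table, and known limitations.

## Quick start (Python API)

```python
import vasculogen as vg
from vasculogen import morphometrics as mm

params, scenario = vg.load_preset("mini")   # 100x100 lattice, 69 cells
traj = vg.run_simulation(params, scenario["n_cells"], total_mcs=1500,
                         snapshot_stride=100, seed=42)
mask = traj.final_mask()
record = mm.analyze(mask, traj.final.state, params)
for key, val in record.summary().items():
    print(f"{key:22s} {val:8.3f}")
print("closure at MCS:", vg.time_to_closure(traj))
```

Output (exactly reproducible — every run is a pure function of
parameters, scenario and seed):

```
n_components              1.000
n_lacunae                 6.000
mean_lacuna_area        120.333
mean_lacuna_roundness     0.837
coverage                  0.679
percolative               1.000
spanning_length         492.000
mean_cord_width           8.789
n_nodes                  13.000
mean_degree               3.154
interface_length        825.000
fractal_dimension         1.102
lacunarity                3.800
mean_cell_length          1.284
max_cell_length           1.646
closure at MCS: 100.0
```

The 69 cells have fused into a single percolative network (`n_components
1`, `percolative 1`) enclosing 6 lacunae, with 13 branch nodes of mean
degree 3.2 — the polygonal plexus morphology.

## Command line

```bash
vasculogen simulate --preset mini --seed 42 --mcs 600 --out demo
```

writes `final_mask.png`, `final_snapshot.npz` (+ PNG), `morphometrics.json`,
`manifest.json` (config hash, seed, code version, timestamps) and `run.log`
into `demo/`. With the command above, `morphometrics.json` contains i.a.:

```
n_lacunae         9
coverage          0.686
percolative       1.0
n_nodes           17
mean_cell_length  1.3185421070890553
```

Other subcommands: `analyze` (morphometrics of an existing binary mask),
`sweep` (sensitivity / diffusivity / chemotaxis-ratio / density suites),
`dynamics` (time-resolved β0/β1/percolation/cell lengths), `fixtures`
(generate ground-truth test patterns). `vasculogen --help` lists options.

## Experiment suites

`vasculogen.engine` provides replicate statistics (`run_repetitions`) and
the study sweeps: `sweep_sensitivity` (each PDE rate ×0.1 / ×10),
`sweep_diffusivity` (three transport modes), `sweep_chemotaxis_ratio`
(bound fraction μ_b/μ at fixed total μ), `sweep_density` (cell count at
fixed tissue size, with percolation-onset and optimum detection), and
`track_dynamics` / `time_to_closure` for network-formation kinetics.

Scenario presets ship as data files: `reference` (400², 1100 cells),
`dynamics-800` (400², 800 cells), `scaled-ci` (200², 200 cells) and `mini`
(100², 69 cells); the scaled presets preserve cell density.

## Testing

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` checks the headline scientific claims
(closure timescale, elongation statistics, sensitivity directions,
diffusivity robustness, chemotaxis-ratio dependence, density optima,
steady-state stability, and a suite of exact numerical properties) at desk
scale; the remaining files unit-test each module against independent
oracles (brute-force Hamiltonian, ODE integration, flood-fill and
Euler-characteristic topology). Some acceptance checks are currently
expected to fail honestly — with a uniform paracrine source the model has
no long-range attraction between separated cell islands, so a minority of
runs retain small isolated clusters past the closure bound, and at
near-confluent density strong ECM overproduction freezes a fine web
rather than reducing lacunae counts; see docs/methods.md §8.

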