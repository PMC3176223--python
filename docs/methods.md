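# Methods

This document describes the model implemented by `vasculogen`, the numerical
methods used, the default parameter set, and known limitations.

## 1. Biological setting

During early embryonic vasculogenesis, endothelial precursor cells
(angioblasts) dispersed in the mesoderm coalesce into a polygonal primary
vascular plexus. The signalling is *paracrine*: VEGF is produced by an
adjacent tissue layer, roughly uniformly over the area of interest, rather
than by the responding cells themselves. The cells, however, secrete
extracellular-matrix (ECM) components carrying VEGF-binding sites, so
matrix-bound VEGF accumulates preferentially where cells are or have been.
Because cells chemotact most strongly toward this *bound* VEGF, they
effectively follow and reinforce their own trails, which stabilizes
cell-cell contacts and drives coalescence into a reticular network with
enclosed avascular lacunae.

## 2. Model

### 2.1 Cellular Potts model

Cells live on a square lattice of side `lattice_side` (default 400 px at
2 µm/px, i.e. a 0.8 × 0.8 mm tissue patch). Each lattice site carries a cell
index σ ∈ {0 (medium), 1, …, N}; a cell is the set of sites sharing its
index. The Hamiltonian is

    H = Σ_(i,j) J(τ(σ_i), τ(σ_j)) · [σ_i ≠ σ_j]  +  λ Σ_c (a_c − A)²

with boundary energy `J_cc` between two different cells and `J_cm` between a
cell and the medium, summed over unordered neighbour pairs up to second
order (Moore neighbourhood); sites outside the lattice count as medium.
The area term holds every cell's area `a_c` near the target `A`.

Dynamics follow the modified Metropolis scheme: per Monte Carlo step (MCS),
`lattice_side²` copy attempts are made. Each picks a random site and a
random Moore neighbour and proposes copying the neighbour's index onto the
site. The energy change is evaluated locally and augmented by a chemotactic
bias

    ΔH_chem = −μ_b (b(target) − b(source)) − μ_s (s(target) − s(source)),

where `s` and `b` are the soluble and bound VEGF fields, so both extensions
and retractions are biased up-gradient. Attempts are accepted with
probability 1 if ΔH ≤ 0 and `exp(−ΔH/T)` otherwise, with fluctuation
amplitude `T` acting as a motility temperature. Copies that would annihilate
a cell's last pixel are rejected; cell *connectivity is not enforced* (see
§5). One MCS corresponds to 1 s of simulated time.

### 2.2 Reaction–diffusion fields

Three fields live on the same lattice: soluble VEGF `s`, free ECM binding
sites `e`, and matrix-bound VEGF `b`:

    ∂s/∂t = D ∇²s + α_V − k·s·e − γ_s·s
    ∂e/∂t = α_E·1[cell]       − k·s·e
    ∂b/∂t =                     k·s·e

VEGF production `α_V` is spatially uniform (paracrine source); binding-site
production `α_E` occurs only under cells; only `s` diffuses; bound VEGF is
immobile and is not degraded, so `b` is pointwise non-decreasing. Zero-flux
(Neumann) boundaries. Three transport modes are supported: `normal`,
`no_diffusion` (D treated as 0), and `well_mixed` (after each reaction step
the total amount of `s` is redistributed homogeneously).

### 2.3 Coupling

Each MCS performs one Metropolis sweep, then integrates the fields over 1 s
using the current cell mask as the ECM production domain. Fields start at
zero; all spatial structure in `b` is generated by the cells themselves.

## 3. Numerics

- **Diffusion**: explicit forward Euler with the 5-point Laplacian
  (`scipy.ndimage.laplace`, `mode='nearest'` for zero-flux walls). The step
  is split into `pde_substeps` substeps per MCS; construction-time
  validation enforces the stability bound dt ≤ h²/(4D), and the integrator
  additionally raises the substep count automatically when the reaction
  rates are stiff (positivity heuristic dt·k·max(e,s) < 0.5). Negative
  round-off residuals are clipped with a warning; genuine overshoots raise.
- **Reactions**: forward Euler, operator-split from diffusion. A spatially
  uniform configuration reproduces the well-stirred ODE system to
  first-order accuracy (validated against `scipy.integrate.solve_ivp` in the
  test suite).
- **Metropolis sweep**: compiled with numba (`cache=True`). All randomness
  of a sweep is pre-drawn in a documented order (target sites, neighbour
  choices, acceptance uniforms — the uniform is consumed whether or not the
  attempt reaches the acceptance test), which makes the kernel exactly
  reproducible and lets the test suite verify the compiled sweep against a
  pure-Python reference sweep on identical random streams.
- **Reproducibility**: every run is a pure function of
  (parameters, scenario, seed). Replicate seeds are derived with
  `numpy.random.SeedSequence(base).generate_state(n) % 2^31`.

## 4. Default parameters

| Parameter | Symbol | Default | Units | Rationale |
|---|---|---|---|---|
| Lattice side | — | 400 | px | 0.8 mm tissue patch at 2 µm/px |
| Pixel size | h | 2 | µm | resolves cords 3–10 px wide |
| MCS duration | — | 1 | s | matches observed coalescence timescales |
| VEGF diffusivity | D | 10 | µm²/s | matrix-hindered growth-factor diffusion |
| VEGF production | α_V | 0.003 | conc/s | uniform paracrine source |
| ECM production | α_E | 0.003 | conc/s | secreted only under cells |
| Binding rate | k | 0.5 | 1/(conc·s) | fast sequestration onto ECM |
| Soluble decay | γ_s | 0.001 | 1/s | slow clearance of free VEGF |
| Fluctuation amplitude | T | 40 | energy | motility high enough to remodel, low enough not to fragment cells |
| Target area | A | 100 | px (400 µm²) | spread angioblast footprint; puts density-matched coverage near ½, which trail-overlap closure requires |
| Area stiffness | λ | 50 | energy/px² | keeps areas within a few px of A, so transient orphan fragments are reabsorbed or dropped |
| Cell–cell energy | J_cc | 40 | energy | — |
| Cell–medium energy | J_cm | 30 | energy | γ_cm = J_cm − J_cc/2 = +10 > 0: contacts are adhesive, free boundary is penalized |
| Chemotaxis (total) | μ | 350 | energy/conc | strong enough that bound-VEGF ridges steer protrusions against J and λ |
| Bound fraction | μ_b/μ | 0.8 | — | bound VEGF is the dominant cue (μ_b = 280, μ_s = 70) |
| Neighbour order | — | 2 | — | Moore, for both energy sums and copy attempts |
| PDE substeps | — | 12 | per MCS | satisfies the diffusion stability bound with ~2× margin |

The CPM constants (T, A, λ, J, μ) were fixed once, from a mechanism study of
the closure process on the scaled (200²) scenario, before the statistical
test protocols were designed, and are not tuned against test outcomes. The
key insight of that study: with a uniform paracrine source there is *no
long-range attraction* between distant cells — network closure is driven by
(i) coverage near one half, (ii) "zipping" where the bound-VEGF trails of
neighbouring cells overlap, and (iii) positive cell–medium surface tension
making established contacts sticky. Parameter sets with zero surface
tension or low coverage produce dispersed blobs that never percolate.

## 5. Cell connectivity

The copy dynamics do not enforce cell connectivity, so a cell can
transiently split; 1-pixel orphan fragments occur when a retraction
disconnects a protrusion tip. With the default energies these fragments are
short-lived: deleting an orphan pixel releases its full boundary energy
(8·J_cm with the Moore neighbourhood) which outweighs the area-deficit and
chemotaxis cost of the parent giving it up. Morphometric cell lengths are
computed on each cell's largest 8-connected piece, because the covariance
of a split cell's pixels would measure fragment separation instead of cell
shape.

## 6. Morphometrics

All measures operate on the binary cell mask:

- **β0 / β1**: 8-connected foreground components and enclosed 4-connected
  background components (`n_lacunae`); holes touching the image border are
  excluded by default. Validated in the test suite against independent
  flood-fill and Euler-characteristic (V−E+F) oracles.
- **Lacuna geometry**: per-hole area (pixel count), perimeter (traced
  pixel-edge contour simplified with a 1.2 px Douglas–Peucker tolerance —
  axis-aligned rectangle perimeters are exact, digital circles within ~1% of
  2πr), and roundness Q = 4πA/P², capped at 1.
- **Percolation**: some single 8-connected component touches all four image
  borders.
- **Skeleton measures**: homotopy-preserving thinning
  (`skimage.morphology.skeletonize`); spanning length = skeleton pixel
  count; cord widths = Euclidean distance transform of the mask sampled at
  skeleton pixels.
- **Node graph**: skeleton pixels with ≥3 skeleton neighbours are raw
  branch points; degree-2 chains are contracted to edges; proximate branch
  nodes are merged agglomeratively whenever their separation is smaller
  than the larger of their local cord half-widths (closest pair first), so
  a thick junction counts once.
- **Fractal dimension**: box counting over a dyadic size series, by default
  on the skeleton.
- **Lacunarity**: gliding-box statistic Λ(r) = var(M)/mean(M)² + 1 of box
  mass, computed with an integral image; reported per size and as the mean.
- **Interface length**: count of 4-adjacent foreground/background pixel
  pairs (image border excluded).
- **Cell lengths**: per cell, L = 4·√λ₁ of the population covariance of its
  (largest piece's) pixel coordinates — the major axis of the
  moment-equivalent ellipse — normalized by the isotropic diameter
  2·√(A/π).

## 7. In-silico experiment suites

- `run_repetitions`: replicate runs with derived seeds; morphometric
  mean/SD tables.
- `sweep_sensitivity`: each PDE rate (k, α_V, α_E, γ_s) varied ×0.1 and ×10
  against the shared-seed reference.
- `sweep_diffusivity`: the three transport modes.
- `sweep_chemotaxis_ratio`: μ_b/μ swept at fixed μ.
- `sweep_density`: cell count swept at fixed tissue size; reports the
  percolation onset (midpoint between last failing and first passing
  density), and the densities maximizing node and lacunae counts.
- `track_dynamics` / `time_to_closure`: per-snapshot β0, β1, percolation
  and cell lengths; closure = first snapshot that is a single percolative
  component.

## 8. Limitations

- Forward Euler with operator splitting is first-order in time; the substep
  heuristics favour robustness over efficiency.
- The box-counting dimension on small patterns is sensitive to the box-size
  series; the largest boxes saturate and are best excluded when a pattern
  barely spans the image.
- The perimeter estimator is convention-bound (documented above); roundness
  values from other conventions (e.g. raw crack length, Crofton) differ
  systematically.
- At high coverage (≳⅔), strong ECM overproduction freezes the pattern into
  a fine web rather than preventing coalescence outright, because initial
  neighbours are close enough for membrane fluctuations to bridge the gaps
  before immobilization; see the experiment-suite discussion in the README.
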