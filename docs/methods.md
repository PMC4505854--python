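# Methods

## The model

Glioblastoma multiforme (GBM) infiltrates the brain diffusely, preferentially
along white-matter fiber tracts, and its margin is a smooth gradient of cell
density rather than a sharp interface.  `gbmsim` implements a diffuse-interface
binary-mixture description of this process.  Tissue is a saturated two-phase
mixture: a tumor-cell phase with volume fraction φ and a liquid/host phase
with fraction 1 − φ, both incompressible with equal true density.  Mass and
momentum balance with a Rayleigh-type dissipation closure yield a Darcy-like
law for the cell velocity, **v** = −K(φ)∇Σ, driven by the excess pressure

    Σ = f(φ) − ε² Δφ,      f(φ) = E φ² (φ − φ_e) / (1 − φ),

where f is the derivative of the bulk free energy: adhesion (f < 0) below the
equilibrium fraction φ_e, repulsion above it, diverging at cell saturation
φ → 1.  The ε² term penalizes sharp gradients of φ and regularizes the
interface.  The motility K(φ) = (1 − φ)²/M is the inverse interphase
friction, degenerate at saturation.  Combining these with nutrient-limited
logistic growth and a fiber-aligned Keller–Segel chemotactic flux gives the
phase equation

    ∂φ/∂t = ∇·( φ(1−φ)²/M ∇Σ ) + ν φ (n/n_s − δ)(1 − φ) − ∇·( k_n φ **T** ∇n )

coupled to oxygen reaction–diffusion

    ∂n/∂t = ∇·( **D** ∇n ) + S_n (n_s − n) − δ_n φ n.

**D** is the water diffusion tensor measured by DTI, used directly as the
oxygen diffusion tensor; **T** = **D**/D_n with D_n = tr(**D**)/3 (the mean
diffusivity) is the dimensionless tensor of preferential directions.  It has
trace 3 wherever defined, equals the identity in isotropic tissue, and biases
chemotaxis along the local fiber orientation without changing its overall
strength.

Boundary conditions on the skull boundary: φ = 0 and ∇φ·n̂ = 0 (the latter is
the natural condition of the Σ equation in the mixed form), and n = n_s —
the vasculature maintains the physiological oxygen level far from the tumor.
The initial tumor is a Gaussian bump with peak slightly above φ_e (default
1.1·φ_e, width σ = 2 mm); the initial oxygen field solves the steady nutrient
equation for that φ, which is n_s outside the lesion and dips toward the core.

## Parameters

All computation is in (mm, day, mM, Pa).  Defaults are the values used by the
full three-dimensional reference simulation of the model; literature ranges
are wider and any value can be set per run in the TOML config.

| symbol | field | default | units | meaning |
|---|---|---|---|---|
| ν_c | `nu_c` | 0.25 | 1/day | proliferation rate (sensitivity studies use 1) |
| δ_c | `delta_c` | 0.3 | – | hypoxic-death threshold on n/n_s |
| n_s | `n_s` | 0.07 | mM | physiological oxygen concentration |
| k_n | `k_n` | 100 | mm²·mM⁻¹·day⁻¹ | chemotactic coefficient (literature value 1296) |
| M | `M` | 5000 | mm⁻²·Pa·day | interphase friction (literature 1378–4287) |
| ε | `eps` | 0.02 | Pa^½·mm | diffuse-interface coefficient |
| E | `E` | 694 | Pa | Young's modulus of brain matter |
| φ_e | `phi_e` | 0.389 | – | equilibrium cell fraction |
| S_n | `S_n` | 10⁴ | 1/day | blood–tissue oxygen transfer rate |
| δ_n | `delta_n` | 1000 | 1/day | oxygen uptake rate (admissible 8640–15650) |
| D_n | `D_n` | 86.4 | mm²/day | scalar oxygen diffusivity for isotropic runs |
| χ | `chi` | 900 | Pa | interstitial fluid pressure scale (960 for tumor tissue) |
| l_n | `l_n` | 0.1 | mm | oxygen penetration length |

Two derivations close the set.  The uptake rate is δ_n = D_n/l_n², giving
8640–15650 day⁻¹ for D_n between 86.4 and 156.5 mm²/day at l_n = 100 μm.
For ε the literature's dimensional bookkeeping (a "characteristic interaction
distance ε/χ of the order of the cell size") cannot be made consistent as
stated; this package adopts the convention ε = √χ · cell_size, which makes
ε²Δφ carry pascals like f(φ).  With χ = 900 Pa and a 15 μm cell this gives
ε = 0.45; the reference comparison run instead states ε = 0.02 directly, and
`eps` is always accepted as a plain number.  Note that on desk-scale meshes
both values put the equilibrium interface width far below the cell size, so
the numerical interface is resolution-limited; this is a property of the
model at these parameters, not of the implementation.

## Discretization

**Space.**  Linear (P1) tetrahedral finite elements, assembled vectorized in
numpy/scipy.sparse.  The fourth-order phase equation is solved in the
standard mixed form in (φ, Σ).  Nonlinear coefficients are evaluated with
one-point (cell-mean) quadrature in flux terms and nodally in reaction terms;
the Jacobian differentiates exactly these quadratures, so Newton is exact for
the discrete residual.  Mass matrices are lumped (vertex quadrature)
throughout: for the nutrient equation this preserves discrete monotonicity,
and for the phase equation it suppresses the node-to-node oscillation that
consistent-mass P1 transport develops at the advancing chemotactic front
(with consistent mass the phase field accumulates undershoot of order 10⁻²
at coarse resolution; with lumping it stays non-negative to solver
tolerance).  Structured domains use the Kuhn (Freudenthal) subdivision of a
hexahedral grid — six tetrahedra per cell — which is conforming and exactly
symmetric under coordinate permutation, so isotropic runs are spherical to
round-off by construction.  Local refinement near the tumor seed is red
(1:8) subdivision with green conformity closure (single-edge and face
templates; non-template configurations are promoted to red).

**Time.**  The phase system uses Crank–Nicolson.  The nutrient equation is
advanced first in each step by TR-BDF2 (the L-stable, second-order
trapezoidal/BDF2 composite with γ = 2 − √2).  Plain trapezoidal stepping is
not an option for the nutrient: its reaction terms are very stiff
(S_n·dt ≈ 500 at the default dt), the trapezoidal amplification factor is
then ≈ −1, and the oxygen field oscillates past n_s by ~10⁻⁴ relative,
violating the maximum principle n ∈ [0, n_s].  TR-BDF2 damps the stiff modes
and keeps n within bounds to round-off while preserving overall second-order
accuracy (verified: observed order ≈ 2 globally, ≈ 3 per step against a
stiff ODE oracle).

**Coupling.**  Staggered: the nutrient solve sees the phase field only
through its uptake coefficient δ_n φ n, with φ at the intermediate and new
time levels supplied by linear extrapolation from the two previous steps
(first step: one predictor–corrector pass).  This keeps the phase
nonlinearity out of the nutrient solve and the chemotaxis term linear in the
Newton system, at no cost in order.  Setting `staggered = false` runs the
corrector pass every step.

**Solvers.**  The nutrient systems are symmetric positive definite after
symmetric elimination of the Dirichlet rows and are solved by Jacobi-
preconditioned conjugate gradients (the stiff reaction makes them strongly
diagonally dominant; a handful of iterations suffices), with a direct solve
as fallback.  The (φ, Σ) Newton system exploits the diagonal lumped mass in
the Σ block: the Σ increment is eliminated exactly and only the N×N Schur
complement in φ is solved, by GMRES preconditioned with a near-exact
incomplete LU (drop tolerance 10⁻⁵, fill factor 10 — an exact factorization
of this two-hop-stencil operator suffers severe fill).  The preconditioner
and Schur matrix are refreshed lazily, only when the Newton residual stops
contracting (or dt changes); the convergence test is always on the true
residual (relative tolerance 10⁻⁸, max 20 iterations).  On Newton failure
the step is halved, up to three times.

**Guards.**  f(φ) and the flux coefficients are evaluated on φ clipped to
[0, 1 − 10⁻⁶] (`clip_eta`); clip events are counted and logged.  A step
whose phase field leaves [−10⁻², 1 + 10⁻²] aborts with advice to reduce dt;
smaller excursions beyond ±10⁻³ are logged.  Nutrient bounds are checked at
every snapshot.

## Shape metrics

The tumor region is Ω_t = {x : φ ≥ ε_t}, realized as the cells whose
barycentric (vertex-mean) φ reaches the threshold; its volume is the sum of
those cell volumes.  ε_t defaults to 0.05 — the model only requires
ε_t > 0 and no canonical value exists, so every report states the ε_t used.
Semi-axes Δx, Δy, Δz are measured along the coordinate axes through the
region centroid (matching how the growth figures are drawn, not via
principal components): φ is interpolated along each axis line and Δ is half
the distance between the outermost crossings of the ε_t level, with linear
interpolation between samples.  For a Gaussian profile of amplitude A and
width σ this recovers the closed form Δ = σ√(2 ln(A/ε_t)) to a fraction of
a cell.  For indicator-like fields the barycenter rule biases the volume by
O(h); convergence to the analytic volume under refinement is first order.

## Synthetic phantoms

Patient DTI and the patient mesh are not distributable, so the tensor
phantoms stand in for them:

* **isotropic** — D = D_n·I everywhere; T = I.  The control condition.
* **axis-aligned** — D_xx = D_n, all other components zero, so T =
  diag(3,0,0); the degenerate single-fiber-direction construction used by
  the sensitivity studies.
* **fiber bundle** — a curved tract: within a radius of a polyline
  centerline the tensor has eigenvalues (parallel, perp, perp) with the
  principal axis tangent to the centerline; outside, isotropic at the mean
  eigenvalue.  Emulates a tract such as the corpus callosum.

What these phantoms do not emulate: measurement noise, partial-volume
effects, negative-eigenvalue artifacts (handled separately by
`regularize`), background/CSF segmentation, or registration error.  Passing
tests on phantoms therefore validates the transport and normalization
machinery and the solver's response to anisotropy — not the clinical
pipeline upstream of it.

Voxel-to-mesh transfer assigns each cell the tensor of the voxel containing
its barycenter (nearest-voxel, no interpolation), matching the
voxel-to-tetrahedron assignment used with registered patient data.  Voxel
grids are axis-aligned (world = origin + index·spacing); general affines are
rejected explicitly.  Background voxels (zero mean diffusivity) receive
T = I, are masked from statistics, and are never silently divided by zero.

## Desk-scale experiment defaults

The drivers reproduce trends, not patient-geometry numbers.  Problem sizes
were chosen once so a full study runs in minutes on one core:

* Sensitivity sweeps: 36 mm box, 12³ hex resolution (10 368 tets), axis-
  aligned phantom, dt = 0.1 day; horizons 6 day (M–k_n) and 9 day
  (S_n–δ_n); ν = 1, ε = 0.45 as in the sensitivity studies.  Default grids
  M ∈ {2000, 5000}, k_n ∈ {1, 100}, S_n ∈ {4000, 10⁴}, δ_n ∈ {2000, 8640}:
  values inside the stated admissible ranges, spaced widely enough that the
  monotone trends exceed discretization noise at this resolution (the
  trend assertions carry a 2 % tolerance).
* Comparison runs: same box, reference parameter set, 10 day horizon.
* Isotropy check: 40 mm box at 24³ (82 944 tets), 6 day horizon.

The documented trends all reproduce: the maximum fraction ratio grows with
M while tumor size barely responds; elongation along the fiber axis and
total volume grow with k_n (k_n = 1 stays spherical within 1 %); raising
S_n raises the peak fraction and shrinks the thresholded volume; raising
δ_n deepens the nutrient sink and grows the volume; and the anisotropic run
is longer along x and occupies more volume than its isotropic control,
i.e. ignoring fiber anisotropy underestimates the invaded region.

## Known limitations

* Absolute case-study sizes (e.g. a 10.6 mm major semi-axis at day 25)
  depend on the unavailable patient DTI, mesh and seed location and are out
  of scope; only trend-level statements are validated.
* The diffuse interface is resolution-limited on desk meshes (see above);
  semi-axes carry O(h) uncertainty.
* No angiogenesis, therapy, resection or tissue-specific parameter maps;
  the vasculature is homogeneous through S_n.
* The mesh readers accept straight-sided tetrahedra only; labeled meshes
  must be prepared externally.
* Chemotactic transport is discretized with central (Galerkin) fluxes;
  lumping controls oscillations at the resolutions used here, but very
  large k_n on coarse meshes remains under-resolved and is reported through
  the phase-bound guards rather than silently stabilized.
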