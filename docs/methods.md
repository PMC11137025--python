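# Methods

## The five-element circuit and its steady state

The cell is coarse-grained into an active contractile element (myosin),
a compression branch in parallel with it (microtubule element `c_mt` plus
vimentin element `c_v1`), and a tension branch in series (actin element
plus vimentin element `c_v2`) that connects to a linear matrix spring
`k_m`. Contractility is a stress-valued state variable ρ coupled to the
transmitted tension σ by a linear positive feedback, ρ = f_m σ + f₀ρ₀,
which coarse-grains tension-activated signalling (Rho-ROCK, Ca²⁺). The
feedback gain must satisfy f_m < 1; at f_m ≥ 1 the loop has no bounded
fixed point and the solver raises a stability error. f₀ and ρ₀ never
appear separately in the 1D model, so they are lumped into the single
basal active stress `f0_rho0`.

The actin element stiffens with tension but not compression:
C_A(σ) = c_i + β σ₊/(1 + σ₊/σ_sat). The saturating form is a modelling
choice: the stiffening part must vanish at low tension, grow with σ, and
plateau so that stiffness and traction saturate on rigid matrices. β is
the initial stiffening slope (dimensionless), σ_sat the stress scale at
which half the asymptotic stiffening β·σ_sat is reached.

Eliminating strains gives the scalar residual
g(σ) = σ(1 + C_p(1/C_s(σ) + 1/k_m) − f_m) − f₀ρ₀, strictly increasing on
σ ≥ 0 with g(0) = −f₀ρ₀ < 0 and g ≥ 0 at σ = f₀ρ₀/(1−f_m), so the root is
unique and always bracketed. It is found with scipy's safeguarded Brent
iteration at machine-precision tolerances and verified against |g| ≤ 1e-10
(configurable). The degenerate tension branch C_s ≡ 0 is returned as
σ = 0 (total loss of force transmission) rather than an error.

Sign conventions: tension positive, ε_p ≤ 0 in the compression branch,
compatibility −ε_p = ε_s + ε_m with a fixed far boundary. The vimentin
element `c_v1` is linear and bidirectional by default (a compression-only
variant was considered and not adopted; at the solved steady states the
parallel branch is always in compression, so the distinction is inert
there).

## Perturbation operators

Perturbations return new parameter objects (inputs are never mutated) with
`magnitude` the retained fraction in [0, 1]:

- `vimentin_null`: c_v1 = c_v2 = 0 (genetic knockout).
- `mt_depoly`: c_mt → m·c_mt and f₀ρ₀ → f₀ρ₀·(1 + g_gef·(1−m)). The
  contractility boost models GEF-H1/Rho-ROCK activation by depolymerised
  tubulin; the biology constrains only the direction of the effect, so the
  law is the simplest one linear in the depolymerised fraction, with gain
  `g_gef`.
- `actin_disrupt`: scales both c_i and β (drug reduces filaments and the
  capacity to form stress fibres).
- `myosin_inhibit`: scales f₀ρ₀.

## Default wild-type preset and the genotype crossover

Model units are dimensionless (stresses in units of the basal active
stress f₀ρ₀ = 1; stiffnesses on the same scale); the preset is not
calibrated to kPa. The pinned wild-type preset is

| parameter | value | meaning |
|---|---|---|
| c_mt | 3.5 | microtubule element |
| c_v1 | 0.5 | vimentin ∥ microtubules |
| c_i | 0.02 | initial (sparse) actin network |
| β | 6.0 | actin stiffening gain |
| σ_sat | 3.0 | stiffening saturation stress |
| c_v2 | 0.15 | vimentin ∥ actin |
| f_m | 0.5 | tension–contractility feedback gain |
| f₀ρ₀ | 1.0 | basal active stress (stress unit) |
| g_gef | 0.5 | GEF-H1 contractility gain |

The large dynamic range of the actin element (c_i = 0.02 up to
c_i + β·σ_sat ≈ 18) encodes the difference between a sparse cortical
network on soft matrices and a saturated stress-fibre network on rigid
ones; it is what lets the series vimentin element dominate transmission at
low tension while becoming negligible at high tension.

The crossover logic in closed form: at fixed stress level the knockout
transmits less than the wild type iff C_A < c_mt·c_v2/c_v1. Since C_A
rises from c_i (soft, low tension) toward c_i + β·σ_sat (stiff, high
tension), choosing c_i below and the saturated stiffness above the
threshold produces exactly one crossover; with β = 0 the comparison is
stress-independent and no crossover can occur, which is asserted as a
regression property. The preset was selected by a seeded random scan over
stiffness ratios for this phenomenology with comfortable margins
(including under ×2 scalings of either vimentin element) and then rounded
and pinned. One caveat the scan exposed: in the extreme-soft limit
k_m → 0 the matrix term C_p/k_m dominates and the knockout (smaller C_p)
always transmits marginally more, so the default genotype grid
(logspace(−1, 3), 57 points) starts above that reversal; within the grid
the knockout is strictly more sensitive to matrix stiffening near the
crossover. Crossover refinement bisects fresh steady-state solves in
log-k_m to 1e-6 relative width, ties toward the lower stiffness.

## Axisymmetric contractile disc

The full 3D arbitrary-shape continuum is reduced to a plane-stress
axisymmetric disc of uniform thickness h on an elastic foundation:

- principal directions are r and θ; each carries the 1D circuit
  independently (Poisson coupling neglected). Per node and direction the
  total strain splits as ε_d = (σ_d − ρ)/C_p + σ_d/C_s(σ_d), solved by
  bracketed scalar root finding (the left side is strictly increasing in
  σ_d).
- contractility feedback acts isotropically on the local in-plane mean
  stress: ρ = f_m·(σ_rr + σ_tt)/2 + f₀ρ₀. Tensorial contractility
  evolution is out of scope.
- the nucleus (r < nucleus_radius) is a passive, stiffer material region
  (linear springs c_mt = c_i = 10, no activity, no feedback), not an
  envelope/lamina shell.
- focal adhesions are a two-level foundation: stiffness Y = k_f below a
  traction threshold and k_f·fa_stiff_factor above it. The hard switch is
  regularized by a linear ramp over ±5% of the threshold; without the
  ramp, nodes sitting at the threshold flip state between fixed-point
  iterations and the outer loop can limit-cycle at some mesh sizes. The
  ramp is used identically in the residual evaluation.

Force balance d σ_rr/dr + (σ_rr − σ_tt)/r = Y(u)·u/h is discretized with
central differences (u(0) = 0; traction-free edge σ_rr(R) = 0 via a
second-order one-sided stencil) and solved by a secant-stiffness
fixed-point loop: freeze K_d = C_p C_s/(C_p+C_s) and prestress
P_d = ρ C_s/(C_p+C_s) at the previous stress, solve the linear sparse
system, recover exact per-node stresses, update ρ and Y, under-relax u
(factor 0.7), and iterate to a relative change below 1e-9 of the basal
stress (default; 400 iterations maximum). The reported residual is the
algebraic residual of the assembled finite-difference system at the
converged state, scaled by the mesh spacing to stress units.

Defaults: R = 20, nucleus radius 5, h = 1, 201 nodes; substrate presets
foundation_stiffness = 1.0 (stiff) and 0.002 (soft), fa_threshold = 0.1,
fa_stiff_factor = 1.5. With a near-rigid foundation and uniform material
the interior reproduces the 1D rigid-limit stress to well below 0.1% (a
thin edge boundary layer of width √(K h/Y) accommodates the free edge).
The branch summaries are σ_c (compressive-branch stress magnitude,
C_p·|ε_p| where ε_p < 0) and σ_t (tensile series stress σ₊), reduced to a
juxtanuclear mean (r within 1.2× the nucleus radius) and a peripheral mean
(outer 10% of radius). For axisymmetric fields the per-direction extrema
coincide with the eigenvalues of the diagonal stress tensor; the tests
cross-check against a generic eigensolver.

## Bead drag

Vector elasticity around a translating sphere is replaced by a pseudo-1D
spreading model: the transmitted force amplitude F produces local stress
F·(r0/x)^p with spreading exponent p = 2 (configurable), the local strain
is the inverse constitutive law, and u(x) integrates the strain from the
fixed far boundary (L = 21·r0, u(L) = 0). F is found by bracketed root
finding on the imposed bead displacement u0 = ∫ε dx (strictly increasing
in F for monotone laws). Quadrature is cumulative Simpson on 2001 uniform
nodes, which reproduces the linear closed form
u(x) = u0(1/x − 1/L)/(1/r0 − 1/L) to ~1e-8 of u0. The drag is
quasi-static; the experimental 2 µm/s speed is not modelled.

Laws: linear σ = e0·ε; stiffening σ = e0·ε(1 + (ε/ε_c)^(n−1)) with n = 2,
ε_c = 0.05 (secant modulus grows with strain); softening bilinear with
tangent dropping to 0.3·e0 above ε_c = 0.05 (damage). The exponents are
implementation choices — the experiment constrains only the
stiffening/softening character — and the pointwise ordering
u_stiffening ≥ u_linear ≥ u_softening is a theorem for fixed u0 (stiffer
far-field response redistributes strain outward), asserted strictly over
the mid-domain. ε_c = 0.05 sits below the near-bead linear strain (~0.21)
so both nonlinearities are actually engaged.

## Filament generation and curvature

Synthetic buckled filaments are y(x) = A·sin(2πx/λ) plus i.i.d. Gaussian
noise on y, sampled at fixed spacing (default 0.1 µm) over 90 µm,
reproducible by seed. Curvature is the three-point circumradius (Menger)
formula κ = 2|cross|/(abc) after moving-average smoothing of the
coordinates (window 5 points, odd); collinear triples give κ = 0. The
circumradius form was chosen over spline fitting for robustness and exact
analytic test cases (line, circle, sinusoid crest κ = A(2π/λ)²); it is
rotation/translation invariant and scales as 1/s under uniform scaling.

The genotype fixture mirrors ~100 filaments per condition (10 cells × 10
filaments): wild type A = 0.25 µm, λ = 12 µm; vimentin-null A = 0.8 µm,
λ = 15 µm (higher A(2π/λ)²), both with 10 nm noise at 0.5 µm trace
spacing. At fine spacing the Menger estimator amplifies localization noise
(κ_noise ~ 2·noise/h²), so the fixture uses the coarser tracing spacing at
which the buckling signal dominates; real STORM-derived traces would need
stronger smoothing or spline regularization first, which is why passing
tests here validate the estimator and the comparison statistic, not
robustness to raw localization noise. Group comparison is a two-sided
unpaired Student's t test with the per-filament mean curvature as the
statistical unit; tests cross-check its p value against a seeded
permutation oracle (10⁴ shuffles) in a regime where p is away from the
floor.

## What the synthetic data do and do not emulate

The generators cover: matrix-stiffness grids spanning soft-to-rigid
substrates (the experimental 4.5/15/40 kPa moduli map qualitatively into
the soft/crossover/stiff regions of the default grid, but no kPa
calibration is claimed); wild-type vs vimentin-null presets; controlled
buckled-filament populations; and the 1 µm/200 nm bead-drag geometry.
They do not emulate: real traction-microscopy noise and reconstruction,
3D cell shapes, viscoelasticity or dynamics, biochemical pathway kinetics,
or image-derived filament traces. Passing tests therefore establish the
internal consistency and the predicted qualitative orderings of the model,
not quantitative agreement with any particular cell type.

## Numerical choices and limitations

- Steady-state root finding: Brent bracketing on (0, f₀ρ₀/(1−f_m)],
  xtol 1e-15, residual check 1e-10.
- Sweeps propagate solver failures with the offending k_m; grids must be
  strictly ascending and positive.
- Disc: decoupled-direction rheology ignores Poisson coupling; the
  foundation ramp width (5% of threshold) is a regularization, not a
  physical parameter; mesh-doubling changes in peripheral tension are
  under 1% at the default 201 nodes.
- Bead drag: the spreading exponent fixes the geometry; no viscous or
  inertial terms.
- All CSV output is deterministic (fixed column order, 12 significant
  digits) with JSON metadata sidecars carrying parameter hashes and seeds;
  every random draw flows from one seeded generator per run.
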