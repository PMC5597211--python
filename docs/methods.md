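# Methods

`multifib` simulates the growth of an avascular tumour spheroid into a
collagen hydrogel with a two-scale biphasic model: a macroscale poroelastic
continuum whose stromal constitutive behaviour is homogenised, every time
step, from microscale cross-linked fibre networks.

## Macroscale model

The domain is one octant of a sphere: tumour `Ω^T` (radius 0.1 mm) inside a
peritumoural stroma (PTS) shell `Ω^P` (thickness 0.5 mm), with symmetry
planes on the three coordinate planes. Quasi-static momentum balance in the
reference frame,

    ∇·(F·S − P·I) − Q = 0 ,

couples the solid (2nd Piola–Kirchhoff stress `S`, deformation gradient `F`)
to the interstitial fluid pressure `P` with an effective-stress coefficient
of one; `Q` is the homogenised body-force correction. Mass balance

    (1/M) ∂P/∂t + θ^S ∇·V^S + θ^F ∇·V^F − Q^F = 0

carries Biot storage (`M` the undrained bulk modulus), solid compaction and
Darcy transport `V^F = −K (θ^F ∇P + d)`. Solid and fluid volume fractions
satisfy `θ^S + θ^F = 1` and are constant per region in the mass balance.

The tumour is hyperelastic with multiplicative growth `F = F_e F_g`,
`F_g = f(t) I`, and the isochoric neo-Hookean energy

    W = μ/2 (J^{-2/3} I₁ − 3) + κ/2 (J − 1)² .

This form is stress-free in the reference configuration and reproduces the
drained shear and bulk moduli (μ, κ) exactly at small strain; the commonly
written variant without the isochoric split carries a spurious reference
stress μI, which contradicts the stated stress-free initial state, so the
isochoric completion is used. Growth follows a Gompertz stretch
`f(t) = α exp(−β exp(−γt))`, applied in normalised form `f(t)/f(0)` so the
simulation starts at stretch 1; the plateau of the normalised stretch is
`exp(β)` and is the configuration parameter (`growth.plateau`).

Boundary conditions: zero normal displacement on the symmetry planes and on
the outer sphere (rollers), zero fluid flux through every boundary, traction
and flux continuity across the tumour–stroma interface by shared assembly.
For benchmark problems the solver also accepts constant tractions and
drained (P = 0) facets.

## Microscale model

Each stromal RVE is a unit parametric cube containing a random cross-linked
fibre network: straight segments with uniform random orientations and
midpoints are welded at near-intersections (tolerance 0.03 side lengths)
into pin joints, clipped at the faces (boundary nodes), trimmed of dangling
ends, and reduced to the largest connected component; sub-fibres shorter
than 0.08 side lengths are contracted (the drag model scales as 1/length, so
slivers would dominate the permeability). The truss-element count is kept in
configured bounds by adapting the segment count (noisy bisection) and, when
the percolation transition overshoots the band, by seeded pruning of the
giant component. Prealigned networks bias the direction distribution by
`d → diag(s)² d / |·|`; the default prealignment stretch
(1.246, 1.0, 1.231) produces orientation-tensor diagonals ≈ (0.39, 0.23,
0.38).

Fibres carry axial force only,

    f = (a^f e^f / c₀) [exp(c₀ ε) − 1] ,

with Green strain `ε = (ℓ² − ℓ₀²)/(2ℓ₀²)`; the same expression describes
compression (no buckling model). The interpolated interstitial pressure
enters as an axial force `−a^f p̄` per fibre; no microscale pressure
equation is solved. Equilibrium of the free pin joints is found by a
Levenberg-style Newton descent on the exact network energy (the closed-form
integral of the force law, an `erfi` expression), with adaptive diagonal
shifts for the indefinite tangents of buckled regions, load substepping, and
a trust-region Newton fallback for the rare flat-mode stalls. Boundary
increments are extended into the interior by their best-fit affine field
before equilibration, which makes warm starts robust to the large rigid
translations carried by the downscaled macro motion.

## Scale coupling

Downscaling interpolates macro displacements to RVE boundary nodes with the
quadratic shape functions and pressures to all RVE nodes with the linear
ones, converting displacements to the parametric frame with the physical RVE
side length (20 µm). Upscaling evaluates, per RVE in the deformed
configuration:

* stress `S = (1/V) Σ f (n̂_f ⊗ n̂)` over boundary-crossing fibres,
  symmetrised before use as a macroscale 2nd Piola–Kirchhoff stress;
* body source `Q = (1/V) Σ ((s − S)·u′)·n̂`, with `u′` the displacement
  gradient along the incident fibre;
* permeability `K = (1/V) Σ (rᵀ c r)⁻¹` from square-cylinder-array drag
  coefficients `c₁₁ = 4πℓ/(−ln θ^S − 1.476 + 2θ^S − 0.5 θ^S²)`,
  `c₂₂ = c₃₃` with the −1.774 θ^S² companion (perpendicular/parallel drag
  ratio → 2 in the dilute limit);
* mixing vector `d = (1/V) Σ k·v^S` and fluid source
  `Q^F = (a^f/V) Σ (V^S − v^S)·n̂`.

Dimensionalisation uses `η = θ^S V/(a^f L)` with the substitution
`x_dim = ηx` applied uniformly: stresses scale as 1/η and permeabilities as
1/η⁴. Two frame choices matter and are deliberate. First, η and the drag
volume fraction are evaluated in the **current** frame: the packing fraction
is `θ^S/J` (J from the affine part of the RVE boundary deformation) and L is
the deformed total length. Equilibrium truss networks accommodate
compression almost entirely non-affinely — fibre lengths barely change — so
a reference-frame evaluation would make permeability blind to compaction;
the current-frame evaluation produces the interface permeability drop that
compaction must cause ("more closely packed, less permeable"). Second, all
RVEs share one gel: each network's cross-section is rescaled so `a^f L` (and
hence η = 2.0) is identical across RVEs. Without this, the sampling spread
of total fibre length enters the permeability as 1/L⁴ and masquerades as a
large spurious spatial heterogeneity.

Two closures are the package's own, because the printed mixing-vector
definition is dimensionally inconsistent with Darcy's law: (i) `d` uses only
the non-affine fluctuation of the micro solid velocity (the affine part is
already carried by the macroscale terms) and is mapped to pressure-gradient
units through the squared scalar permeability, making `K·d` the
permeability-weighted mean fluctuation velocity; (ii) `v^S` in `Q^F` is the
fibre midpoint velocity, so the non-affine lag of the interior relaxation
generates the source (boundary-node velocities equal the downscaled macro
velocity by construction and would cancel identically).

## Discretisation and solvers

Displacements use 27-node triquadratic hexahedra, pressure the 8 corner
nodes (Taylor–Hood-type pairing). The octant is meshed as a cubed-sphere:
three blocks per radial shell, the innermost shell collapsing onto the
origin (positive Jacobians at all interior quadrature points). Solid terms
are integrated with the full 3×3×3 Gauss rule — the reduced 2×2×2 rule
leaves hourglass modes on 27-node elements in a displacement-based solver —
while the multiscale constitutive state is sampled at the 8 standard 2×2×2
points (one RVE each) and mapped to the 27 integration points by
nearest-octant clustering. Fluid matrices use the 2×2×2 rule with the
element-centre constitutive set (single-point fluid sampling).

Each time step solves the coupled momentum/mass system monolithically:
Newton on the joint (U, P) residual with exact blocks (the displacement
tangent by central differences of the batched stress, the coupling and
pressure blocks analytic), backward Euler in time, and an Armijo line search
on the scaled squared residual. A staggered fixed point was tried first and
diverges for storage-dominated coupling (undrained spectral radius above
one). During the macro solve the stroma responds through a linearisation
`S = S₀ + C:(E − E₀)` about the last homogenised state, with `C` probed once
from a reference RVE by finite-difference strain probes; after the micro
solves the baseline is refreshed. The refresh is under-relaxed (factor 0.5)
against the surrogate's own prediction, which damps the staggered
oscillation of the explicit one-step-lagged coupling without moving its
fixed point. Micro solves run serially in a fixed order; repeated runs are
bit-identical, and permuting the solve order changes no output bit.

## Synthetic data and defaults

There is no external data; the generator defines the study conditions. The
desk-scale default is a 60-element octant (angular 2, radial 2 + 3) with 288
RVEs of 60–100 fibres, time step 2 h to 60 h (Gompertz rate γ = 0.08/h,
plateau 1.35, within 2% of the plateau at the end). Material defaults are
documented in `config.py`; the fibre stiffness is set so the homogenised
stroma has a small-strain shear modulus of ~300 Pa (dense collagen gel), and
the permeability scale so the undeformed stroma sits two orders of magnitude
below the tumour conductivity. With these choices the radius increase at
equilibrium is ~26% and the PTS strain ~5%, emerging from the mechanics
rather than being imposed.

What the generator does not emulate: fibre–fibre contact, bending stiffness,
plasticity or rupture; cell-mediated active remodelling; nutrient-limited
growth; deformation-dependent macroscale volume fractions. Passing tests
therefore demonstrate the mechanics of passive, cross-linked elastic
networks in a biphasic continuum, not the full biology of stromal
remodelling.

## Numerical choices and limitations

* Micro residual tolerance: 1e-8 relative to `a^f e^f` (configurable per
  run through `solver.micro_tol`; ~1e-7 relative to actual fibre forces);
  oracle tests pass tighter values explicitly.
* Macro Newton tolerance: 1e-8 relative to the quadrature-weighted stress
  scale; the global discrete fluid-mass balance closes to ~1e-13 per step
  for sealed boundaries.
* The interface fluid-speed contrast against the tumour interior saturates
  near ~5 at this resolution: Biot storage absorbs the influx, making the
  interior speed proportional to radius; the contrast against the far-field
  stroma is ~60–120. Stiffer storage collapses the interface peak as well.
* Stress–permeability and stress–velocity rank correlations are computed on
  element fields extrapolated to the stromal corner nodes. At desk scale
  they reach about −0.87 and +0.83: beyond the first stromal layer the
  deformation signal vanishes and realisation noise of the 60–100-fibre
  networks scrambles the remaining ranks, so the near-unity correlations of
  the full-scale configuration are approached but not reached.
* Degenerate inputs: collapsed-face hexahedra at the origin are accepted
  (positive Jacobians at interior quadrature points); exactly collinear
  networks make K rank-deficient and are rejected by the generator's
  connectivity and face-coverage checks.
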