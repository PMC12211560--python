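# Methods

## The coupled-membrane model

The system is two closed membranes — the outer membrane and the inner
boundary membrane — held parallel at a fixed separation *d* (default
10 nm, the scale set by intermembrane tethering complexes). Its shape is
represented by the mid-surface half-way between them, with area *A* and
total curvature *J = c₁ + c₂* at each point. Because the surfaces are
parallel, their area elements differ from the mid-surface element at
first order in *d·J*, which integrates to

    A_out = A + (d/2)·M,   A_in = A − (d/2)·M,   ΔA = d·M = d·⟨J⟩·A,

with `M = ∮J dA`. These relations hold in the small-curvature regime
`|J|·d < 1`, which the code enforces (`membrane_areas` rejects shapes
where the parallel-surface construction would self-intersect). Gaussian
curvature terms are smaller by a further factor of `|J|·d` and are
neglected; they are never stored.

Both membranes are treated as non-stretchable Helfrich sheets with zero
spontaneous curvature and bending modulus κ. To leading order both carry
the mid-surface curvature, so the system energy collapses to a single
Willmore-type functional, `F = 2·(κ/2)∮J²dA = κ∮J²dA`. Minimizing shapes
are independent of κ, so κ defaults to 1 and energies are reported in
units of κ. For every closed surface `∮J²dA ≥ 16π`, with equality only
for spheres — a floor the test suite checks on all solver output.

### Constraints

Minimization fixes the mid-surface area *A* (non-stretchable membranes;
no lipid exchange on the modelled timescale) and the area difference
ΔA/A (set by how much boundary membrane has folded into cristae). The
enclosed **volume is left free**: water and solutes move across
mitochondrial membranes far faster than lipids do, and fixing the volume
at the sphere's value would forbid any shape change at fixed area. This
is a genuine modelling choice; a volume-constrained variant would trace
a different (generally higher-energy) branch.

### Discretization and minimization

Shapes are closed, axisymmetric, and up–down mirror symmetric (all
shapes on the elongation branch are), so only the half-profile is
represented. The tilt angle of the profile tangent is expanded as

    psi(t) = (π/2)·t + Σₖ aₖ sin(kπt),  t = s/h ∈ [0, 1],

with *h* the half arclength; the boundary conditions psi(0)=0 and
psi(1)=π/2 are built into the basis, so every iterate closes smoothly at
the poles. Defaults: 16 Fourier modes, 400 Simpson quadrature intervals,
radius integrated from cos(psi) by cumulative trapezoid. The unknowns
(h, a₁..a₁₆) are optimized by SLSQP with equality constraints on *A* and
*M*; converged residuals are at machine precision, far inside the 1e-4
acceptance tolerance. A soft penalty keeps the radius non-negative
(inactive at solutions on this branch).

Targets below the sphere's own value 2d/R₀ belong to the oblate /
biconcave branch, which is out of scope and rejected explicitly.

### Continuation and branch control

Families over increasing ΔA/A are solved by continuation: each solve is
warm-started from the previous solution, beginning from a sphere with a
small seeded symmetry-breaking perturbation (0.1% of R₀; results are
insensitive to the seed to ~1e-8 in sphericity). The default step is
0.01 in ΔA/A with halving on failure.

Just above the sphere the energy landscape contains higher-energy
multi-lobed (pearled) local minima, and a naive descent can fall onto
them. Each continuation step is therefore guarded by the
prolate-spheroid trial family: the one-parameter family of spheroids
rescaled to the target area contains a member matching any reachable
ΔA/A, and its energy — computed from analytic elliptic-parametrization
curvatures, independent of the profile code — is a rigorous upper bound
for the constrained minimum. Steps whose energy exceeds the bound are
rejected, halved, and retried from a freshly perturbed iterate. Along
the resulting branch sphericity (36π·V²/A³) decreases and energy
increases monotonically.

A note on morphology: the free-volume minimizers develop a shallow
interior neck almost immediately after leaving the sphere (at
ΔA/A ≈ 0.10 for the 500 nm/10 nm system the necked minimizer costs
1.64·16πκ against 1.91·16πκ for the best neck-free spheroid). Shape
classification is threshold-based: "sphere" at sphericity ≥ 0.999,
"peanut" when the radius profile has an interior local minimum at least
2% of the maximal radius deep, "elongated" otherwise. Smooth prolate
shapes therefore appear as trial shapes and in morphometric fixtures,
while the energy-minimizing branch passes quickly from sphere to peanut.

### Geometric quadrature

Area (`∮2πr ds`), volume (`∮πr² sin psi ds`), and `M` are evaluated by
composite Simpson on the arclength grid (default 200 profile nodes for
exported shapes). Simpson was chosen over trapezoid so that a discretized
sphere reproduces its closed-form area to ~1e-10 relative at the default
resolution; convergence under grid doubling is fourth-order. The
curvature profile uses centred finite differences for dpsi/ds with the
pole limit `sin(psi)/r → dpsi/ds` applied analytically at r = 0.

## Morphometrics

Tracings are closed outline polygons plus open cristae polylines, all in
nm. Area is the shoelace value, perimeter the closed polyline length,
circularity `4π·area/perimeter²` (up to +ε for coarse polygons; stored
unclipped). The 2D cristae fraction doubles each traced crista length
(a crista is two membrane layers): `100·2Σl/(P + 2Σl)`.

The 3D transformation models the mitochondrion as a cylinder with
hemispherical caps of radius R. Each axial ring of width L₁ has 3D area
2πR·L₁ and contributes 2·L₁ to the traced perimeter, so the whole
boundary membrane is `S_boundary = 2πR·(P/2) = πRP`; cap curvature is
absorbed into this approximation. Each crista is a flat disk of diameter
equal to its traced length, counted on both faces: `S = 2π(l/2)²`,
mirroring the 2D doubling rule. The width 2R is automated as the median
chord perpendicular to the principal (second-moment) axis across the
middle 80% of the axial extent; nearly isotropic outlines (moment axis
ratio < 1.05) fall back to the mean caliper width, which by Cauchy's
formula is convex-hull perimeter/π, and are flagged. Whether a manual
"measured diameter" would be a single mid-shape chord or an average is
unknowable from a finished dataset; the median-chord automation is
robust to cap effects and to ~2% outline jitter (within 5% of truth
across 100 seeds in the tests).

Cristae longer than 1.5× the local transverse width are flagged as
likely tracing errors but never dropped. Tracings without any cristae
are measurable; the pipeline excludes them by default (with a logged
count), since in stained-image cohorts "no cristae traced" cannot be
distinguished from "no cristae labelled".

## Synthetic data

The generator emulates manual tracings of dye-stained live-cell STED
images, not the images themselves. Outlines are stadia (2D spherocylinder
silhouettes) with straight sections 0.2–2.2 µm (log-uniform) and cap
radii 125–225 nm (uniform), i.e. organelles 0.45–2.65 µm long and
250–450 nm wide; optional smooth radial jitter (default 2% of the
radius) imitates tracing noise. Cristae are straight transverse segments
— lamellar cristae seen edge-on — with a 40 nm spacing floor.

Cohort coupling: each outline is measured, and its target cristae
fraction is drawn as `f = μ_f + σ_f(ρ·ĉ + sqrt(1−ρ²)·ε)` with ĉ the
standardized circularity, so the population fraction–circularity
correlation equals ρ exactly before crista-length noise (5%
multiplicative by default). Defaults μ_f = 35%, σ_f = 8% keep fractions
in a realistic 10–60% band without clipping. With ρ = −1 and zero noise
the link is deterministic and the sample correlation is −1 exactly.
ρ = 0 serves as the null; across seeds the null r distribution matches
the theoretical `sd ≈ 1/√n`.

Time series implement the conservation mechanism directly: a stadium
retracts its cristae along a non-increasing schedule while the total 2D
IMM length `P + 2Σl` is conserved, so the boundary lengthens as cristae
unfold; the straight section shrinks proportionally to the remaining
cristae and the radius grows to absorb the freed perimeter, ending (at
full retraction) in a circle. This reproduces the rounding-and-swelling
phenomenology of cristae-loss transitions without any lipid gain.

What passing tests on these cohorts do **not** show: robustness to
curved/branched outlines, partially imaged organelles, anisotropic
tracing bias, or segmentation error in raw images — the generator's
`rasterize_trace` provides a first step toward such robustness checks
but photophysically accurate simulation is out of scope.

## Statistics

Pearson r uses the product-moment formula with the exact two-tailed t
transform (n−2 dof) — correct at the small per-group n of size splits —
and is validated against a 10,000-shuffle permutation null in the tests.
The confidence band is the pointwise 95% band for the mean response of
the least-squares fit. The median size split assigns ties to "small"
(the below/above convention leaves ties undefined; a deterministic rule
was chosen and documented). Group comparisons use the unpaired
two-tailed Student's t-test with box summaries (median, IQR, Tukey
whiskers at 1.5×IQR). Time profiles report the Kendall tau of fraction
vs time. No multiple-testing correction is applied anywhere: each
analysis is a single planned test.

## Problem sizes and determinism

Default problem sizes — 5-member shape families at 16 modes/400
quadrature intervals, cohorts of 100, 100–200 seed replicates in the
calibration tests — keep the full suite and the acceptance script in the
minutes range on one CPU while leaving the statistical contracts
well-resolved. All randomness flows through explicit integer seeds
(cohort specs, solver perturbations, raster noise); identical seeds give
byte-identical trace files.

## Known limitations

- Axisymmetric, mirror-symmetric shapes only; no topology changes,
  thermal fluctuations, spontaneous curvature, or area-difference
  elasticity (the hard-constraint limit is used).
- The minimizer finds local minima along a continuation branch; the
  spheroid bound guards against gross branch errors but global
  optimality is not certified.
- The 3D transformation is a deliberately crude cylinder+disk estimate;
  its absolute fractions inherit that crudeness even though trends match
  the 2D measure.
- Synthetic cohorts encode the coupling they are meant to test; they
  validate the pipeline's ability to recover known structure, not the
  biological claim itself.
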