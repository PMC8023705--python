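# Methods

This note documents the physics, the numerical choices and the known
limitations of `sigmadens`.  Everything is in Hartree atomic units:
lengths in bohr, the fine-structure constant α = 1/137.035999, shieldings
dimensionless and reported as ppm (×10⁶).

## Current-density susceptibility from GIAO response matrices

The first-order induced current density of a closed-shell molecule in a
static external field **B** is evaluated in a basis of London orbitals
χ_μ(r) = exp[−(i/2c)(B×(R_μ−R_O))·r] φ_μ(r).  Writing the first-order
complex AO density as D + i Σ_β B_β D^β (D real symmetric, D^β real
antisymmetric — the convention in which engines print GIAO perturbed
densities) and expanding

    J(r) = −Re Σ_{μν} D̃_{μν} χ_ν*(r) [(−i∇ + A(r)/c) χ_μ](r)

to first order in B yields three terms; the gauge origin R_O cancels
between the phase-gradient and diamagnetic terms, leaving

    c·∂J_α/∂B_β = − c Σ_{μν} D^β_{μν} φ_ν ∂_α φ_μ
                  + ½ Σ_{μν} D_{μν} [(e_β×(R_μ−R_ν))·r] φ_ν ∂_α φ_μ
                  − ½ Σ_{μν} D_{μν} φ_μ φ_ν [e_β×(r−R_μ)]_α .

`eval_cdt` implements exactly this expression; no gauge-origin parameter
exists anywhere in the package.  The test suite re-derives the same
quantity symbolically (sympy, with the London phases and an *explicit*
gauge origin) and confirms agreement to 10⁻¹⁰ and independence of R_O.

**Units convention.**  The package stores the *c-scaled* tensor
T = c·∂J/∂B, so that a rigid spherical density carries the Larmor tensor
T_{αβ} = −½ ρ(r) ε_{αβγ}(r−R)_γ with no relativistic prefactor, and the
Biot–Savart kernel carries the whole α² (the atomic-unit analog of
μ₀/4π together with the 1/c hidden in the physical current).  Checks:
the Lamb formula σ = (α²/3)⟨1/r⟩ and the thin-loop field 2πα²I/R both
come out exactly.

**Translation behaviour.**  With the response matrices held fixed, the
GIAO current is *not* invariant under rigid translation: the London
phases contribute a term linear in the absolute coordinate.  Translating
a bundle by t applies the magnetic-translation phase law

    D^β_{μν} → D^β_{μν} + (1/2c) [(e_β×(R_μ−R_ν))·t] D_{μν},

after which the current field is exactly the translate of the original
(`ResponseBundle.translated`; verified to machine precision).  Integrated
shieldings are therefore translation invariant up to quadrature error.

**Charge conservation.**  ∇·(∂J/∂B) vanishes identically for the
analytic models and for closed-shell diamagnetic bundles; for arbitrary
(toy) response matrices, and for finite-basis engine responses, it is
only approximately zero.  `divergence_residual` exposes a second-order
central-difference probe for this.

## Shielding density and sign convention

For nucleus I, σ_{αβ} density = α² [T_{·β}(r) × (r−R_I)]_α / |r−R_I|³.
The sign convention is fixed by physics: a diatropic ring current
(opposing the external field at the ring center) *shields* a nucleus it
encloses, so enclosed nuclei see positive densities; whether a flux
shields or deshields any other nucleus depends only on its direction
relative to that nucleus, not on its tropicity — the model tests encode
exactly this direction rule.

The |r−R_I|⁻³ kernel is integrable; atom-centered radial grids place no
node at r = 0, and any point within 10⁻¹⁰ bohr of R_I is excluded
(treated as zero) to be robust against user-supplied grids.

Positive/negative splits are taken pointwise on the quadrature
contributions w_i·v_i.  The split (unlike the total) is grid-dependent
at the level of the quadrature resolution of the sign boundaries; totals
always satisfy total = positive + negative exactly.

## Quadrature

* **Becke partitioning** with the iterated polynomial p(x) = (3x−x³)/2,
  iteration order k = 3 (the recommended value), Bragg–Slater radii and
  the heteronuclear cell-size adjustment a_ij clamped to |a| ≤ ½.  The
  size adjustment is ON by default because hydrogen radii visibly move
  the H/C domain boundary and hence the per-atom tables; a flag disables
  it.  Partition of unity holds to 10⁻¹² everywhere.
* **Radial grids**: trapezoidal rule on r = eˣ (geometric node ladder),
  the Lindh–Malmqvist–Gagliardi idea of a grid controlled by one
  accuracy parameter ε.  The step law h(ε) = 2.2/(−ln ε)^0.85 and the
  inner/outer cutoffs (r_min ∝ ε^⅓/√ζ_max, Gaussian-tail bound for
  r_max) were calibrated once against analytic ∫r²e^(−ζr²)dr over
  ζ ∈ [10⁻², 10⁴] with an order-of-magnitude safety margin.  When a
  basis is attached to the grid build, each atom's exponent range is
  taken from its own shells (padded ×2 both ways); otherwise generous
  per-element defaults are used.
* **Angular grids**: Lebedev rules of 6, 14, 26, 38 and 50 points
  (algebraic degrees 3–11) implemented from their closed-form orbit
  parameters — e.g. the 38-point rule's (p,q,0) orbit with
  q² = (1−3^(−½))/2 and weights 1/105, 9/280, 1/35 — each verified
  against exact sphere moments at build time of the test suite.  Higher
  degrees use Gauss–Legendre × trapezoid product rules, exact to any
  requested degree (default 29, comparable to a 302-point Lebedev
  grid).  Both families use the unit-measure convention (weights sum to
  1; ×4π at assembly).
* **Default production settings** (radial ε = 10⁻¹⁰, angular degree 29)
  give ~2×10⁴ points per atom on an aromatic ring — the scale customary
  for this kind of multicenter NMR quadrature — and reproduce the
  closed-form loop shielding to ~10⁻⁷ relative and the Lamb value to
  ~3×10⁻⁸ ppm.  Thin current tubes far from every grid center are the
  hard case; the loop reference calculation therefore places auxiliary
  quadrature centers on the ring, as the CLI's loop source does.

## Analytic models (the engine-free reference problems)

* **LoopModel**: toroidal current with Gaussian cross-section
  (normalized so the circulating current per unit field is the strength
  parameter), responding only to the field component along the loop
  normal.  Closed forms: center/on-axis thin-loop fields, and for finite
  width the superposition integral over thin loops, evaluated with
  150-point Gauss–Hermite quadrature (converged to ~10⁻¹³ relative;
  orbits with negative radius, mass ~e^(−½(R/w)²), are dropped).
* **VortexModel**: Larmor current −½ρ(r)(B̂×(r−C)) of a Gaussian 1s
  density; Lamb shielding (α²/3)·2√(2ζ/π) per electron at the center.
* **make_min_bundle**: 1–2 center s-type bundles with analytic overlap,
  the unit-test surface for the CDT expression.
* **benzene_like_composite**: perimeter diatropic loop (R = 3.9 bohr,
  width 0.9, strength 1.0), inner paratropic loop (R = 1.4, width 0.6,
  strength 0.35) and per-atom vortices (tight 2-electron ζ = 8 cores on
  C, ζ = 1.2 single-electron on H) on an idealized D6h ring (C–C 2.636,
  C–H 2.041 bohr).  The strengths were chosen once so that the ring
  currents perturb, but do not swamp, the on-site vortex shielding —
  the regime of a real aromatic molecule.  The model reproduces the
  qualitative sign topology of aromatic shielding-density maps (outer
  shielding band, inner-edge deshielding, near/remote asymmetry of the
  paratropic loop) and the localized character of the decomposition
  table.  It is for qualitative map and plumbing tests only and is
  never compared against ab initio numbers.

### What the synthetic fixtures do and do not show

The analytic providers exercise kernel, grids, decomposition, export and
sign conventions against exact answers, and the symbolic oracle proves
the CDT expression itself.  What they cannot exercise is the *input*
side of real applications: self-consistent response matrices in large
AO bases (hundreds of functions, high angular momenta, near-linear
dependence), the near-cancellation structure of real paramagnetic and
diamagnetic terms, or engine AO-ordering quirks.  Passing tests
therefore guarantee the machinery downstream of the bundle, not the
correctness of any particular engine adapter — each adapter must be
validated against its engine's analytic GIAO shieldings (the
`isotropic_shielding_ppm` metadata hook and the 0.1/0.5 ppm gates in the
acceptance suite exist for exactly that).  Those engine gates require an
external quantum-chemistry program and therefore fail in an environment
that has none.

## Numerical details and edge cases

* AO evaluation: real solid harmonics up to ℓ = 4 (g), generated
  symbolically once per ℓ and cached; no Condon–Shortley phase, m
  ordered −ℓ…ℓ, shells in input order.  Cartesian shells beyond p are
  rejected (adapters transform to the spherical dialect).  Points are
  processed in chunks (default 5000 for the CDT) to bound memory at
  ~2×10⁵-point production grids.
* Points coinciding with basis-function centers are evaluated normally
  (Gaussians are smooth); only the Biot–Savart nucleus has an exclusion
  radius.
* Bundle validation tolerances: density symmetry 10⁻¹⁰, perturbed
  density antisymmetry 10⁻⁸, tr(D·S) = n_electrons to 10⁻⁸.
* Decomposition percentages are computed from unrounded row totals;
  negative rows (and hence percentages) are legitimate and occur in
  antiaromatic systems.  A zero grand total flags percentages as
  undefined rather than dividing by zero.
* Cube files store raw (unclamped) values; display clamp ranges and
  suggested isovalues live in the header comment lines.  Plane CSVs
  store raw values; clamping applies only to the in-memory export
  channel.

## Known limitations

* Only the external-field route to the shielding (current induced by B,
  contracted with the nuclear-dipole vector potential) is implemented;
  the converse nucleus-induced-current route, spin–spin couplings and
  magnetizability maps are out of scope.
* No SCF/DFT/coupled-perturbed solver is included; responses always come
  from an engine (or from the analytic models).
* Lebedev rules above 50 points are not implemented (product rules stand
  in at equal algebraic degree but ~2× the point count).
* The positive/negative split and the Becke decomposition depend on the
  chosen partitioning (radii, k, size adjustment); these are physically
  meaningful conventions, not observables.
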