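# Methods

## Constitutive model

The annulus fibrosus is modelled with the Holzapfel–Gasser–Ogden (H-G-O)
anisotropic hyperelastic energy: an isotropic, nearly incompressible
Neo-Hookean ground substance plus two symmetric families of exponential,
tension-only collagen fibers. Per unit reference volume,

    U = C10 (Ī₁ − 3) + (1/D) ((J² − 1)/2 − ln J)
        + k₁/(2 k₂) Σ_α { exp[k₂ ⟨Ē_α⟩²] − 1 }
    Ē_α = κ (Ī₁ − 3) + (1 − 3κ) (Ī₄(αα) − 1)

The volumetric term is used exactly in this form; no alternative
volumetric splits are offered. The volume ratio J is the elastic volume
ratio — there is no swelling or thermal split, and osmotic pre-pressure
is out of scope. The Macaulay bracket ⟨x⟩ = max(x, 0) switches each fiber
family off in compression; the fiber stress vanishes continuously
(C¹) across Ē_α = 0 because the stress carries a factor ⟨Ē_α⟩.

Coordinate convention: axis 3 is the load axis (the spine axis); the
fiber unit vectors lie in the (axis-1, axis-3) plane at ±θ from axis 1,
i.e. θ is measured from the transverse plane, matching how the
inter-fiber angles are measured on MR sections (half the inter-fiber
angle per family). For the diagonal stretch states used here both
families share one pseudo-invariant, Ī₄ = J^(−2/3)(λ₁² cos²θ + λ₃² sin²θ).

### Parameters

| parameter | meaning | unit | default / range |
|---|---|---|---|
| C10 | matrix stiffness (μ₀/2) | MPa | fitted; E ∈ [0.1, 3] MPa |
| D | matrix compressibility (2/K₀) | MPa⁻¹ | tied to E via ν = 0.49 |
| k₁ | fiber stiffness | MPa | fitted on [1, 45] |
| k₂ | fiber non-linearity | — | fitted on [1, 2000] |
| κ | fiber dispersion | — | 0.01 (minimal dispersion) |
| θ | fiber angle from transverse plane | deg | measured; ≈ 28–30 |

ν = 0.49 (near-incompressibility) and κ = 0.01 are held fixed throughout,
as in the characterization protocol this package re-implements. The
conversions C10 = E/(4(1+ν)), D = 6(1−2ν)/E and their closed-form inverse
are exact inverses to machine precision.

## Virtual specimen tests

The physical tests load rectangular annulus blocks uniaxially. Away from
the grips the field is homogeneous, so the virtual test is a single
triaxial stretch diag(λ₁, λ₂, λ₃) with the transverse stretches solved
so that both transverse nominal stresses vanish — a traction-free
lateral surface. This homogeneous surrogate deliberately omits the
clamped-end constraint of a gripped specimen (and of mesh-based
simulations of one); its consequences are discussed under
*Identifiability* below. Nominal (engineering) stress and strain are
used throughout: stress is referred to the undeformed cross-section, and
strains at the interface are engineering strains ε = λ − 1.

Compression (strains 0.10, 0.15, 0.20, 0.25, 0.30) characterizes the
ground substance alone, so the virtual compression test simulates the
bare Neo-Hookean matrix. The fibers are not assumed inactive: if fiber
parameters are supplied, Ē_α is evaluated at every solved state and a
`fiber_activation` metadata flag reports whether the (near-incompressible)
transverse bulging would have stretched the shallow-angle fibers — which
it in fact does for the reference parameter sets. The flag exists
precisely because the common intuition "fibers are slack in compression"
fails for fibers at ~29° from the transverse plane.

Tension (strains 0.10–0.60) uses the full fiber-reinforced energy.
The reported specimen stiffness is the *final-chord tangent modulus*:
the slope of the chord through the last two points of the curve. (A
fitted tangent would be an alternative; the final chord is chosen as the
simplest deterministic definition and used consistently.)

### Numerics

The transverse equilibrium is a 2-unknown root problem per state. It is
solved by a damped Newton iteration on (λ₁, λ₂): analytic first
Piola–Kirchhoff stresses, a central-finite-difference Jacobian of those
analytic stresses, backtracking line search (halving, 12 trials), and a
residual tolerance of 1e−9 MPa on each transverse stress component.
Continuation in the axial strain (substeps of at most 0.02 engineering
strain, each started from the previous solution; identity at the start)
keeps the iterate on the physical branch even for the stiffest
exponential parameters. The solver is *batched*: all quantities
broadcast over numpy arrays, so a full factorial calibration grid
(thousands of parameter sets) is solved simultaneously in a handful of
vectorized iterations. Non-converged batch entries are flagged and
propagate as `inf` objectives in calibration or `failed` records in the
sensitivity sweep, never as silent numbers. Fiber exponents
k₂⟨Ē⟩² > 700 are treated as numeric overflow.

Correctness is anchored by two independent oracles, both in the test
suite and in `scripts/acceptance.py`: (1) the axial nominal stress equals
the central finite difference of the relaxed (transverse-equilibrated)
energy to better than 1e−5 relative over λ ∈ [0.7, 1.6] for all reference
parameter sets (the envelope theorem makes these identical at the exact
equilibrium); (2) a symbolic (sympy) term-by-term evaluation of the
energy at a solved state. The near-incompressible Neo-Hookean solution
also lands within 3% of the incompressible closed form μ₀(λ − λ⁻²) at
λ = 1.1.

## Calibration

Both stages are exhaustive grid searches minimizing the mean squared
stress error at the protocol strain levels only (5 compression / 6
tension points, matching the displacement-controlled protocol; no curve
resampling). Defaults: E from 0.1 to 3.0 MPa in steps of 0.01; k₁ from
1 to 45 MPa in steps of 1; k₂ from 50 to 2000 in steps of 30. The grids
are config-driven; the defaults are chosen for density comparable to a
few-thousand-run factorial design. Ties break toward the smallest
parameter values (softest material) — deterministic and conservative.
The full trace of every evaluated combination is retained, and a
boundary flag marks optima on a grid edge rather than silently accepting
them (the posterior fiber fit, k₁ = 1, sits on the stated lower bound).
R² between observed and best-fit stresses is reported per stage; the
target curves are taken as nominal stress (whether the literature
compression curves are nominal or true stress is not stated there;
nominal is assumed consistently).

## Synthetic data

The generator produces exactly what the analysis consumes: forward
curves from any material parameter set at the protocol strain levels,
optionally with multiplicative Gaussian noise (stress × (1 + e),
e ~ N(0, σ²) clipped at −0.9; relative noise because the experimental
scatter grows with stress level), default σ = 0.05; Gaussian fiber-angle
samples rejection-resampled into (0, 90)°; and a bundled fixture of the
published regional parameter table, median tensile yield anchors
(2.85 MPa at 0.5 strain anterior; 1.95 and 2.06 MPa at 0.6 lateral /
posterior), fiber-angle statistics (29° ± 3.9, 30° ± 4.0, 28° ± 4.1),
and fitted ground moduli (0.38, 0.26, 0.46 MPa). The sample size behind
the published angle SDs is not recoverable, so the generator exposes n.

What the generator does *not* emulate: specimen-to-specimen geometric
variability, clamped-end field inhomogeneity, rate effects, and the
median-over-specimens construction of the experimental curves. Passing
recovery tests therefore demonstrate that the estimator inverts the
package's own forward model under realistic noise — not that it would
recover parameters from gripped-specimen data with edge effects.

An importer for the optional supplementary spreadsheet (sheets
'Little data', 'Anterior', 'Lateral', 'Posterior') is provided; tests
exercise it on a synthetic workbook with the same layout, and the
goodness-of-fit check (R² > 0.8 per region) runs against synthetic
convex compression curves standing in for the experimental ones.

Note on the published parameter table: the posterior row is
self-consistent with its fitted modulus (C10 = 0.077, D = 0.261 ↔
E = 0.46 MPa at ν = 0.49), but the anterior and lateral rows are not
(E = 0.38 MPa converts to C10 = 0.0638, not 0.061; the lateral row
inverts to E ≈ 0.197, not 0.26). This package reproduces the equations;
the bundled fixtures carry the published values verbatim.

## Sensitivity sweep

Full factorial over (E, k₁, k₂): four levels each, 64 combinations.
Level placement inside the studied ranges: linear for E ∈ [0.1, 1] MPa
and k₁ ∈ [1, 45] MPa; geometric for k₂ ∈ [1, 2000] (three orders of
magnitude). θ defaults to 29°. Outputs are specimen-level — tensile
stresses at the protocol strains, final-chord tangent modulus,
compressive stress at 0.30 strain — summarized as per-level quartiles
for box plots. Disc-level ranges of motion and sectional stresses are
*not* computed (they require a reconstructed 3-D disc geometry, out of
scope); the sweep verifies the direction of each parameter's influence —
stiffness non-decreasing in each of E, k₁, k₂ along every lattice line —
not disc-level magnitudes.

## Identifiability limits

Under the traction-free homogeneous surrogate, fibers at ~29° from the
transverse plane engage only late in the tension test: the transverse
contraction shortens the dominant (transverse) fiber component, so
Ī₄ < 1 until λ ≈ 1.25, and the fiber term carries at most ~11% of the
axial stress at 0.6 strain even for the stiffest (anterior) reference
set. Two consequences:

1. Tension curves are much softer than gripped-specimen measurements,
   whose clamped ends hold the transverse stretch near 1 and load the
   fibers from the start. Specimen-level tangent moduli computed here
   are therefore not comparable to gripped-test values.
2. (k₁, k₂) are exactly recoverable from noise-free on-grid curves, but
   under any realistic noise they are *jointly unidentifiable at
   fine grid resolution*: the two parameters trade off along a nearly
   flat ridge of the MSE surface (a well-known collinearity of the
   exponential fiber law), and a one-grid-step perturbation
   (Δk₂/k₂ ≈ 2%) changes the predicted curve by well under 0.1%.
   Measured: with 5% multiplicative noise, 0 of 20 seeded replicates
   land within one grid step of the truth — and still 0 of 20 at 0.1%
   noise. The matrix stage is unaffected (E recovers within one 0.02 MPa
   step in ≥ 80% of replicates at 5% noise). The corresponding
   fiber-recovery check is left failing by design rather than weakened;
   `fiber_noisy_recovery_pct` in the acceptance output reports the
   measured rate.

## Fiber-angle statistics

Mean and sample SD (n−1 denominator; the denominator convention is a
package choice), the fraction of measurements within two SDs of the mean
(defined as 1.0 for zero-spread samples), and the D'Agostino–Pearson
skewness–kurtosis omnibus normality test at α = 0.05 (the protocol this
re-implements names no specific test; the omnibus test is this package's
documented choice, requiring n ≥ 8; smaller or degenerate samples return
an "inconclusive" verdict, not an error). Angles are degrees externally
and radians internally.

## Problem sizes

Default test-suite and acceptance runs use the full default grids
(291-point E sweep, 45 × 66 fiber lattice, 64-combination sweep, 20-seed
noise replicates, 5000-draw angle samples); the batched solver evaluates
the largest of these in well under a minute on one core.
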