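# Methods

## Scope and model

The package implements the TG-43U1 two-dimensional dose-rate factorization
for cylindrically symmetric low-energy seeds,

D(r,θ) = S_K · Λ · [G_L(r,θ)/G_L(r₀,θ₀)] · g(r) · F(r,θ),  r₀ = 1 cm, θ₀ = 90°,

together with its inverse: given a polar dose-rate grid D(r,θ), the radial
dose function and anisotropy function are extracted by dividing out the
geometry function,

g(r) = [D(r,θ₀)/D(r₀,θ₀)]·[G(r₀,θ₀)/G(r,θ₀)],
F(r,θ) = [D(r,θ)/D(r,θ₀)]·[G(r,θ₀)/G(r,θ)].

Assumptions: the source is cylindrically symmetric and mirror-symmetric
about the transverse plane (folding of full-revolution measurement angles
onto [0°, 90°] averages the up-to-four images of each quadrant angle with
equal weights); dose equals kerma at the photon energies involved (≈20 keV,
electron ranges ≪ voxel sizes); and the activity is uniform along the
active length for the line geometry function.

## Geometry function

G_P(r,θ) = r⁻² for the point model.  For the line model of active length L,
β is the angle subtended by the source segment at the field point.  We
evaluate it as a single two-argument arctangent of the cross and dot
products of the end-point vectors,

β = atan2(L·r·sinθ, r² − L²/4),

which is algebraically identical to the difference of end-point arctangents
for every field point outside the source extent, handles obtuse geometries
(r·cosθ < L/2; the dot product goes negative and atan2 returns β > π/2)
without branch logic, and — unlike the difference form — keeps full
relative precision as β → 0.  That matters for the point-source limit:
at L = 10⁻⁶ cm the difference form already carries ~10⁻⁸ cancellation
error, while this form agrees with r⁻² to machine precision.

On the long axis (|sinθ| < 10⁻⁶) the limiting value 1/(r² − L²/4) is used;
the printed convention that the line-source expression is zero exactly on
the axis would make F(r, 0°) undefined even though anisotropy tables
tabulate 0°, so the standard limiting form is adopted.  Axial queries with
r ≤ L/2 (inside the source extent) are domain errors.

The closed form is verified against an independent brute-force quadrature
oracle — a uniform line of inverse-square emitters integrated with
adaptive quadrature — to 10⁻⁶ relative over r ∈ [0.25, 5] cm,
θ ∈ [1°, 179°].

## Extraction, interpolation, reconstruction

Extraction normalizes exactly: g is set to 1 at the reference radius when
tabulated (linear interpolation of the transverse dose supplies D(r₀,θ₀)
otherwise), and the 90° column of F is set to 1 identically.  Both
operations are invariant under any positive rescaling of the grid.

Interpolation of tabulated functions is linear in r for g(r) and bilinear
on the (r,θ) lattice for F (implemented as nested 1-D linear passes, so
lattice nodes evaluate exactly and mid-points obey the arithmetic-mean
rule).  Queries outside the tabulated range raise an error — the package
never extrapolates silently, because low-energy dose gradients make
extrapolation quietly wrong.

Forward reconstruction composed with extraction is the identity on lattice
points of any positive grid (floating tolerance 10⁻⁹ relative); this is a
structural identity of the factorization, independent of the kernel, and
is tested as such.

## Air-kerma strength and dose-rate constant

S_K is the unweighted mean of K̇_δ(r)·r² over the profile distances, with
per-distance diagnostics; a profile whose estimates spread more than a
configurable tolerance (default 1%, relative deviation from the mean) is
flagged as not distance-independent rather than rejected.  For a finite
line in vacuum K̇·r² = atan(u)/u with u = L/2r, so the estimates rise
monotonically to the asymptote; at 150 cm the deviation is ≈ u²/3 ≈ 3·10⁻⁷
for L = 3 mm.  Λ = D(1 cm, 90°)/S_K, and the consensus value for a seed
model is the plain average of the experimental and Monte Carlo values —
no literature-weighting scheme is applied.

The fifth-order polynomial model of g(r) is an ordinary least-squares fit
on the raw (r, g) pairs; R² = 1 − SS_res/SS_tot with SS_tot about the mean
of the g values.  For exactly constant data SS_tot = 0 and R² is reported
as 1 (the constant is the least-squares minimizer).

## TLD reduction

Per chip: subtract the arithmetic mean of the background chips, divide by
the chip's sensitivity factor (reading over batch mean from a uniform
Co-60 irradiation), then divide by t_eff · S_K · ε_λ · E(r,θ).  The
effective exposure time t_eff = (1 − e^(−λT))/λ is the decay-weighted
integral converting an integrated reading from a decaying source into an
initial dose rate; it reduces to T for λT ≪ 1 (0.99915 h for a 1 h
exposure with a 17 d half-life).  The Pd-103 half-life default is
16.991 d, overridable.

Corrected readings below zero are clamped to zero with a warning, not an
error: chips near background at 5 cm are an expected feature of the
measurement, not a fault.  E(r,θ) defaults to 1 everywhere when no
energy-response table is supplied; a partial table is a calibration error
when queried at a missing position.

Replicate chips at one position are averaged.  The reported type-A
uncertainty is the *relative sample standard deviation of a single
reading* (k = 1), i.e. SD/mean·100 over the replicates — the per-reading
dispersion a dosimetrist quotes as %u_A(k=1) — rather than the standard
error of the position mean; the SEM is recoverable as type_a/√n.  Type-A
and type-B components combine as the square root of the sum of squares.

## Synthetic generator

The generator emulates the *structure* of transport tallies and phantom
readings, not their physics.  Kernel:

D(r,θ) = S · c · G(r,θ) · A(r) · f(θ)

- A(r) = e^(−μr)·(1 + b₁·μr·e^(−b₂·μr)); defaults μ = 0.45 cm⁻¹,
  (b₁, b₂) = (9, 10), chosen once so the implied g(r) falls from ≈1.45 at
  0.5 cm to ≈0.16 at 5 cm — the characteristic Pd-103 falloff scale.
- f(θ) = e^(−μTi·t(θ)) with a smooth monotone effective path
  t(θ) = w + (t_cap − w)·|cosθ|³ between the side-wall thickness w
  (0.05 mm) and the end-cap thickness (0.6 mm).  A literal straight-ray
  slab path t_cap/|cosθ| would *increase* with obliquity inside the cap
  region and make F non-monotone near the axis; the smooth form preserves
  the defining qualitative behaviour (F rising monotonically from ≈0.2 at
  0° to 1 at 90°) while staying tied to the capsule dimensions.
  μTi = 29 cm⁻¹ is an effective coefficient folding bead self-absorption
  into the cap term (titanium alone at 20.7 keV is ≈21 cm⁻¹).
- G is the line-source geometry function; an optional five-bead discrete
  mode replaces it with the mean inverse-square sum over equally active
  bead centers, for probing line-vs-discrete differences.
- c is fixed by the configured reference dose-rate constant
  (default 0.690 cGy·h⁻¹·U⁻¹): c = Λ_ref/(G(1,90°)·A(1)·f(90°)), so
  Λ_true is exact by construction.  Ring-kerma profiles carry no medium or
  capsule factor (vacuum, δ = 5 keV cutoff recorded), so S_K,true = S.

Noise is multiplicative lognormal with mean 1 (dose tallies and TLD
readings are positive); grids default to σ = 1% (typical tally precision),
TLD readings to σ = 2.9% per chip, the type-A dispersion of the
measurement design this emulates.  The TLD layout defaults to the radial
spiral phantom: four chips at each of r = 0.5, 1, 1.5, 2, 3, 4, 5 cm on
the transverse axis, with four background chips; the anisotropy phantom
lattice (r = 1.5, 2, 3, 5 cm; 0°–330° in 30° steps) and the simulation
lattice (r = 0.25–5 cm; 0°–90° in 10° steps) ship as constants.  All
outputs are reproducible from (config, seed).

What passing tests do *not* show: agreement with real transport physics
(no spectrum, no scatter kernels, no cross-sections), realistic covariance
between neighbouring tally cells (noise is independent per cell), TLD
glow-curve or annealing effects, or phantom-to-water medium conversion.
Tests against the generator validate the *analysis chain*, not the seed.

## Packaged data and precision conventions

The packaged IR06-type seed dataset stores the dose-rate constants
(TLD 0.689 ± 0.058, Monte Carlo 0.691 ± 0.021 in the phantom medium,
0.692 ± 0.021 in water; consensus 0.690), three g(r) determinations, the
dense Monte Carlo F lattice, and the sparse TLD-measured F values — kept
as a separate table because the two methods have different angular support
(measured angles 0°, 30°, 60° only).  Reports render g/F at 3 decimals and
Λ at 3 significant figures; data files keep full precision and round-trip
bit-identically through the YAML schema.  The polynomial-fit report uses
the Monte Carlo phantom-medium g(r) column, the determination the packaged
fit coefficients derive from.  Relative differences in comparison reports
use the published value as denominator.

## Problem sizes

All computations are closed-form or small linear algebra; the statistical
recovery checks use 50 seeded synthetic experiments (28 chips each) and an
8×10 polar lattice, which characterize the estimator dispersion to a few
percent while keeping the full suite under a few seconds.
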