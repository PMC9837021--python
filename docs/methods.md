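# Methods

`fibermech` predicts the axial Young's modulus `E_fib` and the axial
tensile elastic limit `Σ_ult` of technical plant fibers from their
physicochemical composition, by continuum-micromechanics upscaling of the
intrinsic properties of the cell-wall constituents — most importantly the
crystalline cellulose nanofibril (axial modulus 167.8 GPa, axial tensile
strength 2.3 GPa).

## Multiscale representation

Four representative volume elements (RVEs) on three length scales:

1. **Polymer network** (tens of nm): hemicellulose, lignin, pectin, ash
   and extractive nanopores (modeled as empty) as spherical, isotropic,
   mutually interacting phases → *self-consistent scheme*.
2. **Cellulose microfibril**: crystalline nanofibrils as infinitely long
   aligned cylinders in an amorphous-cellulose matrix → *Mori–Tanaka*.
   The nanofibril stiffness is transversely isotropic with the printed
   zero Poisson-coupling convention; all tensor algebra uses the 6×6
   Kelvin–Mandel representation (order 11, 22, 33, 23, 13, 12; √2 weights
   on mixed components), in which contraction, inversion and orthogonal
   frame rotation are plain matrix operations.
3. **Cell wall** (µm): microfibrils tilted by the microfibril angle ϑ off
   the fiber axis and uniformly distributed in azimuth φ, embedded in the
   polymer network → *azimuthally averaged Mori–Tanaka*. The full
   inclusion problem is rotated (stiffness and Hill tensor jointly); the
   φ-integrals are N-point trapezoid sums.
4. **Technical fiber** (tens of µm): cylindrical lumen voids along the
   fiber axis in a cell-wall matrix → *Mori–Tanaka with voids*.

`E_fib = 1/D_fib,LLLL` from the fiber compliance. The elastic limit
downscales a unit macroscopic axial stress through the cached strain
concentration operators to the nanofibril's axial (fibril-frame) stress
σ_NF,ll and exploits linearity: `Σ_ult = σ_ult_NF / σ_NF,ll(Σ=1)`. The
azimuth-independence of σ_NF,ll is asserted at run time (1e-6 relative)
rather than assumed; transverse and shear nanofibril stresses are computed
but do not enter the brittle failure criterion.

## Hill polarization tensors

Hill tensors are evaluated numerically from the Green-operator surface
integral: spheres by a Gauss–Legendre × trapezoid product rule over the
unit sphere of wave normals (default 16×32, with automatic order doubling
until the result changes by less than 1e-8 relative — strongly anisotropic
references such as the cell wall need finer grids than isotropic ones);
infinite cylinders by the exact aspect-ratio limit, a 256-point trapezoid
line integral over the normals perpendicular to the cylinder axis
(spectrally convergent; machine precision already at 128 points). The
test suite validates both against the classical isotropic Eshelby closed
forms (sphere volumetric/deviatoric projections, vanishing axial row for
the infinite cylinder, plane-strain transverse components) to 1e-6.

## Composition pipeline

Raw literature records (mass fractions of total cellulose, hemicellulose,
lignin, pectin, ash, nanopores; volumetric crystallinity ξ_V; microfibril
angle ϑ; fiber density ρ_fib, each as min/avg/max triples) are converted
to model inputs:

* masses normalized to 100 % (proportional down-scaling above 100;
  deficits counted as extractive nanoporosity),
* ξ_V converted to the mass-based index ξ_M via the amorphous/crystalline
  density ratio 1.50/1.59, splitting total cellulose,
* masses → volumes via phase densities, renormalized,
* lumen porosity back-calculated as `1 − ρ_fib/ρ_cw`, clamped to [0, 1),
  with the cell-wall density ρ_cw always evaluated from the
  *average*-composition volume fractions.

**Scenarios.** The favorable ("max") scenario combines the reported
maximum cellulose mass and crystallinity — but at least 5 percentage
points above the average — with the minimum microfibril angle and maximum
fiber density; non-cellulose masses are rescaled proportionally to keep
the total at 100 %. The unfavorable scenario mirrors this. Fallbacks
where only an average is reported: ±3° on the angle, ±10 % on the
density, the average itself for mass fractions. The 5-pp shifts operate
on the *normalized* average cellulose mass; this reproduces the derived
literature volume-fraction table cell-for-cell within the 1-pp printed
rounding.

## Numerical choices

| knob | default | rationale |
|---|---|---|
| azimuth points `n_azimuth` | 72 | periodic smooth integrand; doubling changes E_fib by < 1e-6 for every fiber |
| SC tolerance / cap | 1e-10 / 500 | plain fixed-point from the Voigt start converges in tens of iterations at these phase contrasts; the fixed point is start-independent to 1e-8 |
| `eq11_denominator` | `standard_mt` | the bare concentration tensors in the orientation-average normalizer; the alternative `as_printed` keeps the inclusion stiffness inside the bracket, which is dimensionally inconsistent and collapses all moduli to ~1 GPa — kept only as a switch for comparison |
| pectin shear modulus | 3.47 GPa | derived from k = 10.4 GPa and an assumed Poisson ratio 0.35, the same convention used for the other amorphous polymers; configurable |
| `sigma_ult_NF` | 2300 MPa | sonication-derived wood nanofibril strength, taken as plant-independent |

Mori–Tanaka estimates with anisotropic, non-aligned phases are not
exactly major-symmetric; each homogenized stiffness is symmetrized
(C ← (C+Cᵀ)/2) and the pre-symmetrization asymmetry is logged. Across
the packaged database it stays below 5 % relative (largest for fibers
with microfibril angles near 20° and high stiffness contrast, e.g.
isora; well below 1 % for near-axial bast fibers). Degenerate inputs: an all-void polymer
network, unit lumen porosity and a singular fiber stiffness raise errors;
a fiber with *no* polymer network (the degenerate all-cellulose anchor)
skips the self-consistent step and collapses the chain exactly onto the
nanofibril properties.

## Synthetic records

`composition.random_fiber_record` draws physically valid but fictitious
fiber records (renormalized uniform masses, crystallinity 20–100 %, angle
0–50°, density below the implied cell-wall density) for property-based
tests. It emulates only the *structure* of literature records — value
ranges and ordering of the min/avg/max triples — not the correlations of
real plants (e.g. bast fibers pairing high cellulose with low angle), so
passing property tests demonstrates robustness of the pipeline over the
valid input domain, not predictive accuracy for any real species.

## Known limitations and model behavior

* **High microfibril angles.** The predicted elastic limit decreases with
  ϑ only up to roughly 30–35°; beyond that it *rises* again, because the
  axial modulus (and with it the macroscopic strain per unit stress)
  degrades faster than the resolved fibril-axis stress grows. The axial
  nanofibril stress concentration is bounded by the resolved cell-wall
  strain along the fibril times the nanofibril axial stiffness, which
  caps it near 9 for a 45°-angle fiber — so ever-lower strengths at high
  angles are not reachable under the axial-fibril-failure criterion. In
  the packaged database this affects exactly coir and oil palm (the only
  fibers whose reported angle intervals lie above 30°): their strength is
  *not* monotone in ϑ, and coir's favorable scenario has a slightly lower
  elastic limit than its unfavorable one. Physically, fibril-bridging
  matrix shear failure (not modeled) would be expected to govern in this
  regime.
* Only the axial modulus and the axial tensile elastic limit are
  validated; shear and transverse moduli are computed but uncorroborated.
* Elastic limit = strength by the elasto-brittle assumption; no fracture
  mechanics, no statistical (Weibull) size effects.
* Dry-matter properties only: no moisture, poromechanics or viscoelastic
  effects; the cell wall is a single homogeneous layer (no S1/S2/S3
  resolution).
* Literature min/max columns combine independent sources; occasional
  1-pp inconsistencies in the printed derived tables are tolerated in the
  regression tests rather than reverse-engineered.
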