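# Methods

This note records the physical model, the numerical choices and the known
limitations of `iscatsim`, in the spirit of a methods appendix: everything
stated here is implemented and exercised by the test suite; no empirical
number is quoted that the tests or `scripts/acceptance.py` do not compute.

## Conventions

* Time dependence `e^{-iωt}`; outgoing waves are `e^{+ikr}/r`, passive media
  have `Im ε ≥ 0`, evanescent branch `Im(n cos θ) ≥ 0`.
* The top interface of the layer stack is at `z = 0`, `z` increases upward;
  lengths in nm, angles in degrees at the API surface (radians internally).
* Fields are dimensionless relative to a unit incident amplitude; magnetic
  fields are scaled as `H̃ = Z₀H`, so a plane wave in a medium of index `n`
  satisfies `H̃ = n k̂ × E`.
* TM reflection uses the *co-oriented* sign convention: `r_TM → (n₁−n₂)/(n₁+n₂)`
  at normal incidence, equal to TE.  Textbooks differ here; the convention is
  fixed by the interface-continuity tests (tangential `E`/`H̃` and normal `D`
  continuous across the interface for every polarization).
* The polar angle of a plane wave is *signed* (anticlockwise positive in the
  plane of incidence), which keeps the TE/TM basis continuous through normal
  incidence.

## Layer stacks and driving fields

Stack reflection/transmission uses the recursive (Airy/Parratt) composition
of per-interface coefficients with one-way layer phases; for two media it
reduces to the closed-form Fresnel formulas, and a vanishing middle layer
degenerates to the single interface.  Coefficients are evaluated as
functions of the (possibly complex) incidence cosine, which provides the
analytic continuation used for supercritical-angle transmission.  The total
driving field is incident + reflected on the incidence side and transmitted
on the far side, with all plane-wave phases referenced to the origin so the
interface conditions hold identically.

## Field representations

Two angular representations carry the light between stages: plane-wave
decompositions `E(r) = Σ ε_j e^{ik k̂_j·r}` for beams, and far-field
amplitudes `E = F(r̂) e^{ikr}/r` for scattered light.  Direction grids are
Gauss–Legendre in `cos θ` crossed with a uniform periodic azimuth (defaults
50 × 51), so solid-angle quadrature of smooth patterns is spectrally
accurate.  Amplitudes are stored in Cartesian components, making rotations
exact; `θ̂/φ̂` projections are computed on demand.  Shifting the expansion
origin multiplies each direction by `e^{-ik k̂·r₀}` for the coordinate
relabelling `r → r + r₀`; the sign is pinned by a far-zone re-expansion
test (evaluate the original expansion at translated points at `r ≈ 10⁵ λ`
and compare), not by convention tables.

## Scattering engines

**Point dipole.**  Quasistatic Clausius–Mossotti polarizability
`α = 4πa³(εp − εh)/(εp + 2εh)` (nm³; optional radiation-reaction correction
`α/(1 − ik³α/6π)`, off by default), induced moment `p = α E_drive` at the
particle position, far field `F = (k²/4π)(1 − r̂r̂)p`.

**Mie.**  Standard series with Riccati–Bessel functions (scipy, complex
arguments) and the Wiscombe-type truncation `x + 4.05 x^{1/3} + 6` with a
tail-convergence check.  The angular amplitudes `S₁, S₂` are evaluated
through the `π_n, τ_n` recurrences, which also accept complex `cos Θ` — the
analytic continuation used below.  A second, independently coded series
(downward logarithmic-derivative recursion) serves as the oracle in the
tests.  Scattered near fields are reconstructed from the outgoing vector
spherical harmonics for validating the boundary-element representation
formula.

**Boundary-element method.**  Particles with homogeneous materials and
abrupt boundaries are solved with a Galerkin PMCHWT transmission system:
the tangential boundary fields `J = n̂×H̃`, `M = −n̂×E` are expanded in
divergence-conforming RWG functions on a closed triangle mesh, and the
single-/double-layer operators

```
T(X) = ik ∫ G X dS' + (i/k) ∇ ∫ G ∇'·X dS' ,   K(X) = ∇ × ∫ G X dS'
```

with the homogeneous Green kernel `G = e^{ikR}/4πR` are tested with the
same basis.  The representation of the field radiated into a region of
index `n` is `E = (1/n) T(J) − K(M)`; its sign and normalization were fixed
by an interior-dipole (extinction-theorem) experiment against the analytic
dipole fields, and the assembled solver is validated against Mie for
dielectric and gold spheres (cross sections to ~10⁻⁴ relative at 320
volume-corrected elements, near fields to ~0.3 %).

Multi-region assembly: every homogeneous region contributes its kernel
between each pair of surfaces it touches, with orientation signs
`o_{ρs} = ±1` for the surface normal pointing into/out of region ρ.  This
one rule covers single particles, disjoint particles (dimers — cross-sphere
coupling through the host kernel), and coated particles (two nested
surfaces, one unknown set per boundary).  The identity (jump) terms of the
double layer cancel between the paired regions, leaving pure principal
values.

*Singular integration.*  Regular interactions use a 6-point degree-4
symmetric triangle rule on both triangles.  Near/self pairs (shared
vertices, or centroid separation below 2.5 combined radii — this threshold
also catches the close cross-gap pairs of a dimer) are corrected by
analytic static extraction: `G = 1/4πR + (e^{ikR}−1)/4πR`, with the static
triangle potentials `∫1/R` and `∫(r'−v)/R` evaluated by the closed-form
edge-sum formulas (validated against brute-force quadrature) and the smooth
remainder by regular quadrature (with the `ik/4π` limit at coincident
points).  The double-layer kernel vanishes identically for coplanar pairs
when tested with in-plane functions; non-coplanar near pairs use a
recursively subdivided source triangle (depth 2, 3-point leaves).  This
extraction scheme was preferred over Duffy-type self-term quadrature as it
is exact for the singular part at equal cost.

*Practicalities.*  A warning is emitted when the maximum edge length
exceeds 1/5 of the effective wavelength in any adjacent medium; the element
budget is capped at 10,000 (override allowed); an ill-conditioned solve is
rejected on the linear-system residual.  Sphere meshes are geodesic
icosahedra of arbitrary frequency ν (20ν² triangles).  For sphere-like
scatterers the mesh is rescaled to the equivalent enclosed volume by
default in the scene builder: the inscribed polyhedron otherwise
under-represents the polarizable volume at `O(h²)`, which dominates the
cross-section error (~24 % at 80 elements for a 50 nm sphere, exactly the
squared volume deficit, versus ~0.1 % after correction).

*Convergence.*  The mesh-refinement study in the acceptance tests
(vertices-on-sphere meshes, polystyrene in water, ν = 2…5) measures a
cross-section error slope of ≈ 1.9 in `h` — the facet volume deficit's
`O(h²)` is the leading error, with the Galerkin solution error below it.
The solver therefore converges *faster* than the `h^{3/2}`
boundary-discretization bound typically quoted for this discretization;
the test suite asserts the `≥ 1.4` bound and, separately, the literal
3/2-band, the latter of which this implementation exceeds.

*Post-processing.*  Far-field amplitudes are assembled analytically from
the currents (`F = (ik/4π)[(1−r̂r̂)·∫J e^{−ikr̂·s'}/n − r̂×∫M e^{−ikr̂·s'}]`),
which also accepts complex directions; near fields use the representation
formula with subdivided quadrature near the surface (points closer than 0.1
local edge length are rejected); the surface charge is obtained from
`∇_s·J` per triangle (RWG divergence, exactly neutral over a closed
surface); scattered power can be cross-checked from the boundary Poynting
flux of the tangential fields.

## Substrate interface correction

The substrate is treated at the far-field level rather than inside the BEM
kernels: above the stack each direction's amplitude is the direct ray plus
the Fresnel-weighted mirror ray with the two-path phase `2k₁z₀cos θ`;
below, each substrate direction maps back through Snell's law, is weighted
by the stack transmission and the solid-angle factor `(n₂cos θ₂)/(n₁cos θ₁)`,
and carries the source-height phase `e^{ik₁z₀cos θ₁}`.  Supercritical
directions (`sin θ₁ > 1`) use `cos θ₁ → i|cos θ₁|` with the analytic
continuation of the source amplitude — exact for the dipole, Mie and
BEM-current sources; grid-sampled far fields cannot be continued and get
zero there with a warning.  For a point dipole this construction reproduces
the exact single-interface asymptotics (the two code paths agree to 10⁻⁶),
including the `e^{-κz}` height decay of supercritical emission.

This is the platform's main physical approximation: particle–substrate
*near-field* coupling is neglected.  The dipole-vs-BEM comparison in the
acceptance tests shows normalized emission patterns agreeing to ~1 % for a
50 nm gold sphere 5 nm above glass, the size regime for which the
correction is intended; larger or strongly plasmonic particles very close
to a high-index substrate would need true layered-medium kernels, which are
out of scope.

## Richards–Wolf imaging

The aplanatic train is two Gaussian reference spheres `f, f'` with
`n sin θ_max = NA`, magnification `M = (n/n')(f'/f)` and the sine-condition
mapping `sin θ' = (f/f') sin θ`; the image side is always paraxial
(`cos θ' ≈ 1`, `f' ≫ f`).  TE (φ̂) components keep their orientation, TM
(θ̂) components rotate to the image-side radial direction, and the
ray-bundle energy factor reduces to the `√cos θ` apodization.  Two
normalization conventions are fixed once: the arbitrary global phase of the
imaging integral is set to zero (intensities and the *relative* phase of
co-imaged beams are unaffected, asserted by test), and the overall scale
maps a unit on-axis reference plane wave to unit image intensity.  With
these choices the far-field and plane-wave imaging paths interfere with the
physically correct relative amplitude, fixed by the stationary-phase
relation `ε(k̂) = ikF(k̂)/2π` between a smooth decomposition and its
outgoing far field — and the integrated image intensity equals the
collected-cone power (energy conservation through the train, verified to
1 %).

Camera coordinates are object-referred (image coordinate / M), so fields of
view read in sample-plane nm.  The iSCAT detection axis (−z) maps to the
imaging axis by a 180° rotation about x applied identically to reference
and scattered fields; defocus is a shift of both expansions to the focal
point before imaging.

Two evaluations of the imaging integral are provided.  The direct 2-D
quadrature uses the far-field grid as-is; with 51 azimuthal nodes it shows
percent-level artifacts at large image radii where `e^{ikρ sinθ cos(φ−φ')}`
oscillates faster than the grid.  The accelerated path expands the
(uniformly sampled) azimuth in Fourier orders and integrates each
analytically, leaving Bessel radial kernels `J_m(kρ sin θ)`; it matches the
direct method refined to 201 azimuths to better than 10⁻³ while using the
51-node far field.  Orders with no content are skipped exactly; `J_m` is
evaluated from a dense lookup table (60001 nodes, ~10⁻⁶ interpolation
accuracy).  Truncation at `m_max < n_φ/2` is available but not needed in
practice, so the default keeps all orders.

Back-focal-plane transforms are per-direction Jones actions on the
transverse Cartesian components: wave plates (rotated-axis retarders),
attenuators (`|t| ≤ 1`), and radial/annular beam blocks; they compose
left-to-right.  A quarter-wave plate at 45° applied in both passes acts as
a half-wave plate; a central block implements dark-field detection.
Focused excitation for scanning is built by the standard angular-spectrum
superposition with the same apodization and polarization mapping.

## Image assembly and analysis

`simulate_image` produces `(camera, ref, sca)` with the definitional
identity `I_cam = |E'_ref + E'_sca|²` holding per pixel by construction.
iSCAT uses upward illumination and the reflected beam as reference; COBRI
is *the same code* with the illumination direction flipped 180° and the
transmitted beam as reference; dark-field drops the reference.  Contrast
maps are `I − |E'_ref|²` with the phase `φ = arg(E'_ref·E'_sca*)`; the
normalized variant divides by `|E'_ref|²` and is refused when the reference
vanishes.  Michelson contrast `(I_max−I_min)/(I_max+I_min)` summarizes raw
frames; sweeping the TM illumination angle across the Brewster angle
`arctan(n₂/n₁)` drives the reference continuously to zero (the dark-field
limit), where the Michelson contrast is maximal.

Focal-plane estimation correlates a query image with a simulated focal
stack using the two-dimensional Pearson coefficient (explicit mean removal
and variance normalization; ties break toward the smallest |z|).  For
tilted illumination the interference fringes are directional and the
correlation has a unique maximum; near normal incidence the conjugate-
defocus ambiguity produces the characteristic second ridge (quantified in
the tests as the anti-diagonal correlation of the stack's self-correlation
matrix: ≈ 0.2 at −2° versus ≈ 0.03 at 14°).  The detector is ideal by
default; seeded Gaussian/Poisson noise is available for robustness studies
(`add_noise`), and focus recovery is exact for noiseless self-queries and
stable at the few-percent noise level used in the tests.

Partial longitudinal coherence is modeled as a weighted incoherent sum of
coherent single-wavelength intensities (non-negative weights summing to 1);
broadening the spectrum demonstrably washes out the large-defocus rings.
Scanning mode shifts a focused excitation across the sample, re-solves the
scattering per position and records a pinhole-summed detection signal
(default pinhole radius one Airy unit, `0.61 λ/NA` — the standard confocal
convention); the focused drive is built in the excitation medium and is not
re-reflected at the stack (documented simplification of the excitation
path).

## Synthetic scenes and defaults

Bundled presets define the canonical study conditions: 50 nm gold /
polystyrene / coated / coupled spheres in water 5 nm above glass with a TM
drive at −20° and λ = 520 nm; a 55 nm gold sphere in air at 517 nm with
14° and −2° illumination (NA 1.3, total magnification 133.33, 3.9 µm field
of view); the Brewster sweep of a 40 nm gold sphere at a glass–water
interface; and a 100 nm silver nanocube at 450 nm (NA 1.42, magnification
160, 4.4 µm field of view).  Gold and silver optical constants are
transcribed from the standard published compilation into
`wavelength_nm,n,k` CSVs (342–984 nm) with linear interpolation; constant
indices: water 1.33, glass 1.5, polystyrene 1.59, air 1.0.

What these synthetic scenes do **not** emulate: coverslip roughness,
plasmonic-substrate enhancement, lens aberrations and back-reflections,
camera shot/read noise (unless explicitly added), and the measurement-side
postprocessing of real data (background acquisition, Fourier filtering of
spurious reflections).  Passing tests therefore demonstrate the fidelity of
the forward model under ideal-instrument conditions, not agreement with any
particular measured frame.

## Problem sizes used in the tests

Solver validation uses icosphere frequencies 2–5 (80–500 elements) against
Mie; the dimer acceptance run uses 720 elements per sphere (4,320 RWG edges
per current, a 8,640-unknown PMCHWT system, ~1.5 min); images in the tests
use 48–96 pixel grids over 2–4 µm fields with the default 50 × 51 angular
grid, and the energy/artifact checks use 256² pixels over 16 µm.  These
sizes were chosen so the full suite exercises every production code path at
quantitative tolerances while staying comfortably within a desktop-scale
run.

## Known limitations

* No substrate near-field (layered-Green-function) coupling inside the BEM
  kernels; accuracy degrades for large or strongly coupled particles very
  close to high-index substrates.
* Homogeneous, isotropic, non-magnetic media only; no genuinely
  inhomogeneous particle materials.
* Grid-sampled far fields cannot radiate into supercritical substrate
  angles (analytic sources can).
* The direct imaging quadrature needs azimuthal refinement for large
  fields of view; use the Bessel path (default in the pipeline).
* Fields inside intermediate stack layers are not evaluated.
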