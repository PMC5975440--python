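# Methods

This note records the models implemented in `lstmsim`, the approximations
behind them, the defaults and why, and what the synthetic tests do and do
not establish about real instruments.

## Optical geometry

**Elongated working distance.** The illumination objective is an air
objective dipped (behind a coverslip-sealed cap) into immersion oil. We
model the refraction of the *marginal* (aperture-edge) ray at a flat
air/medium interface: the ray leaves at `asin(NA)`, refracts to
`asin(NA/n)`, and crosses the axis at `EWD = WD · tan(asin NA) /
tan(asin(NA/n))`. The paraxial alternative `WD·n` differs by ~1 mm at
NA 0.28/n 1.454 (42.89 vs 43.84 mm); the marginal-ray form is the one
consistent with the instrument's published constraint analysis, and the two
agree in the NA → 0 limit (tested). The coverslip is treated as
index-matched to the oil; its thickness is not modelled.

**Angular bounds.** Two constraints bound the angular separation θ between
the illumination propagation axis and the detection axis: barrel collision
(`W₂ sin θ = D₁/2 + (D₂/2) cos θ`) and clearance of the detection working
distance (`W₂ cos θ = W₁ + (D₂/2) sin θ`), with `W₂` the elongated working
distance when the illumination objective is air. Both are solved by
bisection on the fixed bracket (0°, 90°) to 1e-6° — deterministic, no
initial guess. The illumination barrel diameter defaults to 28 mm (a
nominal value for the 4× macro objective; configurable), giving bounds of
43.47°/62.28° for the 10×/0.6 NA detection pairing. Angles are degrees at
every interface, radians internally. θ = 60° is the default everywhere, the
largest practical separation for this pairing (thinner effective sheet at
the cost of a longer tissue path).

**Path lengths.** The maximum illumination path length (MIPL) is computed
for the bulk slab: `t / cos θ` oblique, `w` (or `w/2` two-sided) orthogonal.
Corner wedges are ignored. The LSTM-favoured partition uses a strict
inequality with a 1e-12 relative guard so exact boundary points
(`w = t / cos θ`) classify as equal-or-LSM-favoured despite floating-point
rounding of the cosine.

## Sheet propagation and axial resolution

The sheet is Gaussian in its thin axis: intensity FWHM `b` at the waist,
1/e² half-width `w₀ = b/√(2 ln 2)`, Rayleigh range `z_R = π w₀² n / λ`,
thickness `b√(1 + (x/z_R)²)` at propagation distance `x`. `LightSheet`
stores the *actual* (perpendicular) thickness; because instruments are
usually specified by the *effective* (axial) thickness `b / sin θ`,
`LightSheet.from_effective_thickness` inverts the projection. Defaults:
excitation 0.488 µm, emission 0.52 µm (GFP/YFP band), n = 1.454, effective
thickness 4 µm — the middle of the 2–5 µm range such instruments run at.

The predicted axial FWHM at field position `s` is

```
FWHM(s) = sqrt( (b(d(s)) / sin θ)²  +  (1.77 n λem / NA²)² )
```

where `d(s)` is the distance from the sheet waist to the detection-plane
intersection. `d(s)` is *derived from the explicit 3-D scan trajectory*
(`scan.scan_trajectory`), the single source of truth: the 2-axis scan
decomposes the row displacement `s·x̂` into galvo (`s cos θ`, perpendicular
to propagation) and tunable-lens (`s sin θ`, along propagation) offsets so
`d ≡ 0`; the 1-axis scan keeps the lens fixed, leaving `d = |s| sin θ`; the
orthogonal LSM mode parks the waist at the field centre with θ = 90, so
`d = |s|`.

**Quadrature, not product.** The sheet's axial footprint and the detection
axial response are combined in quadrature (independent-Gaussian /
convolution approximation). The true system response is the *product* of
the illumination and detection profiles, which is narrower; quadrature is
the conservative standard approximation, keeps the model consistent with
the simulator's separable-Gaussian blur, and matches measured bead FWHM
ranges better than the product does. This is an explicit modelling choice,
stated here rather than hidden in the code.

## Acquisition simulator

Coordinates: `z` is the detection axis (focal plane `z = 0`), the shutter
scans along `x`, propagation is `û = (sin θ, 0, cos θ)`, the thin axis is
`v̂ = (cos θ, 0, −sin θ)`; voxel indices are 0-based `(z, y, x)` and
physical positions are voxel centres.

For each shutter row the sheet's waist line sits at the trajectory's
position; a voxel's illumination is the Gaussian sheet profile at its
perpendicular offset from the sheet mid-plane, with the local thickness
taken at its along-propagation distance from the waist. The detected stack
is emission × illumination blurred by a separable Gaussian detection PSF
(lateral FWHM `0.51 λem/NA`, axial as above) and summed over the
open-shutter rows only — a half-open row-offset window derived from the
rolling-shutter exposure, so disjoint consecutive windows add exactly to
the fully open acquisition (tested as an invariant), and narrowing the
window can only reject light.

Implementation: since phantoms are point emitters rendered as Gaussian
blobs (FWHM = bead diameter — a deliberate simplification over hard
spheres), the renderer evaluates each emitter analytically instead of
rasterizing an illumination volume: per row and z-plane it computes the
emitter's perpendicular and along-propagation offsets from the waist line,
folds the detection axial width and bead size into the sheet profile by
Gaussian convolution (the quadrature rule above, expressed in the thin-axis
coordinate), gates the per-row responses with the shutter window via prefix
sums, and multiplies by the lateral PSF. Illumination is sampled at the
bead centre. This is exact for point emitters under the stated blur model
and keeps a 9-bead, 1.2 mm-field, 0.5 µm-voxel acquisition (2.3 Mvoxel
stack) under a second on one core. Intensities are relative: each sheet
profile is normalized to unit peak (the instrument's absolute radiometry is
out of scope). Optional Poisson noise sits behind a seed and defaults off
so oracle tests are exact; two runs with identical inputs are
bit-identical.

The two symmetric illumination arms are modelled as one (the mirror arm
adds nothing for these questions and doubles runtime); z-stepping is
discrete stage motion — continuous-scan shearing is out of scope; the
camera's bi-directional readout mode is carried as a flag but the simulator
always models the one-direction sweep.

**FWHM measurement** extracts the axial line profile through the bead's
intensity maximum (refined in a ±2-voxel lateral neighbourhood), subtracts
the median of the profile tails (10% each end) as background, and measures
the separation of the half-maximum crossings by linear interpolation.
Flat or truncated profiles raise a measurement error; the per-field report
collects per-bead failures alongside the partial results.

## Energy load

The oblique sweep is simulated on a (width × thickness) voxel grid, one
voxel deep along the length (tiles along the length scale both geometries
by the same factor and cancel from the ratio). Imaged planes are spaced one
voxel apart through the thickness; per plane, sheet positions step along
the width by the sheet step (default: the voxel size — non-overlapping
sheets at the imaged plane); a voxel is counted when its centre lies within
half a step of the oblique sheet mid-plane (slab clipped to the sample
box). The orthogonal total is analytic, `(w/f) · N_voxels`, with
fractional tile counts by default and an integer-tile flag. The z-spacing
of the sweep's planes is not published for the original calculation, so the
voxel size defaults to `f/100` and we verify *scale invariance* instead
(scaling all lengths together leaves ratios unchanged, tested): absolute
ratio values depend on the discretization, the trends do not.

Trends established by the tests, each in its regime: the ratio decreases
monotonically with sample width and approaches 1 for wide, thin samples
(the oblique redundancy is thickness-limited while LSM's grows with
width); for compact samples (`w < t·tan θ`) the ratio is smaller at wider
angular separation (70° vs 50° tested). The θ-dependence is
regime-dependent — for very wide, thin samples the oblique total instead
grows as `1/cos θ` — and the discrete sweep makes the θ-curve slightly
jagged, so only the robust pairwise comparison is asserted. The simulation
is verified against a brute-force point-in-slab oracle, exactly, on grids
up to 20³ voxels at θ ∈ {0°, 30°, 45°, 60°}.

`bleaching_trend` returns the least-squares slope and Kendall rank
statistic of mean tile signal versus acquisition order; a constant series
reports τ = 0 by convention. Interpretation is left to the caller.

## Acquisition planning

Effective magnification `nominal · f_tube/180 mm`, pixel sampling
`pitch/M`, field of view `cols · pitch/M`. Tiles per axis are
`ceil(extent / (fov·(1−overlap)))` with a 10% default overlap — the
overlap used for the published tile counts is not recoverable, so frame
counts are planning estimates, while frame-count → bytes arithmetic is
exact. Byte figures are decimal (SI): a 2048² × 16-bit frame is 8.389 MB,
and only decimal units reproduce published frame-count/volume pairs
(23,001 frames → 192.95 GB ≈ "193 GB"). Single-channel by default;
channels are a multiplier.

## Phantoms

Bead grids (per-axis node count `max(1, floor(extent/spacing))`, optional
seeded uniform jitter clipped to the volume), uniform random beads with
log-normal(0, 0.25) amplitudes, and smooth random-walk filament chains
(emitter spacing half the bead diameter, boundary reflection). All
generators are pure functions of (parameters, seed); emitters never leave
the declared volume.

## What the synthetic tests do and do not show

The phantoms are sparse point emitters in a homogeneous, index-matched,
non-scattering medium. Passing tests therefore establish the *geometric
optics* of the method — trajectory correctness, slit gating, the
resolution-uniformity contrast between scan modes, energy accounting — not
its performance in scattering tissue: depth-dependent attenuation, sheet
broadening by scattering, aberrations from index mismatch, and stitching
artefacts are all outside the model. The scattering advantage of the
oblique geometry enters only through the illumination-path-length proxy.

## Problem sizes and numerical choices

Default test/acceptance problem sizes — a 1.2 mm field at 0.5 µm lateral
voxels with a 60 µm z-range (2.3 Mvoxel stacks), energy grids of order
100–2000 columns — keep the full suite and the acceptance run in seconds
to a couple of minutes on one core while leaving discretization errors an
order of magnitude below the tolerances tested. Angular roots are bisected
to 1e-6°; slab membership uses a 1e-9·voxel inclusive guard so centre-in-
slab ties resolve identically in the simulation and its brute-force
oracle; the shutter window is half-open in row offsets so window unions
are exact. The rolling-shutter exposure for bead characterization defaults
to 0.1 ms, the finest virtual slit the camera's published range offers,
as appropriate for PSF measurements.
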