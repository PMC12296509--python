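# Methods

`tomomorph` quantifies structures in labeled cryo-electron tomograms of
brain tissue: synaptic-vesicle size and shape, microtubule-bundle geometry,
and filament-axis coordinates for sub-volume averaging. Because the tomogram
data such pipelines are developed against are rarely public, the package
carries a synthetic-scene generator that reproduces the statistical
structure the analysis assumes, so every stage is validated against known
ground truth.

## Vesicle morphometry

A vesicle arrives as one integer label in a `(z, y, x)` voxel grid with an
isotropic voxel size in Å (bin8 tomograms at 15.84 Å/voxel are the
reference sampling; anisotropic voxels are rejected rather than silently
mishandled). Per vesicle the pipeline computes:

- **Diameter `d`** — the median over occupied z-slices of the per-slice 2D
  Feret diameter, where the Feret diameter is the maximum pairwise distance
  between *pixel centers* in the slice. Pixel centers (rather than
  corner-padded calipers) make the measure unambiguous and brute-force
  verifiable; the systematic offset is sub-voxel. A single-pixel slice
  contributes 0 and still enters the median. Slices are taken along z, the
  beam axis. The label's outer extent — membrane included — defines `d`.
- **Sphere volume** `V_s = π d³ / 6`.
- **Convex hull** volume `V_h` and area `A_h` of the voxel centers
  (scipy's Qhull), in nm³/nm².
- **Wadell sphericity** `Ψ = π^(1/3) (6 V_h)^(2/3) / A_h`, 1 for a sphere.

Labels whose voxel centers do not span a 3D hull (< 4 voxels, or coplanar)
carry absent hull metrics, are flagged, and always fail the quality filter.
Quality filtering keeps records with `Ψ ≥ min_sphericity` (default 0.80)
and `voxel_count ≥ min_voxels` (default 100); both thresholds exist to
discard partially segmented vesicles and are exposed in the API and CLI.
The defaults are this package's own choice — reasonable values for
bin8-scale vesicles, not community constants.

For a true sphere of diameter `D`, the per-slice Feret of a slice at height
`z` is `2√(R² − z²)`; the median over uniformly sampled slices is `√3 R`,
so the median-of-slices estimator converges to `(√3/2) D ≈ 0.866 D`. Tests
pin the measured/true ratio of digitized spheres (≥ 40 voxels across) inside
[0.82, 0.90]; the factor `2/√3` converts a median-Feret reading back to a
diameter when a physical size is wanted.

Per-tomogram summaries report the *mean of the per-vesicle medians*; group
comparisons (e.g. across postmortem intervals) use a Kruskal–Wallis
k-sample test at α = 0.05 on per-tomogram means — the tomogram, not the
vesicle, is the unit of analysis. Completely tied data (all values
identical) is reported as statistic 0, p = 1 rather than an error. The
choice of a rank-based test is a design decision: it is robust, k-sample,
and assumption-light; a parametric ANOVA on the same summaries would be a
reasonable alternative.

## Missing-wedge model

Single-axis tilting from `tilt_min` to `tilt_max` (default ±60°) about the
y axis measures, at tilt θ, the central Fourier plane rotated θ from the
untilted plane. A frequency is measured iff the folded angle
`φ = atan2(k_z, k_x) ∈ (−90°, 90°]` lies within the tilt range; the
unmeasured complement is the classic double wedge *around the beam axis*
`k_z`. The operator zeroes those coefficients (DC and the tilt-axis line
are always kept), is linear and idempotent, preserves conjugate symmetry,
and can only remove energy. The tilt increment is acquisition metadata and
does not enter the mask.

Corrupted densities are re-binarized at half the corrupted volume's
maximum — parameter-free and monotone in artifact severity.

**Bias characterization.** The wedge's real-space signature is elongation
along the beam axis. For a *solid* binarized sphere, half-max re-thresholding
therefore *grows* the convex hull (~5% at ±60°). The documented segmentation
bias — smaller hulls and lower sphericity — operates through the membrane:
a membrane patch whose normal is parallel to the beam has its spectrum
inside the wedge, so the polar caps of a vesicle fade. The bias study
accordingly renders vesicles as unit-density membrane shells
(`render_membranes`, default band thickness 4 nm, the canonical bilayer
figure), corrupts, re-binarizes, and re-measures. At 4 nm the cap loss and
the elongation nearly cancel for the hull: the volume decrease is small
(≲ 1%) and holds in roughly 91–95% of replicates, sitting near the ≥ 95%
bound the acceptance suite asserts; for thinner bands (≲ 3 nm) the decrease
is decisive. The sphericity decrease is robust (100% of replicates) at any
thickness. Real U-Net segmentations, which miss the caps entirely rather
than attenuating them, show the hull effect much more strongly than this
threshold model.

## Synthetic scenes

- **Vesicles**: true diameters are normal (mean 45.4 nm, SD 2.2 nm,
  truncated to positive — the values reported for cryo-preserved synaptic
  vesicles); centers are rejection-sampled so spheres sit fully inside the
  grid with a surface-to-surface gap ≥ `min_gap` (default 5 nm), erroring
  out if packing is infeasible within a bounded number of attempts. A voxel
  belongs to a sphere iff its *center* lies inside it — the same
  digitization the Feret/hull oracles assume. Every scene carries a truth
  table (label, center, true diameter) in bijection with the labels.
- **Filament bundles**: filaments run along z with cross-section positions
  placed as *pairs* separated by draws from a truncated normal (default
  mean 57.7 nm, SD 22.4 nm, lower bound 2 nm), each pair kept clear of
  everything already placed so both members realize their drawn
  nearest-neighbor distance exactly; an odd count anchors one extra
  filament under the same no-interference rule. The realized
  nearest-neighbor spacings of the final cross-section are recorded as
  truth. A truncated normal is a stand-in for the unreported empirical
  distribution: the analysis needs controllable first and second moments,
  not the exact shape, and it does not reproduce the rare > 200 nm
  spacings real dendrites show. Each backbone gets a sinusoidal lateral
  wobble (default amplitude 1 nm — microtubule persistence length is
  millimetric, so sub-micron segments are nearly straight; the wobble
  exercises the spline machinery without eroding truth recovery), with a
  control point every 24 nm emulating a trace point every 10–20 bin8
  slices. Wobble 0 yields exactly straight lines, for which measured
  distances equal construction distances to numerical precision.
- **Randomness**: one integer seed expands through `SeedSequence` spawning
  into independent substreams (diameters, centers, layout, wobble), so
  changing one draw count never perturbs the others; identical seeds give
  bit-identical scenes.

The generator makes no attempt at electron-optical contrast, CTF, noise,
or cellular context (membranes, ribosomes, synapse architecture), and the
voxelizer paints hard labels, not densities. Passing tests therefore
demonstrate the *measurement* pipeline's correctness on known geometry,
not segmentation performance on real tomograms.

## Filament analysis

Traces are IMOD-style point lists (`[object] contour x y z`, voxel units,
scaled to Å at load); single-point contours are skipped with a warning.
Each trace is fitted with a cubic interpolating spline under cumulative
chord-length parameterization (not-a-knot end conditions; 2–3 point traces
fall back to piecewise-linear). Arc length is accumulated by composite
5-point Gauss–Legendre quadrature on sub-2 Å panels — far below the 0.01 Å
tolerance the pipeline assumes — and arc-length queries invert the
cumulative table by interpolation. On a helix sampled every 20°
(radius 120 Å, pitch 80 Å), total length lands within 0.02% of the closed
form and resampled tangents within 1° of the analytic tangent away from
the ends.

Interfilament distance is *per-filament nearest-neighbor closest approach
in 3D between spline curves*: for each filament, the minimum over all
other filaments in the same tomogram of the minimum distance between the
two curves, computed on 10 Å polylines and refined by exact segment-pair
closest approach around the coarse minimum (agreement with a dense 1 Å
brute force is within 0.2 nm). One value per filament matches a
per-filament unit of analysis; an all-pairs mode exists behind a flag.
Distances are center-to-center; no microtubule-radius offset is applied.
Curves rather than raw trace points matter because traces are sparse
(every 10–20 slices) and raw-point distances would overestimate.

Lattice-defect bookkeeping counts curated annotations
(`missing_protofilament`, `incomplete_end`) — defect *detection* is out of
scope. Depth profiles place each serial section at
`(section_index + ½) × pitch` (default pitch 5 μm) below the top of the
lift-out, sort by depth, and never smooth.

## Particle seeding

Spline axes are resampled every 40 Å — the axial repeat of a tubulin
monomer — dropping the final partial interval to preserve lattice register.
Each sample becomes a particle row: coordinates divided by the extraction
pixel size (1.98 Å unbinned × 4 = 7.92 Å, box 84 px by default) and ZYZ
Euler priors `(rot, tilt, psi)` with `tilt = arccos(t_z)`,
`psi = atan2(t_y, t_x)`, and `rot = 0` — the spin about the filament axis
is unconstrained, left free for alignment. The convention is
`R = R_z(psi) R_y(tilt) R_z(rot)` with the filament axis `R ẑ`; the
round trip reproduces the tangent to < 10⁻⁶. Rows whose centered box
exceeds the volume are flagged, not dropped — extraction tools differ in
how they pad, so the decision belongs to the consumer. Tables are written
as classic single-block STAR files (`data_particles`, one `loop_`,
whitespace-delimited), the smallest form every downstream reader parses.

## Reporting

Feature prevalence over tomogram catalogs is reported as `(k/n, or p%)`
with percentages at printed precision: nearest integer at ≥ 1%, one
decimal below 1% or on request, round-half-even, locale-independent. Raw
`k/n` always accompanies the string so rounding loses nothing.

## Problem sizes and numerical choices

The validation suite uses scenes sized for exactness of the checks rather
than realism of scale: 10–500 vesicles per scene, 64³–72³ wedge grids,
100 wedge replicates, 200-filament bundles (~15 s for the full
nearest-neighbor matrix), and 6 × 20-vesicle tomograms for recovery
studies. Voxelization ties go to the nearest backbone, then the lowest
label; out-of-grid traces are clipped with a warning; packing failures and
malformed point files raise errors that name the offender. Exported floats
are written at 6 significant digits.

## Known limitations

- The wedge-bias threshold model understates the hull-volume bias of real
  learned segmentations (see above); its hull half is a borderline effect
  at a 4 nm membrane band.
- Truncated-normal spacings and diameters are moment-matched stand-ins,
  not the unreported empirical distributions.
- Feret values are pixel-center based; a region-boundary convention would
  read ~1 voxel larger.
- Group comparison is a single k-sample rank test; no multiple-comparison
  machinery is included.
- The generator's clean labels cannot expose failure modes that arise from
  segmentation noise, touching vesicles, or non-spherical organelles.
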