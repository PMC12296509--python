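# tomomorph

Quantitative morphometry for cryo-electron tomography of brain tissue.

Cryo-ET of vitrified hippocampus yields labeled tomograms of synaptic
vesicles and traced microtubule bundles; turning those into numbers —
vesicle sizes that are honest about the missing wedge, interfilament
spacings measured between curves rather than sparse trace points, particle
coordinates ready for sub-volume averaging — is the job of this package.
It is written for cryo-ET practitioners and image-analysis developers who
need the measurement side of such a study as tested, reusable code.

## What it computes

**Vesicles.** For each integer label in a volume (axis order `(z, y, x)`,
voxel size in Å): the diameter *d* as the median over z-slices of the
per-slice 2D Feret diameter (max pairwise pixel-center distance); the
sphere volume *V*<sub>s</sub> = π*d*³/6; the convex-hull volume
*V*<sub>h</sub> and area *A*<sub>h</sub> of the voxel centers; and the
Wadell sphericity

&nbsp;&nbsp;&nbsp;&nbsp;Ψ = π<sup>1/3</sup> (6 *V*<sub>h</sub>)<sup>2/3</sup> / *A*<sub>h</sub>,

which is 1 for a sphere. Partial segmentations are excluded by thresholds
on Ψ and voxel count; per-tomogram summaries report the mean of the
per-vesicle medians, and groups of tomograms are compared with a
Kruskal–Wallis test.

**Filaments.** IMOD-style point lists become chord-length-parameterized
cubic splines with arc-length queries; interfilament distance is each
filament's nearest-neighbor closest approach in 3D to any other filament
in the same tomogram, pooled into `mean ± SD (median, n)`. Lattice-defect
annotations are tallied, and filament counts are profiled against serial
lift-out depth.

**Particle seeding.** Spline axes resampled every 40 Å (the tubulin
monomer repeat) become a STAR particle table with coordinates at the
extraction pixel size (1.98 Å × 4 = 7.92 Å by default) and ZYZ Euler
priors pointing the reference z-axis along the filament tangent.

**Synthetic scenes.** A generator builds labeled volumes with known truth
tables — spherical vesicles (45.4 ± 2.2 nm at 15.84 Å/voxel) and parallel
filament bundles (nearest-neighbor spacings 57.7 ± 22.4 nm) — plus a
Fourier-space ±60° missing-wedge model and a membrane-shell renderer, so
the whole pipeline is testable without any experimental data. See
`docs/methods.md` for the model details and their limitations.

## Worked example

```python
import numpy as np
import tomomorph as tm

scene = tm.gen_vesicle_scene(20, seed=1)                      # labeled volume + truth
records = tm.measure_vesicles(scene.volume)
kept = tm.filter_vesicles(records, tm.FilterSpec())           # psi >= 0.8, >= 100 voxels
summary = tm.summarize_tomogram(kept, "demo")
print(f"{summary.n_vesicles_pass}/{len(records)} vesicles pass filters")
print(f"mean of per-vesicle median Feret: {summary.mean_of_median_feret_nm:.2f} nm")
print(f"diameter estimate (x 2/sqrt(3)):  {summary.mean_of_median_feret_nm * 2 / np.sqrt(3):.2f} nm")
print(f"generator truth mean:             {scene.truth_table().true_diameter_nm.mean():.2f} nm")

bundle = tm.gen_filament_bundle(tm.BundleSpec(n_filaments=30, seed=7))
splines = [tm.fit_spline(t) for t in bundle.traces]
table, s = tm.nearest_neighbor_distances({"demo": splines})
print("interfilament:", tm.format_distance_summary(s))

pos, tan = tm.resample_arclength(splines[0], spacing=40.0)
rows = tm.build_particle_table(pos, tan, tm.ExtractionSpec(), tomogram_id="demo")
print(f"{len(rows)} particles seeded on filament 1")
```

Output:

```
20/20 vesicles pass filters
mean of per-vesicle median Feret: 38.75 nm
diameter estimate (x 2/sqrt(3)):  44.74 nm
generator truth mean:             44.95 nm
interfilament: 59.7 ± 19.1 nm (median 51.5 nm, n = 30)
151 particles seeded on filament 1
```

The median-of-slices Feret reads √3/2 ≈ 0.866 of the true diameter (the
median slice of a sphere is not its equator); multiplying by 2/√3 recovers
the physical size, here within 0.3 nm of the generator's truth. The
interfilament summary pools one nearest-neighbor distance per filament.

The same operations are available from the shell:

```bash
tomomorph simulate-vesicles --out scene --n-vesicles 20 --seed 1
tomomorph measure-vesicles --labels scene.mrc --out scene --min-sphericity 0.8
tomomorph simulate-filaments --out bundle --n-filaments 30 --seed 7
tomomorph measure-filaments --points bundle_points.txt --voxel-size 15.84 --out bundle
tomomorph seed-particles --points bundle_points.txt --voxel-size 15.84 --out particles.star
tomomorph prevalence --catalog features.csv
```

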