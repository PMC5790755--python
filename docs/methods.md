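# Methods

`sasmorph` reimplements, as a tested pipeline, the morphometric analysis of
synaptic junctions in FIB/SEM serial-section stacks: 3D segmentation of the
electron-dense pre/postsynaptic specializations, extraction of the synaptic
apposition surface (SAS) as an open triangle mesh, per-synapse measurement
(area, perimeter, curvature, Feret diameter, shrinkage correction), shape
classification (macular / perforated / horseshoe), and population
statistics (log-normal size fitting with goodness-of-fit ranking,
Mann-Whitney and chi-squared comparisons, area-perimeter regression).
Because no real stacks are distributed with the package, every stage is
validated against synthetic phantoms whose geometry is known in closed
form; this note records the model, the defaults, and the design choices.

## The phantom model

The target SAS of a phantom is a spherical cap of radius `R` and half-angle
`theta`, which has closed forms for every quantity the pipeline measures:

    area      A = 2 pi R^2 (1 - cos theta)
    perimeter P = 2 pi R sin theta
    curvature c = (1 - cos theta) / 2        # the 1 - projected/area statistic
    Feret     F = 2 R sin theta              # minimal enclosing sphere

`cap_angle_rad = 0` denotes the flat-disc limit (radius stored in
`sphere_radius_nm`). The cap is thickened into three concentric shells —
postsynaptic density, synaptic cleft, presynaptic density — all rendered at
the dark `density_gray`, since the densities image as dark electron-dense
material and the segmentation deliberately merges the pre- and
postsynaptic sides into one 3D object. The apposition surface is the sphere
`rho = R` in the middle of the cleft.

Curvature is controlled by `theta` alone and `R` is solved from the drawn
area (`A = 4 pi c R^2`), so area and curvature are independent by
construction; a population generated this way shows no area-curvature
correlation, matching the study's empirical finding.

Per-synapse type: excitatory (AS) phantoms carry a 40 nm PSD, inhibitory
(SS) phantoms a 15 nm PSD (the classical thick/thin criterion); both use a
20 nm cleft and a 20 nm presynaptic density. Curvature draws are normal
with class means 0.07 / 0.10 / 0.11 (macular / perforated / horseshoe,
the reported per-class ordering), sd 0.03, truncated to [0.02, 0.30].

### Shape classes

* **Perforated** caps carry `k` circular holes (geodesic radius
  `0.25 R theta / sqrt(k)`, centers on the ring at polar angle
  `0.45 theta`), fully interior to the cap. `k` is 1 with probability 0.8,
  else 2.
* **Horseshoe** caps have a radial notch (azimuthal half-width 0.35 rad)
  whose polar extent is solved from
  `sin(theta - delta) = (1 - frac) sin(theta)`, so that the notch depth *in
  the projection plane* equals `frac` times the projected equivalent
  radius — the same quantity the classifier measures. Generated fractions
  are uniform in [0.65, 0.85], safely above the 0.5 decision threshold.
* **Macular** caps are plain.

Class assignment is tilted by size: the probability of a junction being
perforated or horseshoe grows as a power of its area (exponents 2.0 and
1.55), rescaled by iterative proportional fitting so the expected class
frequencies equal the requested mixture exactly. This reproduces the
reported pattern that perforated and horseshoe junctions live in the right
tail of the size distribution (their mean areas come out ~2.5x and ~2.1x
the macular mean), while leaving the log-normal area marginal and the
mixture marginal untouched — both are asserted by tests.

### Population defaults

The generator's defaults are the study conditions of the pooled cortical
population: log-normal SAS areas with location mu = 10.84 and scale
sigma = 0.79 (log nm^2), mixture 93 / 4.5 / 2.5 %, excitatory fraction
90.83 %, voxels 3.7 x 3.7 x 20 nm (the 20 nm step is the section
thickness). Gray levels (background 180, density 60, noise sd 10 on an
8-bit scale) are fixture choices — the real gray-level distribution of the
source stacks is not published — picked to give the strong contrast
typical of heavy-metal-stained densities.

## Rendering

Voxels are classified by their center: a voxel belongs to a phantom if its
center lies in the slab shell and inside the cap cone, minus holes and
notch. Gaussian noise is added and the stack clipped to 8 bits. The label
volume stores the phantom id and a two-valued side code (postsynaptic /
presynaptic), split exactly at the apposition sphere: the cleft's inner
half is attributed to the post side and its outer half to the pre side, so
that the pre/post voxel interface *is* the SAS up to half a voxel. Slabs
thinner than one section along z are rendered but flagged (aliasing risk),
which is the expected regime for SS phantoms at 20 nm sectioning.

## Segmentation

Gaussian blur with per-axis sigmas in nm (converted to voxel units per
axis, so smoothing is isotropic in physical space), a dark-side gray
threshold (per-stack Otsu by default; the original workflow used an
interactively chosen threshold, which is not reproducible), 26-connected
components, and a physical minimum-volume filter (default 20,000 nm^3,
below the smallest reported SAS area times one section). 26-connectivity is
used because the 20 nm z-step under-samples oblique junctions and
6-connectivity fragments them. A component touching any of the six stack
faces is flagged truncated — including the first/last sections — and the
exclusion step partitions the population exactly as the field-of-view
exclusion does on real stacks.

AS/SS typing estimates the mean slab thickness along the surface normal as
component volume / SAS area, subtracts the nominal cleft and presynaptic
thicknesses (config, 20 nm each), and calls the junction AS when the
remaining PSD thickness reaches 25 nm (config). The original study gives no
number for this split; 25 nm sits midway between the generator's 15 and
40 nm and the balanced-fixture accuracy is asserted at >= 95 %.

## SAS extraction

Two point sources feed one mesher:

* with pre/post sublabels (always available on synthetic data through the
  label volume), the cloud is the centers of voxel faces separating the
  two sides — exact to half a voxel, with per-point precision weights
  `1/step^2` so faces across the coarse sectioning axis count less;
* without sublabels, the segment's voxel centers are collapsed to their
  per-cell height midrange — a thinning of the slab to its medial sheet.

The mesher is a smoothed height field. Points are projected onto the
cloud's principal plane with the in-plane axes rotated so one axis is
horizontal (sampled at the 3.7 nm pixel pitch) and the other absorbs the
projected 20 nm section step; the binning grid is anisotropic accordingly
(base cell 6 nm). Per-cell heights are smoothed by a weighted
local-quadratic (Savitzky-Golay) fit, 7x7 cells, 3 passes — a quadratic
fit is unbiased on gently curved sheets even where the window is one-sided,
so neither the steep rim of a cap nor its dome curvature is flattened (a
windowed mean or a first-order fit measurably biases both; this
grid-level smoothing also replaces mesh-space Taubin smoothing, which on
an open mesh shrinks the rim and biases area). Occupied
cells are triangulated by 2x2 blocks; interior sampling dropouts smaller
than 1000 nm^2 are closed while real perforations survive; the largest
face-connected component is kept. Boundary vertices are then pushed
outward to the supporting extreme of the data in their 3x3 cell
neighbourhood plus half a local sample spacing (cell centroids otherwise
stop half a cell short of the true rim, a several-percent area deficit on
small junctions), carrying the fitted height gradient.

Measurements on the mesh:

* **area** — triangle-area sum;
* **perimeter** — length of the longest boundary loop after a light
  moving-average and a 5 nm Douglas-Peucker simplification (raw voxel-scale
  jitter would inflate the length); perforation rims are reported
  separately, not added to the perimeter;
* **curvature** — `1 - projected_area / area` with the projection on the
  area-weighted least-squares plane of the triangle centroids, which makes
  the statistic rigid-motion invariant; 0 for a flat surface;
* **Feret diameter** — exact minimal enclosing sphere (Welzl's randomized
  incremental algorithm, cross-checked against brute force) of the mesh
  with denoised boundary loops, since the enclosing sphere is governed
  entirely by extreme points;
* **shrinkage correction** — measured values are divided by 0.81 (areas),
  0.90 (lengths), 0.73 (volumes); curvature, a ratio of areas, is
  invariant. Division is used because the measurements are made on shrunken
  tissue and the pre-shrinkage value is wanted; the factors are mutually
  consistent (0.81 = 0.90^2, 0.73 ~ 0.90^3).

Accuracy on 200 random noise-free cap phantoms spanning the population
size range (the geometry-oracle experiment): median relative error ~2 % in
area, ~1.5 % in perimeter, ~0.7 % in Feret, and ~0.008 absolute in
curvature. The residual area deficit is the half-voxel quantization of the
rendered interface; it grows on the smallest junctions (rim radius a few
tens of nm).

## Shape classification

`n_holes = 1 - chi` with `chi = V - E + F` (disc chi = 1, annulus 0);
multi-component meshes are rejected — fragmented/partitioned PSDs are
outside the taxonomy. Indentation depth is the maximum distance from the
projected outer outline to its 2D convex hull, normalized by the projected
equivalent radius. A mesh with any hole is perforated regardless of
indentation; otherwise indentation >= 0.5 (config) makes it horseshoe; else
macular. The 0.5 threshold is this module's key free parameter — the
original criterion was visual — and is surfaced in the config and CLI.
Detection limits: a hole needs to span about two grid cells (roughly 45 nm
diameter at the anisotropic cell size), and the hull-chord measure
under-reads the notch depth by ~0.07 of the equivalent radius; both are
irrelevant for realistically sized (large) perforated/horseshoe junctions
and quantified by the recovery tests.

## Population statistics

Log-normal fitting is maximum likelihood on logs (`mu` = mean,
`sigma` = 1/n-denominator sd); family ranking fits
lognormal/normal/gamma/weibull by ML and orders by the one-sample KS
statistic with AIC reported alongside (the original study used a
commercial fitting package; ML + KS is a stated methodological
substitution). Mann-Whitney is exact by the standard counting recurrence
for tie-free samples with min(n) <= 8, else a tie-corrected normal
approximation with continuity correction; the exact path is cross-checked
against an independent implementation. Chi-squared is Pearson's without
Yates correction, warning when expected counts drop below 5. The
area-perimeter regression is OLS of perimeter on sqrt(area) — the scale on
which similar shapes are exactly linear, with the circle reference
P = 2 sqrt(pi A) — plus a log-log fit; no multiple-testing correction is
applied by default, matching the raw pairwise p-values reported in this
literature. SEM uses the n-1 sample standard deviation.

## What the synthetic data does and does not show

The phantoms emulate the geometry and contrast of segmented junctions —
anisotropic voxels, merged pre/post densities, truncation at stack faces,
log-normal sizes, the class mixture and its size tilt — but not neuropil
texture (membranes, vesicles, mitochondria), multi-synaptic boutons,
touching junctions, or realistic noise statistics. Passing tests therefore
demonstrate that the measurement chain is unbiased and stable for
junction-like geometry at FIB/SEM sampling, not that the segmentation
would isolate junctions in real neuropil; on real stacks the gray
threshold and minimum-volume filter would need tuning, and the pipeline
reads standard multi-page TIFF for exactly that use.

## Problem sizes

The bundled experiments use the study's own sample sizes where printed
(6259 draws for the log-normal refit) and 2000 rendered phantoms for the
end-to-end mixture recovery, 200 for the geometry oracle; each phantom is
rendered in its own tight stack, which keeps the full mixture experiment
at a few minutes on one core.

## Known limitations

* The interface cloud is quantized at half a voxel; on junctions whose rim
  radius approaches the section thickness the area bias reaches ~10 %.
* Holes smaller than ~45 nm across and notches shallower than ~0.1 r_eq
  are below the mesher's resolving power at 20 nm sectioning.
* The medial (no-sublabel) extraction path assumes the apposition surface
  is midway through the merged slab; with asymmetric pre/post thickness it
  is biased toward the thicker side by half the thickness difference.
* `classify_as_ss` needs the nominal cleft and presynaptic thicknesses as
  config; on real data these would be calibrated, not known.
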