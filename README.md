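# sasmorph

Morphometry of synaptic junctions from 3D electron microscopy, built
around the **synaptic apposition surface** (SAS): the single open surface
standing in for the presynaptic density / postsynaptic density (PSD) pair
of a chemical synapse. Given an anisotropic FIB/SEM serial-section stack
(a few nm per pixel in-plane, 20 nm sections), the pipeline

1. **segments** synaptic junctions — Gaussian blur, dark gray-level
   threshold, 3D 26-connected components, a physical minimum-volume
   filter, and exclusion of junctions truncated by the field of view;
2. **extracts** the SAS of each junction as an open triangle mesh;
3. **measures** it: surface area *A*, outer perimeter *P*, Feret diameter
   (smallest circumscribing sphere), and the curvature statistic
   `c = 1 − A_projected / A` (0 for a perfectly flat synapse, growing
   toward 1 with bending), with shrinkage correction
   (linear 0.90, surface 0.81, volume 0.73);
4. **classifies** shape — *macular* (plain disc), *perforated* (one or
   more holes in the PSD, detected from the mesh Euler characteristic
   `χ = V − E + F`, holes `= 1 − χ`), *horseshoe* (deep outline
   indentation relative to the equivalent radius) — and synapse type —
   excitatory/asymmetric (AS, thick PSD) vs inhibitory/symmetric (SS,
   thin PSD);
5. runs **population statistics**: maximum-likelihood log-normal fits of
   the size distributions with goodness-of-fit ranking across candidate
   families, Mann-Whitney pairwise tests (exact by enumeration for small
   tie-free samples), χ² contingency tests, and the perimeter ~ √area
   regression with the circle reference `P = 2√(πA)`.

It is aimed at connectomics / quantitative neuroanatomy work where
synapse sizes and shapes must be measured reproducibly at scale. Since no
public EM stacks ship with the package, it includes a first-class
**synthetic phantom generator**: spherical-cap synapses with closed-form
area `2πR²(1−cos θ)`, perimeter `2πR sin θ`, curvature `(1−cos θ)/2` and
Feret `2R sin θ`, rendered into noisy anisotropic stacks with ground-truth
labels, with population sizes drawn log-normal(μ = 10.84, σ = 0.79 in
log nm²), a 93 / 4.5 / 2.5 % macular/perforated/horseshoe mixture and a
90.83 % AS fraction. Every downstream stage is validated against these
analytic oracles; see `docs/methods.md` for the model and its limits.

## Worked example

One typical cortical synapse phantom (area 65,073 nm², curvature 0.07),
rendered into a noisy 3.7 × 3.7 × 20 nm stack and pushed through
segmentation, SAS extraction, morphometry and classification:

```python
import math
from sasmorph import synthgen, experiments

spec = synthgen.PhantomSpec(sphere_radius_nm=272.0, cap_angle_rad=0.5355,
                            orientation=(0.2, -0.5, 0.84))
truth = synthgen.analytic_truth(spec)
res = experiments.measure_phantom(spec, seed=5, noise_sd=10.0)
r = res.record
print(f"analytic: area={truth.area_nm2:.0f} nm^2  perimeter={truth.perimeter_nm:.0f} nm  "
      f"curvature={truth.curvature:.3f}  feret={truth.feret_nm:.0f} nm")
print(f"measured: area={r.area_nm2:.0f} nm^2  perimeter={r.perimeter_nm:.0f} nm  "
      f"curvature={r.curvature:.3f}  feret={r.feret_nm:.0f} nm  "
      f"shape={r.shape_class}  type={r.synapse_type}")
```

prints

```
analytic: area=65073 nm^2  perimeter=872 nm  curvature=0.070  feret=278 nm
measured: area=62522 nm^2  perimeter=849 nm  curvature=0.074  feret=277 nm  shape=macular  type=AS
```

i.e. the full image-based chain recovers the analytic area within ~4 %,
perimeter within ~3 %, curvature within 0.004, Feret within 1 nm, and
assigns the correct shape class and (from the 40 nm PSD slab thickness)
the correct AS type. Refitting a seeded log-normal sample at the pooled
population parameters,

```python
fit = experiments.lognormal_recovery(seed=1)   # n=6259 draws at (10.84, 0.79)
print(f"mu={fit.location:.3f} sigma={fit.scale:.3f} KS={fit.ks_statistic:.4f}")
# mu=10.836 sigma=0.789 KS=0.0053
```

recovers location and scale to three decimals.

## Command line

```bash
sasmorph all --seed 1 --out run1/         # synthetic end-to-end pipeline
sasmorph simulate --n 50 --seed 0 --out sim/
sasmorph segment --stack stack.tif --voxel 3.7 3.7 20 --sigma-nm 7.4 7.4 20 --out seg/
sasmorph measure --mesh run1/meshes/sas_00001.ply
```

`sasmorph all` writes the stack and label TIFFs, per-segment and
per-synapse CSVs, PLY meshes, summary tables (`table1_areas.csv`,
`table2_perimeters.csv`, `table3_shapes.csv`, `comparisons.csv`), SVG
plots, and a checksummed `manifest.yaml`; identical seeds reproduce
bit-identical artifacts.

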