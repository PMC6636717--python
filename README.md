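# nucleomorph

Nuclear morphometry and chromatin-texture analysis for DAPI-stained nuclei.

Changes in nuclear size, shape and chromatin condensation accompany cell-type
differences, malignant transformation and mechanical or chemical perturbation
of cells.  `nucleomorph` turns raw multi-frame fluorescence images of
DAPI-stained nuclei — including the noisy, drifting stacks produced by
low-cost or mobile microscopes — into a quantitative per-nucleus description
and a low-dimensional feature space in which cell populations can be
compared.  It is aimed at researchers building image-based nuclear phenotyping
or screening pipelines who need every stage testable without proprietary
acquisition software.

## What it computes

**Preprocessing** (per field): integer-pixel frame alignment by
cross-correlation → pixel-wise averaging (noise ∝ 1/√N) → rolling-ball
background subtraction → radius-1 median filter → Otsu threshold →
single-nucleus masks and crops.

**Nine parameters per nucleus** — morphometric: projected area *A* (μm²),
aspect ratio, perimeter *P* (μm), shape factor *P*²/(4π*A*), relative
concavity (*A*ₕᵤₗₗ − *A*)/*A*ₕᵤₗₗ; textural: centre–centroid mismatch (μm),
intensity entropy −Σ *p* log₂ *p* (bits, 256 bins), SD of min-max-normalized
intensities, and the **autocorrelation length-scale**: the largest circle
inscribed in the nucleus is min-max scaled and mean-subtracted, the Pearson
correlation between the circle and a copy shifted by every integer vector is
computed over the overlap of the supports, coefficients are averaged in
unit-width annular distance bins, and the length-scale is the first zero
crossing of that mean curve — the shift at which bright chromatin structures
on average meet dark ones.

**Feature space**: parameters pooled over all nuclei are standardized
(mean 0, SD 1) and decomposed by PCA (covariance eigendecomposition;
deterministic sign convention).  Group segregation is reported as silhouette
coefficient and leave-one-out nearest-centroid accuracy on the first three
components, plus the top-loading morphometric and textural parameter per
component.

**Synthetic data**: a first-class generator produces nucleus fields with
known ground truth — elliptical-to-concave shapes, band-pass chromatin
texture with a controllable correlation length, polynomial background,
per-frame translations and sensor noise — so every stage is testable without
any image download.  `docs/methods.md` has the full model description.

Also included: a documented utility computing the compressive force per cell
for a weighted-coverslip loading experiment
(`force_per_cell`: (m − m_buoyant)·g / n_cells).

## Worked example

End-to-end run on the built-in two-population preset (30 synthetic nuclei,
group B with 2× the area and 2× the chromatin correlation length of group A):

```python
from nucleomorph.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(preset="two-populations", seed=7,
                                  n_per_group=15), "out")
print(manifest)
```

prints

```
{'preset': 'two-populations', 'seed': 7, 'n_fields': 30,
 'n_nuclei_generated': 30, 'n_nuclei_segmented': 30,
 'n_missing_length_scale': 0, 'n_rows_dropped_missing': 0,
 'silhouette': 0.43019211249461076, 'nearest_centroid_accuracy': 1.0,
 'variance_explained_first_k_pct': 81.90665132679163}
```

All 30 generated nuclei were segmented; none had a degenerate texture.  The
two groups separate perfectly (every nucleus closer to its own group's
centroid than to the other's, leave-one-out), and the first three principal
components carry 81.9% of the variance.  `out/features.csv` holds the nine
parameters per nucleus:

```
nucleus_id group  projected_area_um2  shape_factor  autocorrelation_length_scale_um
  f000_n00     A               94.00      1.106318                         0.863204
  f001_n00     A               81.36      1.077451                         0.856407
  f002_n00     A              111.40      1.039671                         0.784932
```

(group A is generated at 100 μm² mean area and 0.8 μm texture scale — the
measured values recover both through the full noisy pipeline), and
`out/pca_variance.csv` the spectrum:

```
component  variance  pct_explained  cumulative_pct
      PC1  4.301724      47.796938       47.796938
      PC2  1.867508      20.750087       68.547025
      PC3  1.202366      13.359627       81.906651
```

The same stages are scriptable from the shell:

```bash
nucleomorph synth --preset field --seed 1 --out fields/
nucleomorph preprocess fields/field_000.tif --pixel-size 0.2 --out proc/
nucleomorph features proc/field_000_crop_00.tif proc/field_000_mask_00.tif \
    --pixel-size 0.2 --out features.csv --curve-out curves.csv
nucleomorph pca features.csv --components 3 --out pca/
nucleomorph run --preset two-populations --seed 7 --out out/
nucleomorph force            # -> 21.9 uN per cell (default experiment)
```

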