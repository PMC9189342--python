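# scomorph

Spatial single-cell, single-mRNA expression analysis for multiplexed
smFISH + immunofluorescence kidney micrographs, with super-resolution
podocyte morphometry.

Bulk transcriptomics of kidney biopsies drowns signals from rare cell
populations (a biopsy is mostly proximal tubule), and dissociation-based
single-cell methods destroy the spatial context a pathologist needs.
smFISH keeps both: each mRNA molecule appears as a diffraction-limited
fluorescent spot in the intact FFPE section. `scomorph` turns such
four-channel micrographs (immunofluorescence, two smFISH channels, DAPI)
into quantitative per-cell expression tables by

1. **spot calling** — difference-of-Gaussians band-pass, non-maximum
   suppression, and subpixel localization via the gradient radial-symmetry
   center (the point x̂ minimizing Σᵢ wᵢ d²(x; pᵢ, ∇Iᵢ), the weighted
   squared distances to the lines through pixel centers along local
   gradient directions);
2. **virtual microdissection** — glomerular tufts from the podocin IF
   channel, nuclei from DAPI by distance-transform watershed, cell
   territories by nearest-nucleus label expansion; externally predicted
   UNet/StarDist masks are first-class inputs;
3. **per-cell quantification** — spots assigned to cells and to the
   intraglomerular vs tubulointerstitial compartment by label-mask lookup,
   expression normalized per cell to an on-slide reference transcript
   (PPIB-style): `normalized = n_target / n_reference`;
4. **podocyte analysis** — podocytes = marker-positive (WT1-style nuclear
   IF) intraglomerular cells; per-glomerulus morphometry (tuft area,
   Feret diameter, podocyte density);
5. **reference-gene screening** — model-based stability values
   (NormFinder-style variance decomposition; lower = more stable) on
   log2 expression matrices;
6. **statistics & morphometry** — a normality-gated decision tree
   (Welch t / Mann–Whitney / ANOVA + Dunnett / Kruskal–Wallis + Dunn),
   OLS co-expression with 95% confidence bands, spatial transcript
   density surfaces, and filtration-slit density
   FSD = slit length / area (µm⁻¹) from skeletonized podocin images —
   the standard foot-process-effacement readout.

A built-in simulator renders star-convex nuclei, glomerular tufts,
negative-binomial per-cell transcript counts as Gaussian spots, and
Poisson + read noise, returning exact ground truth (masks, spot
ownership, per-cell counts), so every stage is testable without any
external data.

## Worked example

Simulate two tissue fields and run the batch pipeline:

```python
from pathlib import Path
from scomorph import TissueSimParams, simulate_tissue_image, RunConfig, run_batch
from scomorph.simulate import write_simulation

indir = Path("demo"); indir.mkdir()
for i in range(2):
    stack, truth = simulate_tissue_image(TissueSimParams(seed=100 + i))
    write_simulation(stack, truth, indir)

result = run_batch(RunConfig(), indir, indir / "out")
```

or equivalently from the shell:

```bash
scomorph simulate demo --seed 100 --n-images 2
scomorph run demo demo/out
```

`demo/out/cells.csv` then holds one row per segmented cell:

```
image_id  cell_id      x        y   nucleus_area_um2  compartment         glom_id  marker_positive  count_fish1  count_fish2  normalized_expression
sim_100   1        304.83   972.73             28.58  tubulointerstitial        0  False                      4            7               0.571429
sim_100   2        516.85   359.26             64.19  tubulointerstitial        0  False                      3            4               0.750000
sim_100   3        672.53   521.97             41.97  tubulointerstitial        0  False                      0           13               0.000000
```

`normalized_expression` is the per-cell target/reference spot-count ratio
(undefined, and excluded from statistics, when the reference count is 0).
On this two-image run the marker-positive intraglomerular cells
(podocytes, n = 3) average 0.749 normalized transcripts/cell against
0.222 for all other cells — recovering the simulated 4× enrichment of the
target transcript in the podocyte class.  `summary.csv` reports
intra/extraglomerular areas and spot totals (conservation holds exactly:
intra + extra counts = detected spots per channel), and `gloms.csv` the
per-glomerulus morphometry, e.g.

```
image_id  glom_id  tuft_area_um2  feret_diameter_um  podocyte_count  podocyte_density_per_mm2
sim_100   2              1963.98              50.18               1                    509.17
```

(50.18 µm Feret for a simulated 25 µm-radius tuft cross-section).

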