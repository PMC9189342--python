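# Methods

## Image model and channel conventions

All operations run on single 2D planes; z-stacks are reduced by maximum
projection on read, which is appropriate for the thin (~2 µm) acquisitions
the workflow targets.  Multichannel TIFFs follow the convention
immunofluorescence in C1, smFISH in C2/C3, DAPI in C4; the channel map is
explicit and overridable.  The default pixel pitch is 0.189 µm (confocal
189 nm xy voxel); OME `PhysicalSizeX` metadata is honoured, an explicit
argument wins.  Pixels are indexed 0-based, arrays stored (row = y,
col = x), and all tables report coordinates in (x, y) order with pixel
centers at integers.

## Synthetic tissue generator

The simulator defines the conditions under which the pipeline is
validated; its defaults are fixed, not tuned per experiment.

- **Geometry.** 1024×1024 px fields at 0.189 µm/px (~194 µm across).
  Three glomerular tufts of 25 µm radius — small glomerular
  cross-sections, as a 5 µm section cuts most tufts off-center — placed
  without overlap by rejection sampling (bounded retries; failure raises
  `PackingError`).  25 nuclei per field as star-convex polygons (14
  vertices, radial jitter 22%) with mean radius 3.5 ± 0.7 µm, placed
  non-overlapping with a one-pixel exclusion halo.
- **Cell classes.** 40% of intraglomerular nuclei (exact rounded count)
  are marker-positive, emulating nuclear WT1 in podocytes; marker nuclei
  add a 10× brighter signal to the IF channel than the tuft stain.
- **Expression.** Per-cell transcript counts are negative binomial
  (mean µ, dispersion k; variance µ + µ²/k).  The reference channel uses
  µ = 8.1, k = 5.4, giving SD ≈ 4.5 — the reported behaviour of a strong
  on-slide reference transcript.  The target channel uses µ = 6.0 in the
  podocyte class vs 1.5 elsewhere (k = 5): a 4× class enrichment typical
  of a podocyte transcript.  Poisson would understate the observed
  per-cell count spread, hence NB.
- **Rendering.** Spots are isotropic Gaussians (σ = 1.5 px ≈ 284 nm,
  diffraction-limited at this pitch) with amplitude 150 over a fish-channel
  background of 20, placed uniformly inside the owning cell's territory
  (nucleus dilated 3 µm) with subpixel jitter; ~10 extracellular stray
  spots per channel (Poisson).  Noise is shot noise (Poisson) plus
  Gaussian read noise (SD 5).
- **Ground truth** is exact by construction: label masks, marker flags,
  spot positions with owner ids, per-cell counts (the tally of ownership).

What the simulator does *not* emulate: tissue autofluorescence texture,
optical aberrations and 3D PSFs, stain gradients, segmentation-relevant
pathology (crescents, sclerosis), or spatial transcript clustering inside
a cell.  Passing tests therefore demonstrate correctness of the
algorithms under controlled conditions, not segmentation performance on
clinical material — for that, externally predicted deep-learning masks
can be substituted at the same interface.

Auxiliary generators: `simulate_spot_field` (flat background + Gaussian
noise, so peak SNR = amplitude/noise SD exactly), `simulate_expression_matrix`
(one designed stable gene, group-shifted noisy others; negative SDs are
rejected, a zero stable-gene SD is allowed and yields a constant row),
and `simulate_slit_pattern` (parallel lines or a meander with closed-form
centerline length — a line of n pixels contributes n−1 inter-pixel
steps — and frame area).

## Spot calling

DoG band-pass with σ_small = 1.5 px (matching the PSF) and
σ_large = 2.5 σ_small.  Candidates are 8-neighbourhood local maxima at or
above an absolute threshold on the DoG image, greedily non-maximum
suppressed brightest-first (ties: smaller row, then column; suppression
at Euclidean distance < 3 px).  The default threshold is robust-noise
scaled, 5 × 1.4826 × MAD of the DoG image; on a noiseless image (MAD = 0)
it falls back to a tenth of the peak band-pass response, and a truly
blank channel yields an empty table.  A quantile mode is available.

Subpixel localization uses the classical gradient radial-symmetry
estimator on a 7×7 window: central-difference gradients, 3×3 boxcar
smoothing of the gradient fields, weights |∇I|² further down-weighted by
1/(d + 0.5) where d is the distance to the gradient-magnitude centroid
(far pixels carry mostly noise), then a 2×2 normal-equation solve.  The
window is clamped inside the image; singular or divergent systems fall
back to the intensity centroid and are flagged.  Localization runs on
the band-passed image — the DoG of a radially symmetric profile is
symmetric about the same center, so this suppresses noise without bias —
while intensities are raw peak minus local window median.  Measured
accuracy on the simulator: RMSE ≈ 0.03 px noiseless, ≈ 0.28 px at peak
SNR 5 with recall and precision 1.0 at 200 spots.

## Segmentation

Classical stand-ins for the original trained UNet (glomeruli) and
StarDist (nuclei); both are replaceable by external label masks
(`*_glom.tif`, `*_nuclei.tif` next to the image, auto-discovered in batch
mode, binary masks component-labeled, label images relabeled to {1..K}).

- **Glomeruli**: Gaussian smoothing (σ 2 px) → Otsu on the
  99th-percentile-clipped image → morphological closing (1 µm) → hole
  filling → area filter (≥ 700 µm²) → components.  The clipping step
  keeps the threshold anchored on the background/tuft transition when the
  IF channel also carries a rare, much brighter nuclear marker; a
  genuine tuft, given the area filter, always covers far more than 1% of
  a field.
- **Nuclei**: smoothing (σ 1 px) → Otsu → Euclidean distance transform →
  watershed seeded at EDT maxima (min separation 3 µm) → area filter
  (≥ 10 µm²).
- **Territories**: nearest-nucleus label expansion up to a radius
  (default 3 µm, ≈ a thin cytoplasmic rim; 0 reproduces nuclear-only
  counting).  Territories are disjoint, contain their nuclei, and their
  union is exactly the set of pixels within the radius of any nucleus.
- **Marker positivity**: per-nucleus mean marker intensity thresholded
  either absolutely or by Otsu over the per-label mean distribution
  (default).  Otsu here is computed *exactly* on the sample (sweeping all
  cuts between sorted values, threshold at the optimal gap midpoint):
  histogram-binned Otsu can misplace borderline nuclei when a whole
  intensity cluster lands in one bin.  With fewer than two labels or a
  degenerate distribution the call falls back to the absolute threshold
  and is flagged.

Validation follows detection-precision scoring: predictions matched to
ground truth greedily by descending IoU, one-to-one, a match requiring
IoU ≥ 0.5 (the matching rule is our choice; the precision bars come from
the workflow being emulated).  On the standard five-field set both
nucleus and glomerulus precision measure 100%, clearing the 90% / 93%
bars.

## Quantification

A spot belongs to the territory label and glomerulus label at its rounded
pixel; out-of-bounds spots are excluded and tallied.  A cell is
glomerular iff its nucleus-centroid pixel carries a glomerulus label
(boundary pixels count as inside).  These single-pixel rules make
conservation exact: per channel, Σ per-cell counts + unassigned = spots
in bounds, and intra- + extraglomerular area = frame area.

Normalized expression is the per-cell ratio target/reference; cells with
zero reference count have undefined normalized expression and are
excluded from normalized statistics while remaining in raw tables.  This
is the only definition consistent with reporting "normalized
transcripts per cell"; note its population mean is the mean of ratios,
not the ratio of class means.  Podocytes are marker-positive
intraglomerular cells (DAPI positivity is implied by having a segmented
nucleus).  Per glomerulus we export tuft area, maximum-caliper (Feret)
diameter over pixel centers + 1 px (so a single-pixel object is one
pixel pitch wide, not zero), podocyte count and density per mm² of tuft
cross-section.

## Reference-gene stability

Candidate reference genes are scored on log2 genes × samples matrices by
a model-based variance decomposition: y_igj = α_ig + β_gj + ε_igj with
Var(ε) = σ²_ig.  Within each group, two-way centering removes gene and
sample (array) effects — hence stability values are invariant to adding
a constant to any sample column.  The naive residual variances m_ig are
biased by centering over the finite gene ensemble
(E[m_ig] = σ²_ig (I−2)/I + σ̄²_g/I for I genes), giving the corrected
estimate σ̂²_ig = I/(I−2) · (m_ig − m̄_g/(I−1)), floored at 0; this is why
at least three genes are required.  Group effects d_ig (gene-centered
within groups, centered over groups) are modelled as draws from a
zero-mean ensemble prior with per-group variance γ²_g estimated across
the candidate genes, γ̂²_g = max(Σᵢ d²_ig/(I−1) − mean_i η_ig, 0), where
η_ig is the sampling variance of d_ig implied by σ̂²_ig.  The stability
value averages the shrunken group effect and its standard error,
ρ_i = mean_g(|d_ig| γ̂²/(γ̂²+η_ig) + sqrt(γ̂² η_ig/(γ̂²+η_ig))); lower is
more stable.  Estimating the prior across the ensemble (rather than per
gene) is essential: a per-gene variance floored at zero would grant a
noisy but unshifted gene a stability of exactly 0.  With a single group
the score reduces to the bias-corrected SD of the sample-centered
residuals.  Ranking is ascending stability with ties broken by gene
name.  A linear-scale loader applies log2(x + 1).

The implementation is checked against an independently loop-coded
oracle of the same equations to 1e-10, and recovers a designed stable
gene (4× SD ratio) as rank 1 in 100 of 100 seeded matrices.

## Statistics and density maps

`compare_groups` implements the normality-gated decision tree: per-group
normality by the Lilliefors-corrected KS test at α = 0.05 (mean and SD
are estimated from the sample, so plain KS would be anti-conservative;
for n < 4, where no table exists, the plain KS fallback is essentially
powerless and such groups route parametric).  Two normal groups → Welch
t; two non-normal → Mann–Whitney U (this branch is our addition — the
original tree leaves it unspecified); more groups → one-way ANOVA with
Dunnett's comparisons against a designated control (parametric) or
Kruskal–Wallis with Dunn's all-pairwise rank z-tests, tie-corrected,
Bonferroni-adjusted (non-parametric).  Dunn's — not Dunnett's — is the
standard partner of Kruskal–Wallis; the source workflow's pairing of KW
with "Dunnett's" is treated as a misnomer.  Each comparison row carries
both unadjusted and adjusted p (adjusted ≥ unadjusted).  KW type-I error
under a 3-group null measures 5% ± 2% over 1000 replicates.

Co-expression uses OLS with the pointwise 95% confidence band of the
mean response (narrowest at x̄).  Transcript density surfaces are
Gaussian-kernel intensity maps in the spatial point-pattern convention
(integral ≈ point count; units points/µm²); bandwidth defaults to the
normal-reference rule on the point set, kernel mass outside the extent
is truncated (documented undershoot for edge points), and an empty point
set yields a zero surface with a warning.

## Filtration-slit density

FSD = skeleton length / region area (µm⁻¹).  Binarization is smoothing →
Otsu (overridable) → small-object removal; the mask is intersected with
the region, skeletonized, and edge lengths summed: 1 px per orthogonal
step, √2 per diagonal step, with diagonal steps skipped when the two
pixels share an orthogonal skeleton neighbour (no staircase
double-counting); isolated pixels contribute zero.  Against closed-form
meander fixtures the measured length is within 1%, and on parallel-line
fixtures over whole periods FSD converges to 1/spacing.  The dimensional
law (doubling the pixel pitch halves FSD) holds exactly.  Regions are
supplied as masks (e.g. glomerulus labels); no automatic exclusion of
unmeasurable areas (vessels, folds) is attempted — a known limitation
relative to full morphometry protocols.

## Batch pipeline, determinism, problem sizes

Batch mode processes every TIFF in a directory (mask files excluded by
suffix), logging and skipping per-file failures, failing only when
nothing was processable, and writes cells/summary/gloms CSVs sorted by
(image_id, cell_id) plus the resolved config YAML — identical inputs and
config give byte-identical outputs regardless of listing order.  All
randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give identical images, tables and statistics.

Test and validation problem sizes (five 1024² validation fields, 200-spot
SNR-5 fields, 20 conservation scenes at 256², 100 reference-gene
matrices, 1000-replicate calibration) were chosen so the full suite runs
in well under a minute per criterion on a single CPU while keeping
sampling error far from the asserted margins.
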