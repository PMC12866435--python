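# Methods

`evtricoloc` quantifies how fluorescently labeled extracellular vesicles
(EVs) interact with the cell types of mixed cortical cultures, from
confocal z-stacks through condition-level statistics. This note documents
the measurement model, every tunable that matters, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the procedure was genuinely open.

## Image quantification model

A field of view is a z-stack (default 12 slices, 1.24 µm apart) with up to
five channels: DAPI (nuclei), GFAP (astrocytes), β-tubulin (neurons), Iba1
(microglia; absent in co-culture), and CFSE (dye-labeled EVs). Different
cell types layer at different depths, so all quantification happens on the
maximum-intensity projection.

**Cell-type ROIs.** Each marker channel is smoothed with a disk-shaped
mean filter of radius 5 px (the disk, not a square, matches the "radius"
semantics of ImageJ-style macros; borders use edge replication) and
thresholded. The threshold method is Otsu by default — the common choice
for bimodal marker channels — and is overridable per run (`li`,
`triangle`, or a fixed value). Because the Iba1 channel spills into the
GFAP and β-tubulin channels, the Iba1 ROI is subtracted from both:
`gfap ← gfap \ iba1`, `btub ← btub \ iba1`. The non-cell background mask
is the complement of the union of all ROIs including DAPI. DAPI itself is
never a colocalization target; it exists for the background mask and for
nuclei counting.

**CFSE⁺ detection.** The CFSE background is the mean and SD of non-cell
pixels (at least 100 px required, configurable). A pixel is CFSE⁺ when
`(I − bg_mean) > k·bg_sd`, with k = 3 by default; the rule ties positivity
to the measured non-cell autofluorescence of each image. A fixed global
threshold is available instead. CFSE⁺ pixels are grouped into 8-connected
components (the Analyze-Particles default), and components strictly larger
than 60 px are removed: large autofluorescent debris is rare but bright,
while genuine EV puncta are small. "Over 60 pixels" is read literally — a
60-px object is kept, a 61-px object is not.

**Colocalization.** For each cell type T, `coloc_px(T) = |CFSE⁺ ∩ ROI(T)|`
is reported two ways: normalized to the ROI area (`coloc_px / area(T)`,
the per-type interaction density used for condition comparisons) and as
the share of total CFSE⁺ area (`coloc_px / |CFSE⁺|`, the quantity the
simulator plants directly). A type whose ROI is empty is reported as
missing, not zero; images without microglia are excluded from Iba1
summaries only.

**Rotation null.** Pixel overlap is not specific by itself: two
independent signals that each cover 50% of the field still overlap 50%.
The specificity control rotates one channel 90° about the image center
(default: the cell-type mask, counter-clockwise; both are configurable —
for independent signals the expectation is invariant to the choice) and
re-measures colocalization. Non-square rasters are center-cropped to the
largest centered square before rotation so the rotation is a bijection of
pixels.

**Control subtraction and outliers.** Condition summaries subtract the
PBS-control mean from every condition ("background subtracted using the
average of the PBS sample"), and a condition is flagged as exceeding
controls only when its mean exceeds both the PBS and the dye-only (CFSE)
control means. Images with anomalous non-cell CFSE background are flagged
by an iterative two-sided Grubbs test at α = 0.05 on the per-image
background means, excluded from summaries but retained (flagged) in the
per-image table. Grubbs was chosen over ROUT because the screened variable
is a single well-behaved scalar per image; the method name is recorded in
the output so the choice is auditable.

## Cytokine panel

The 27-plex workflow operates on a long table of
(cytokine, experiment, culture, treatment, replicate, concentration, LOD):

1. **Inclusion.** A cytokine is kept only if at least 3 replicates exceed
   the limit of detection in *every* experiment (any condition counts).
   The rule is undefined for single-experiment tables, which are rejected.
2. **Imputation.** Below-LOD values of retained cytokines are replaced by
   LOD/2 (configurable: LOD or LOD/√2). This is the common multiplex-panel
   convention; the analysis does not otherwise use censored values.
3. **Normalization.** Concentrations are divided by the mean of the PBS
   controls of the same cytokine and experiment, with co- and tri-culture
   controls pooled (the clustering path) or kept separate (the
   direct-comparison path). Per-experiment normalization removes the
   experiment-level offsets that motivated it in the assay design.
4. **z-scores** are computed within each cytokine across all samples
   (sample SD, n−1). Zero-variance cytokines are flagged, not dropped
   silently.
5. **Clustering** is agglomerative with correlation distance
   (d = 1 − Pearson r) and average (UPGMA) linkage, on replicate columns
   or on group-averaged columns (`aggregate=True`, the
   heatmap-of-average-z presentation). Pearson rather than Spearman is
   the named default of clustergram facilities. Leaf order is plain
   dendrogram order — optimal-leaf reordering is disabled for
   determinism. Trees export as Newick; heatmaps as PNG/SVG.

## Viability

**Nuclei counting:** mean filter of radius 1, Otsu threshold,
distance-transform watershed seeded at local maxima (minimum peak
separation 5 px) to split touching nuclei, then a minimum-size filter of
10 px. The minimum size and peak separation are simulator-calibrated
choices; the protocol source states neither. Percent dead is
100·(PI count)/(Hoechst count).

**LDH cytotoxicity:** each well is corrected as A490 − A680, then
`% = 100·(A_treated − mean A_control)/(mean A_lysis − mean A_control)`,
anchoring untreated wells at 0% and fully lysed wells at 100%. Some
protocol texts write the denominator as control minus lysis, which merely
inverts the sign whenever lysis exceeds control; that literal variant is
available behind `literal_denominator=True`.

## Statistics

- **Welch ANOVA** (hand-coded closed form with precision weights and
  Welch–Satterthwaite df; reduces to the squared Welch t with two groups)
  and the **Brown–Forsythe** test (one-way ANOVA on |x − group median|)
  for heteroscedastic group comparisons.
- **Two-way ANOVA** with type II sums of squares, because the designs are
  unbalanced (3–4 wells per condition); the interaction is dropped when
  every cell has a single observation.
- **Multiple t-tests with discovery:** per-comparison Welch t, then the
  two-stage linear step-up FDR procedure (Benjamini–Krieger–Yekutieli) at
  Q = 0.05 marks discoveries. This is an interpretation of
  "multiple t-test, * = discovery, Q = 0.05" as implemented by common
  analysis software; it is checked against a hand-rolled two-stage
  step-up in the tests.
- **Design arithmetic:** percent reduction 100·(max − min)/max, e.g.
  incubation times {240, 60, 20} min → 91.7%, concentrations
  {7.5×10⁹, 1.5×10⁹} particles/mL → 80%.

## Synthetic scenes: what they emulate, and what they do not

The generator exists so every stage is testable against known truth
without any raw imaging data. A default scene is 512² px (0.62 µm/px),
12 z-slices, with:

- **nuclei** as disks of radius 7–10 px (~10 µm at this magnification);
- **astrocytes** as multi-lobed blobs grown until ~20% field coverage;
- **neurons** as persistent random walks dilated to ~7-px-wide fascicle
  bundles, grown to ~35% coverage — deliberately dense, reproducing the
  low signal-to-noise of neuronal colocalization that makes neuron
  specificity hard to establish on real data;
- **microglia** as a few compact blobs (~3% coverage), omitted in
  co-culture scenes;
- **CFSE puncta** as Gaussian spots (σ = 1.5 px, amplitude 800 over a
  background of 100) with compact support truncated at the 2σ level, so a
  punctum's rendered footprint is exactly its 2σ disk and noiseless
  recovery is well defined. Puncta are assigned to cell types at
  configurable fractions (defaults 0.35 GFAP, 0.35 β-tubulin, 0.05 Iba1,
  remainder unbound on background); assigned centroids are sampled from
  the eroded type mask so footprints lie fully inside. A `uniform`
  placement mode ignores assignments for null-calibration studies;
- **debris** as 3 bright disks of radius 9 px (~254 px area), strictly
  above the 60-px gate by construction;
- **noise**: Poisson photon noise plus Gaussian read noise (SD 5);
  every object has a focal plane and spreads across z with a Gaussian
  profile (σ = 1.5 slices).

Coverage targets and puncta fractions are simulator choices, not measured
values. Object sizes were chosen to be physically realistic at 20x with
1.67x zoom; structures much thinner than the 5-px smoothing radius (e.g.
single 1-µm neurites) cannot be recovered faithfully by the protocol's
smooth-then-threshold ROI construction, so the simulator draws fascicle
bundles rather than individual processes. The generator does not attempt
optics-accurate PSF simulation, realistic intracellular texture,
chromatic registration errors, or photobleaching; passing tests therefore
demonstrate correctness of the measurement arithmetic and robustness at a
realistic SNR, not performance on arbitrary real-world image quality.

Replicate emulation elsewhere: cytokine tables are log-normal with
per-(cytokine, experiment) offsets (removed by the normalization path, as
in the real design), multiplicative group effects, and an LOD censoring
flag; the default inflammatory scenario shifts 10 of 27 cytokines 3-fold
in all tri-culture groups. Plates interpolate treated wells between
control (0.30 corrected) and lysis (1.30 corrected) absorbances according
to planted cytotoxicity. Live/dead pairs place non-overlapping nuclei
with a dead subset in the PI channel.

All randomness flows from the single seed of each generator call. The
CLI derives per-stage child seeds as `(seed·1000003 + stage_index) mod 2³¹`.

## Problem sizes used in the checks

The bundled verification (`scripts/acceptance.py`, mirrored by the
end-to-end tests) uses 20 full-size scenes for recovery, 100 scenes of
256² for null calibration, 200 simulated panels for the co/tri clustering
split, and 1000 replicates for the Welch type-I-error and FDR
calibrations — sizes at which the binomial/standard errors of the checked
rates are a few percent or less.

## Known limitations

- Pixel-overlap colocalization is area-based; intensity-weighted
  coefficients (Pearson/Manders) and 3-D colocalization are out of scope.
- The ROI construction is not per-cell instance segmentation; per-type
  areas aggregate all cells of a type.
- The Grubbs outlier screen assumes approximately Gaussian background
  means across images.
- The two-stage FDR "discovery" interpretation and the Otsu default are
  reasoned reconstructions of under-specified steps in the original
  protocol; both are configurable and recorded in the outputs.
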