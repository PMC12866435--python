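# evtricoloc

Quantification of fluorescently labeled extracellular-vesicle (EV) uptake
and cell-type targeting in mixed cortical cultures, from confocal
z-stacks to condition-level statistics.

When cancer-derived EVs are incubated with primary brain cultures
(neurons + astrocytes, with or without microglia), the basic questions
are: how much dye-labeled EV signal ends up in each image, which cell
types does it sit on, is that overlap *specific* or just coincidence from
high coverage, and do the EVs change cytokine output or kill cells? This
package implements that entire measurement chain as a tested, scriptable
library for imaging scientists who would otherwise re-build it as a
one-off ImageJ macro plus spreadsheet:

- **Segmentation** — maximum-intensity projection; per-marker disk mean
  filter (radius 5 px) and automatic thresholding into cell-type ROIs
  (GFAP = astrocytes, β-tubulin = neurons, Iba1 = microglia, DAPI =
  nuclei), with the Iba1 ROI excluded from GFAP/β-tubulin to remove
  channel spillover.
- **Uptake** — CFSE⁺ pixels are those exceeding the non-cell background
  by k·SD (k = 3); 8-connected components larger than 60 px are gated out
  as autofluorescent debris. Colocalization with a cell type T is the
  pixel overlap |CFSE⁺ ∩ ROI(T)|, normalized to area(T). Specificity is
  judged against a randomization null in which one channel is rotated 90°
  about the image center — two independent signals with 50% coverage
  still overlap 50%, and the null measures exactly that coincidental
  overlap. Condition summaries subtract the PBS-control mean; anomalous
  images are flagged by a Grubbs test on non-cell background intensity.
- **Cytokines** — 27-plex panel workflow: keep a cytokine only if ≥3
  replicates exceed the LOD in every experiment; normalize to the PBS
  controls within each experiment; z-score within each cytokine; cluster
  with correlation distance (1 − Pearson r) and average (UPGMA) linkage.
- **Viability** — live/dead nuclei counting (mean filter radius 1,
  threshold, watershed, size filter; % dead = 100·PI/Hoechst) and LDH
  cytotoxicity (A490 − A680, scaled between untreated and lysed controls).
- **Statistics** — Welch ANOVA, Brown–Forsythe, type-II two-way ANOVA,
  and multiple Welch t-tests with two-stage step-up FDR discoveries at
  Q = 0.05.
- **Synthetic scenes** — a first-class generator of confocal-like
  z-stacks (nuclei, astrocyte blobs, neuron fascicles, sparse microglia,
  CFSE puncta planted at known per-type fractions, oversized debris),
  cytokine tables and plates, all with ground truth, so every stage is
  verifiable without any raw data.

See `docs/methods.md` for the measurement model, defaults and their
rationale, and the simulator's scope.

## Worked example

Generate one synthetic tri-culture field of view, run the full per-image
quantification, and compare against the planted truth:

```python
from evtricoloc import (SceneConfig, generate_scene, max_project,
                        build_cell_masks, measure_uptake)

stack, truth = generate_scene(SceneConfig(seed=42))
proj = max_project(stack)
masks = build_cell_masks(proj)
m = measure_uptake(proj, masks, image_id="demo")

print(f"CFSE+ area: {m.total_cfse_area_px} px "
      f"({m.n_objects} puncta kept, {m.n_gated} debris object(s) gated)")
for t in ("gfap", "btub", "iba1"):
    c = m.coloc[t]
    print(f"{t:5s} share of CFSE area = {c.cfse_fraction:.3f} "
          f"(planted {truth.true_cfse_fraction[t]:.3f}), "
          f"observed/area = {c.normalized:.4f}, "
          f"rotation null = {m.null_coloc[t].normalized:.4f}")
```

prints

```
CFSE+ area: 2473 px (143 puncta kept, 3 debris object(s) gated)
gfap  share of CFSE area = 0.384 (planted 0.391), observed/area = 0.0183, rotation null = 0.0054
btub  share of CFSE area = 0.468 (planted 0.448), observed/area = 0.0089, rotation null = 0.0090
iba1  share of CFSE area = 0.052 (planted 0.051), observed/area = 0.0141, rotation null = 0.0135
```

Reading it: the pipeline recovers the planted per-type CFSE shares within
about a point. For astrocytes the observed area-normalized colocalization
(0.0183) is ~3× its rotation null (0.0054): the overlap is specific. For
neurons the observed value equals the null — their ~35% field coverage
makes pixel overlap uninformative, which is precisely what the rotation
control is for.

A command-line interface mirrors the library
(`evtricoloc simulate|uptake|cytokines|viability|stats|all`), e.g.

```bash
evtricoloc all --seed 3 --out run/     # simulate, then run every stage
evtricoloc uptake --images scenes/ --out results/
```

Each run writes its tables as CSV plus a JSON manifest with the config
hash and seed; identical config + seed reproduce identical tables.

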