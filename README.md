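# traffiq

Quantitative downstream analysis for high-content screens of insulin-
stimulated GLUT4 and transferrin-receptor (TfR) trafficking in adipocytes,
plus bait-vs-IgG AP-MS interactome scoring.

High-content assays that stain surface-exposed GLUT4 on non-permeabilized
adipocytes produce per-cell intensity tables spanning many plates,
treatments and time points. Turning those tables into biology requires a
chain of statistics: gating adipocytes away from undifferentiated
fibroblasts, putting plates on a common intensity scale, and fitting
dose–response and kinetic models. `traffiq` implements that chain as a
tested library, together with seeded synthetic-data generators that emulate
the assay (so every stage can be validated against known ground truth) and
the matching analysis for affinity-purification proteomics of trafficking
regulators.

## Models at the core

- **Anchored plate normalization.** For plate *i* with control-well medians
  `med0_i` (0 nM insulin) and `med100_i` (100 nM), and cross-plate anchors
  `maxmed0 = max_i med0_i`, `maxmed100 = max_i med100_i`:

  `Xnorm_i = (X_i − med0_i) · (maxmed100 − maxmed0) / (med100_i − med0_i) + maxmed0`

  so every plate's control medians map exactly onto the common anchors;
  log2 of the normalized values feeds the single-cell distribution views.
- **3-parameter Hill dose–response** (slope fixed at 1):
  `R(d) = Bottom + (Top − Bottom)·d/(EC50 + d)` for stimulation, and the
  mirrored `IC50/(IC50 + c)` form for inhibition, fitted by multistart
  least squares; shared-vs-independent curve comparison by AIC.
- **One-phase association kinetics**
  `S(t) = S0 + (Splateau − S0)(1 − e^{−kt})`, reported as `t1/2 = ln2/k`.
- **Screen summaries**: well-level means → per-condition mean ± SD and
  fold-over-control (FOC) per readout (GLUT4, TfR, nuclei/field, lipid
  droplets), and simple linear regression of knockdown effects across cell
  lines (slope, r², p).
- **AP-MS enrichment**: MaxQuant-style protein-groups filtering, log2
  median normalization, condition-averaged IgG controls, two-step
  imputation (within-condition Normal, then downshifted Normal
  `(mean − 1·SD, 0.6·SD)` for IgG), per-condition t tests with
  Benjamini–Hochberg correction, and "insulin-regulated" calls for proteins
  with `|Δlog2FC| > 2·MAD`, `log2FC > 2` and adjusted p ≤ 0.05.

## Worked example

```bash
python analysis/02_dose_response.py
```

```
                        analysis    parameter  value       se
             insulin stimulation    EC50 (nM) 0.8605  0.01899
              GDC0941 inhibition    IC50 (nM)  7.912   0.1755
               MK2206 inhibition    IC50 (nM)  182.1    4.934
chronic insulin resistance model    IC50 (nM) 0.1665 0.005283
            TNF resistance model IC50 (ng/ml)  0.176 0.005547
```

Each row is a full pipeline run on a synthetic plate experiment: cells are
generated with the named preset (≈2 000 adipocytes per dose plus plate
gain/offset batch effects and a 10 % fibroblast subpopulation), gated by
the automatic lipid-scatter split, plate-normalized against the control
anchors, summarized to per-dose well means and fitted. The insulin EC50 of
0.86 nM says half-maximal GLUT4 delivery to the plasma membrane occurs well
below 1 nM insulin; the PI3K inhibitor GDC0941 suppresses the response with
an IC50 near 8 nM, the Akt inhibitor MK2206 near 183 nM; and chronic
insulin or TNF exposure half-suppress the 1 nM insulin response at 0.17 nM
and 0.18 ng/ml respectively — each matching the generating parameter of its
preset. The other drivers follow the same pattern: `03_kinetics.py`
(GLUT4 t1/2 ≈ 7.6 / 9.7 min at 100 / 1 nM insulin, TfR t1/2 ≈ 3.1 min, basal
surface TfR ≈ 35 % and GLUT4 ≈ 6.6 % of maximum), `04_screen.py`
(a 0.4× knockdown effect recovered as FOC 0.407) and `05_interactome.py`
(20/20 planted insulin-regulated interactors recalled, 1 false label in
1 000 proteins). Outputs land in `results/`.

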