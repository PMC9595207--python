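# Methods

## Scope and data model

`traffiq` starts where image analysis ends: one row per segmented cell
(plate, well, field, cell id, surface-GLUT4 and surface-TfR intensities in
arbitrary fluorescence units (AFU), a lipid-scatter score, and optional
total-reporter and lipid-droplet columns), joined to a well-condition map
(insulin dose, inhibitor and dose, chronic pretreatment and dose, siRNA
target, time point, and a control role marking each well as a 0 nM or
100 nM insulin normalization anchor or as a sample). Segmentation,
illumination correction and background subtraction are upstream concerns;
the pipeline assumes they have been done.

## Synthetic-data generator

Because the raw imaging data behind the assay are not redistributable, the
package ships generators that emulate the statistical structure every
downstream stage assumes, and they are first-class, tested code. The plate
generator draws, for each well:

- a true adipocyte mean response
  `kd · (basal + (max − basal) · stim(d) · inhib(c) · pretreat(q) · time(t))`
  where `stim` is a slope-1 Hill function of insulin dose (default EC50
  0.86 nM), `inhib`/`pretreat` are inhibitory Hill factors for named
  compounds (registered IC50s: GDC0941 8 nM, MK2206 183 nM, GDC0068 121 nM,
  GSK23344 289 nM; chronic insulin 0.17 nM, TNF 0.18 ng/ml), `time` is the
  one-phase factor `1 − 2^(−t/t1/2)` (absent for steady-state wells), and
  `kd` is a per-readout siRNA multiplier;
- per-cell multiplicative lognormal noise with mean exactly 1 and CV 0.35
  (the strictly positive, right-skewed single-cell histograms the assay
  produces), a per-plate gain `~N(1, 0.1)` and additive offset
  `~N(0, 1 AFU)`, plus half-normal read noise (SD 1 AFU). Offset and read
  noise are deliberately sub-percent of the 1 000-AFU full scale,
  representing residual background after upstream correction;
- a Poisson cell count per well (mean 500) and a 10 % fibroblast
  subpopulation (at least 90 % of cells differentiate in this protocol)
  that draws from the basal intensity distribution regardless of any
  stimulus and from a low lipid-scatter mode (0.2 vs 0.9, SD 0.08).

Named presets pin the generating parameters to the study's reported values
(EC50 0.86 nM; GLUT4 half-times 7.5 / 9.5 min at 100 / 1 nM insulin; TfR
half-time 3 min and GLUT4 9 min in the dual-channel preset; basal surface
occupancy 35 % of maximum for TfR and 6.5 % for GLUT4; a fivefold
fold-over-basal; a 0.4× knockdown effect), with the provenance recorded in
`PRESET_CITATIONS`. The dual-channel basal/kinetics preset is single-plate,
matching the single-experiment panels it emulates. Every generator returns
a ground-truth record, and identical (config, seed) pairs are bit-identical;
all randomness flows through one `numpy` generator per call.

What the generator does *not* emulate: spatial effects within wells,
illumination gradients, segmentation errors, cell-cycle or
differentiation-stage covariates, correlations between channels beyond the
shared well mean, and day-to-day biological drift beyond a scalar
gain/offset. Passing tests therefore demonstrate that the statistics
recover parameters under the assumed noise model, not that the model
captures every failure mode of real plates.

The IP-MS generator draws per-protein log2 background abundances
`~N(25.5, 1.8)`, adds a +4 log2 bait-enrichment effect to 8 % of proteins
and a further +2.5 under insulin to 25 % of those, and applies replicate
noise whose SD rises from 0.30 to 0.75 as intensity approaches the
detection limit — the hallmark of label-free quantification. Missingness is
logistic in true log2 intensity (midpoint 22, slope 1), the
missing-not-at-random pattern that downshifted imputation assumes. Decoy /
contaminant / site-only flags mark a 2 % background fraction to exercise
the filters; flags are confined to background rows so the planted truth
remains recoverable. Three replicates per (bait/IgG × basal/insulin)
condition mirror the study design.

## Gating and QC

Adipocytes are separated from fibroblasts and necrotic cells by
thresholding the lipid-scatter score. The default threshold is the
two-class minimum-within-class-variance (Otsu) split of the scatter values
pooled over control wells only — computing it on controls avoids
treatment-induced bias — then applied to all wells; a fixed threshold is
available for reproducibility. Gating is global across plates by default
(the per-plate question is genuinely open; per-plate gating can be had by
calling the gate per plate subset). Wells with fewer than 50 gated
adipocytes fail QC and are excluded from all summaries; exclusions are
logged, never silently dropped.

## Normalization conventions

Plate anchors use cells pooled across all control wells of a plate (not
per-well medians), with the even-count median as the midpoint mean. The
implemented map is the unique linear transform sending `med0_i → maxmed0`
and `med100_i → maxmed100` — the defining property of the anchored
normalization. Cells whose normalized intensity is
non-positive are excluded from the log2 column with a logged count rather
than floored — flooring would pile mass at an arbitrary left edge of the
single-cell histograms. The exclusion count is surfaced so the alternative
convention can be compared.

## Curve fitting

Hill fits use Bottom/Top/EC50 with the slope fixed at 1 — the standard
three-parameter agonist model; no slope was ever reported for this assay,
and a free-slope variant would trade bias for variance at 8-point designs.
Fits run on summary responses per dose (well means), not per-cell values.
Multistart initialization places the half-maximal dose at every observed
non-zero dose plus their geometric mean, with Bottom/Top at the observed
extremes; the best-RSS solution wins, and non-convergence is flagged, never
silently defaulted. Standard errors come from the Jacobian at the optimum;
the half-time SE uses the delta method on the rate constant.

AIC is `n·ln(RSS/n) + 2k` (not AICc, matching how the comparison is usually
reported for these designs). The shared-vs-independent comparison scores
*both* models on the pooled residuals under a common Gaussian error
variance — k = 3m for m independent curves, k = 2m + 1 when the
half-maximal dose is shared. Summing per-dataset AICs instead would imply a
separate error variance per dataset and is biased toward the independent
model by the concavity of `n·ln(RSS)` irrespective of the noise level, so
the pooled form is the package's default and only mode.

An ambiguity worth recording: whether curves were historically fitted per
experiment and averaged, or pooled, is unclear from figure legends. The
pipeline fits per-condition summary means; per-experiment fitting is a thin
loop over the same function and the spread of fitted parameters is reported
by the standard errors.

## Screen summarization and population views

Wells, not cells, are the unit of replication: per-condition SDs over well
means would otherwise be underestimated by orders of magnitude at ~500
cells/well. Fold-over-control divides each condition mean by the
non-targeting control mean within the same insulin-dose × cell-line
stratum, which cancels plate gain after normalization. Inference across
targets uses two-sided Welch tests with Benjamini–Hochberg correction per
readout — an explicit, simpler substitute for repeated-measures
ANOVA/Dunnett machinery, labelled as such, not a reproduction of it.

Kernel densities of log2 normalized intensities use Gaussian kernels with
Silverman's bandwidth; a shared evaluation grid (and optionally a shared
bandwidth) makes curves comparable across conditions within a figure. The
trapezoidal integral over the grid (which extends 4 bandwidths past the
data) is checked to be 1 within 1e−3. The population shift metric is
`(median(condition) − median(basal)) / (median(insulin-like) − median(basal))`,
affine-invariant and anchored at 0 (basal-like) and 1 (insulin-like); for
resistance titrations the insulin-like anchor is the uninhibited population
at the *same* acute insulin dose, so half-suppression reads as 0.5.

## Interactome analysis

Filtering removes decoy ("Reverse"), contaminant and site-only rows, then
proteins with fewer than two quantified values in *every* bait condition —
the default reading of an ambiguous rule; the pooled "across all bait
samples" reading is implemented behind `sparse_rule="across_all"`.
Median normalization shifts each sample's log2 median to the grand median
of sample medians, preserving the pooled scale. IgG replicate r is the mean
of its basal and insulin measurements (a single present partner is carried
forward — the unstated case), and the merged IgG set serves as the control
for both bait conditions, which also makes the insulin − basal fold-change
difference independent of IgG noise.

Imputation is two-step: within a protein × condition group with ≥ 2
quantified replicates, missing values are drawn from Normal(mean, SD) of
the quantified ones; remaining missing values in IgG controls only are
drawn per sample from Normal(sample mean − 1·SD, 0.6·SD) — the downshifted
left tail that MNAR dropout implies. Proteins still incomplete after both
steps (e.g., a bait condition quantified once) are excluded from testing
and reported. Tests are equal-variance two-sample t tests (the convention
of the standard proteomics toolchain; Welch is a flag), BH-corrected within
each condition (pooled adjustment by flag).

The regulation call uses the raw MAD — no 1.4826 normal-consistency factor,
since none was specified — of Δ = log2FC(insulin) − log2FC(basal) across
all tested proteins. "Insulin-regulated" requires |Δ| > 2·MAD, log2FC > 2
in at least one condition, and adjusted p ≤ 0.05 in that same condition;
Δ is signed insulin − basal. Each clause's reading is configurable; these
are the defaults and the ones the tests pin down.

## Numerical and testing choices

Degenerate inputs fail loudly: identical scatter values (no separable
classes), non-responsive plates (`med100 ≤ med0`), degenerate min/max
anchors, all-equal kinetic responses, zero-variance t tests, and fewer than
3 tested proteins for the MAD all raise or flag rather than return numbers.
Problem sizes in the test and acceptance workflows — ~2 000 gated
adipocytes per condition, 2 plates, 8-point dose/time grids, 1 000-protein
matrices — are the package's chosen working scale: large enough that
summary-level Monte-Carlo error sits well inside the 15–20 % recovery
tolerances, small enough to iterate quickly. Recovery checks compare fitted
parameters against the generating values; distributional checks use ~3
Monte-Carlo-SE tolerances with SEs estimated from the data, not assumed.

## Known limitations

Single-cell fitting, mixed-effects dose–response models, per-plate gating,
spatial/illumination artefacts and real MaxQuant quirks (MaxLFQ ratio
compression, match-between-runs) are out of scope. The lognormal per-cell
noise family is an assumption validated only against the pipeline's own
invariants — no parametric family was ever reported for these
distributions. The interactome module scores synthetic matrices; it does
not attempt to reproduce any published interactor list, which would require
the deposited raw data.
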