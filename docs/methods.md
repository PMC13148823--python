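# Methods

## The model

The package implements the quantitative skeleton of a tissue-bioenergetics
comparison between two groups (here benign mammary tissue and HER2-driven
tumors). Its central object is the per-state oxygen flux ladder from
high-resolution respirometry, and its central operation is the three-way
normalization that disentangles *how much* mitochondria a tissue has from
*how hard* each unit of mitochondria works:

1. **Wet weight.** Flux per mg tissue, as measured. Sensitive to tissue
   density, hydration and fat content.
2. **Total protein.** Flux divided by the group-mean Bradford factor
   (µg protein per mg wet weight). Removes density/hydration effects.
3. **Mitochondrial content.** The total-protein value divided by the group
   mitochondrial enrichment factor, MEF = Σ mito protein / Σ total protein,
   from label-free proteomics with MitoCarta-style mitochondrial flags.

The identity worth keeping in mind: flux per wet weight divided by
(protein factor × MEF) is flux per unit *mitochondrial protein*. If a group
difference survives MEF normalization it cannot be explained by
mitochondrial content.

## Respirometry model and flux estimation

Within each respiratory state, chamber O2 (µM = nmol ml⁻¹) is assumed to
decline linearly; the state flux is the OLS slope over an analysis window,
converted by chamber volume (default 2 ml) and sample amount. Windows start
`discard_s` (default 30 s) after each injection — a declared
mixing/stabilization allowance; the instrument literature reports
steady-state fluxes without stating windows — and span `window_s` (default
60 s), truncated at the next event. The pre-first-event segment is the
endogenous state E and receives the same initial discard. States whose
interval is consumed by the discard are flagged missing, never silently
dropped. Raw-window OLS is used deliberately instead of any vendor slope
smoothing; for noiseless piecewise-linear traces the estimate is exact and
independent of the sampling interval.

Composite state names concatenate substrate additions
(PM → PMD → PMDG → PMDGS, → PMDGSC with cytochrome c); inhibitor events
open fresh states OMY, AMA and AMA_ROT, matching the figure vocabulary.
Coupling metrics reference the maximal pre-oligomycin composite (PMDGSC
when cytochrome c was added, else PMDGS). Technical replicates are pooled
by arithmetic mean into one biological row; the replicate-level table is
retained. Negative fitted fluxes are kept and flagged rather than clamped,
preserving the noise structure for downstream statistics.

## The synthetic study

The generator emulates the study's data structure with known ground truth;
its preset (`data/presets.yaml`, version 1) *is* the study condition set:

* Ground-truth flux ladders per group, with tumor/benign PMDGS = 70/10
  pmol s⁻¹ mg⁻¹ (ratio 7.0, inside the reported 4.9–9.9× wet-weight
  band) and a lipid ladder with MDPC ratio 8.3.
* Oligomycin coupling fractions 0.80 (tumor) and 0.55 (benign); 2%
  antimycin A + rotenone residual.
* Chamber loadings 3 mg (tumor) and 18 mg (benign), matching the reported
  2–5 / 15–20 mg ranges; O2 starts at 180 µM; 2 s sampling; 240 s per
  state; two technical replicates per sample.
* Trace noise: i.i.d. Gaussian, sd 0.2 µM, on the O2 readings. Biological
  variability: a per-sample lognormal factor on the whole ladder with
  CV 0.30, consistent with the reported 23–46% CVs; the factor is shared
  across technical replicates.
* Proteome: 1000 log-normal features, 15% mitochondrial (the full
  36/4/9/16/19 OXPHOS subunit block plus mito filler), natural-log noise
  sd 0.25 around per-feature baselines shared between groups. Tumor
  mitochondrial abundances are scaled by `content_scale` = 0.65 (content
  loss), plus an optional extra `mito_log2fc`.
* Bradford factors 40 (benign) vs 100 (tumor) µg protein per mg wet
  weight: benign mammary tissue is adipose-rich and protein-poor. Together
  with the content scale this puts the preset's MEF-normalized fold change
  near 4×, i.e. inside the ~2–4-fold intrinsic increase the wet-weight and
  content numbers imply.
* Detection dropout rate 0.25 per feature×sample (the observed
  unique/shared Venn proportions are ~25–30% unique). Two modes:
  `uniform` (abundance-independent Bernoulli, the default — simplest model
  whose mask is exactly enumerable in tests) and `censor` (the lowest
  quantile of each sample's intensities falls below a detection limit),
  which is what actually produces group-exclusive detection sets once
  group shifts are present.
* Transcriptome: log-normal expression normalized to TPM (columns sum to
  10⁶ exactly); tumor OXPHOS blocks shifted per complex
  (CI −1.0, CII −0.8, CIII −1.0, CIV −0.9, CV −0.6 log2).
* Cell-type tables: six IF-harmonized types (epithelial, mesenchymal,
  myeloid, T, endothelial, plasmablasts) with reference-atlas proportions
  summing to 1 and per-group immunopositive areas capped so groups sum to
  ≤ 100% (overlap-free convention).

All outputs are deterministic in (config, seed); the generator derives
independent substreams per output type from a seed sequence.

**The content-contrast scenario** (`central_contrast_config`) isolates the
normalization algebra: tumor mitochondrial content is set to 50% of benign
and the intrinsic flux per unit mitochondrial protein is made equal by
construction (the tumor flux ladder is the benign ladder × 0.5). Its
Bradford factors are derived from the realized simulated proteome
(`bradford_from_proteome`), encoding "non-mitochondrial protein per mg is
identical across groups", so the scenario is internally consistent rather
than relying on expected values. Biological CV is reduced to 0.10 and
dropout disabled. Expected outcome, and what the tests verify over 30
seeds: a ~2-fold wet-weight difference that MEF normalization removes to
within 5%.

## What the generator does *not* emulate

Real label-free intensities have peptide-level missingness correlated with
hydrophobicity and length, batch structure, and non-lognormal tails; real
traces have instrument drift, background O2 flux and re-oxygenation events;
real tumors have heterogeneous regions rather than one lognormal factor per
sample. Passing tests therefore demonstrate that the *operations* are
correct and that the normalization logic recovers known ground truth — not
that the pipeline is robust to every artifact of real instrument data.
DESeq2-style count modeling is deliberately out of scope: externally
produced differential-expression tables are first-class inputs, and the
built-in Welch-t + BH stand-in exists only so synthetic data can flow end
to end.

## Statistics

Welch's t is the default comparison (tumor/benign variances differ by
construction); the pooled-variance Student variant sits behind
`equal_var=True` since group comparisons in the source figures use it.
Cohen's d uses the (n−1)-weighted pooled SD. BH adjustment is the
standard step-up with monotone enforcement (via statsmodels), verified in
tests against a brute-force implementation of the definition. Post hoc
power for the two-sided two-sample t-test uses the noncentral t
distribution, ncp = d·√(n/2), df = 2n − 2 (harmonic-mean n for unequal
groups, flagged); the construction is validated against Monte-Carlo
rejection rates of the pooled t-test. scipy's noncentral-t tail functions
underflow to NaN at extreme noncentrality; the negligible tail is then
replaced by its limit (0 or 1).

Zero-variance features in differential abundance receive p = 1 with a
`zero_variance` flag rather than NaN, so noiseless simulations remain
processable. Pseudocounts default to 1.0 for protein intensities and 0.5
for TPM.

## Cell-type scoring decisions

The OXPHOS mRNA Index is the literal product of two percent-scale
quantities; no rescaling, because only the ranking of cell-type
contributions is interpreted. The reference-atlas proportion weighting is
applied inside %Expression_CT, before the immunopositive-area product.
Cell-type name harmonization (cancer/normal epithelial → epithelial,
CAFs/PVL → mesenchymal, B cells dropped for lack of an IF marker) ships as
an editable CSV; merged types combine pct_expressing as a
proportion-weighted mean and sum their atlas proportions. When genes are
missing in some cell types the per-complex mean is taken over the genes
present for that cell type (dropped genes are logged) — a declared choice,
since the order of averaging versus weighting for missing genes is not
standardized.

## Numerical and interface choices

* Trace CSVs are written with `%.17g` and read with round-trip float
  parsing, so write→parse is bit-exact.
* TPM validation uses a 1e-6 relative tolerance on column sums.
* Gene matching across omics layers is case-insensitive; multi-mapped
  symbols collapse to the entry with the largest mean abundance
  (`base_mean` column) or, absent that, the smallest adjusted p — logged.
* Units are carried as explicit strings on every flux table and rewritten
  by `apply_normalization`, never inferred.
* `min_samples` for "detected in a group" defaults to 3, robust to
  single-sample artifacts at the n = 5–6 group sizes used.

## Problem sizes

Tests and the acceptance script run the study at desk scale: 20 biological
samples per group for respirometry (6 per group × 30 seeds for the
content contrast), 1000-feature proteomes with 6 samples per group, and
200 replicate cohorts for the null-FDR check. These sizes were chosen so
that Monte-Carlo error is comfortably inside each assertion's tolerance.

## Known limitations

Tissue-scale results that depend on the deposited experimental datasets
(absolute DE counts, the exact enrichment pathways, receptor fold changes)
are outside what synthetic data can reproduce and are deliberately not
asserted. The ROS normalization-direction flip reported for H2O2 emission
depends on group factors that are not printed anywhere, so the H2O2 path is
verified only against closed-form and oracle calibrations. Instrument
background-flux correction and vendor binary formats are not implemented.
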