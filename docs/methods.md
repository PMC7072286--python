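# Methods

This note documents the models and procedures implemented in `gbpal`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Normalization and case-to-normal ratios

Raw counts are normalized with the median-of-ratios size-factor procedure:
sample *j*'s size factor is the median over reference genes (genes positive
in every fitted sample) of `x_gj / geomean_g`. When tumor and control
matrices enter one analysis they are normalized **jointly** in a single run
so both sides share a scale; the normal reference and the CNRs are then
taken from that one run.

Two properties worth stating precisely:

- Against a *fixed* fitted reference, rescaling a sample's raw counts by
  k > 0 leaves its normalized column exactly unchanged.
- In a self-referential whole-matrix run, the rescaled sample also moves
  the per-gene geometric means, so the normalized matrix is reproduced only
  up to a single global factor k^(1/m). That factor cancels in any
  between-sample ratio and in CNRs computed from a jointly normalized run
  (exactly so at pseudocount 0). The test suite checks both forms.

**Pseudocount.** CNRs feed into logarithms, so zeros must be regularized.
A pseudocount (default 1.0, in normalized-count units) is added to the
sample value and to the control values before averaging, making
`CNR = (x + q) / geomean(controls + q)`. The control average is the
geometric mean by default so that ln CNR is centered at 0 for null genes;
an arithmetic-mean option exists for sensitivity analyses. Gene-set
mismatches between samples and reference are resolved by intersection
(with logging), never by zero-filling, which would fabricate extreme
ratios.

## Pathway activation levels

`PAL_pj = Σ_n ARR_np ln CNR_nj / Σ_n |ARR_np|`, natural log, with both sums
running over the measured members of pathway *p* only. Normalizing within
the pathway keeps each pathway's score independent of every other
pathway's content and makes PAL the |ARR|-weighted mean of signed log
ratios, so its magnitude is directly interpretable in ln-units of
expression change.

Numerical/degenerate-input rules:

- Genes absent from the CNR matrix are excluded from numerator and
  denominator alike.
- Members with ARR = 0 are neutral: zero weight in both sums. They appear
  in the coverage report but do not count toward `min_coverage`.
- A pathway with fewer than `min_coverage` (default 1) measured
  nonzero-ARR members, or with Σ|ARR| = 0 after exclusion, is dropped and
  logged; if every pathway is dropped the run errors out rather than
  returning an empty result.

The engine is validated against an independently coded direct summation on
random small instances to 1e−12, and against closed forms (unit CNRs ⇒ 0;
single activator at CNR = e ⇒ 1; invariance under uniform ARR-magnitude
scaling; antisymmetry under ARR sign flip; linearity in ln CNR).

## Differential analysis

**Pathway level.** The AUC of each feature between two groups is the
tie-corrected Mann–Whitney pair statistic, computed from midranks (exactly
`(#{pos>neg} + ½#{pos=neg})/(n₊n₋)`). Recurrent-like samples form the
positive class, recorded in the output so direction is unambiguous.
Significance is two-sided — `max(AUC, 1−AUC) ≥ threshold` (default 0.7) —
with direction from the group medians, since both up- and down-regulated
pathways are of interest. No multiplicity correction is applied at the
pathway level (threshold rule only); this mirrors common practice for
AUC-screened pathway panels and is noted in the output contract.

**Gene level.** The differential-expression caller is deliberately simple
and rank-based, matching the AUC philosophy: per-gene two-sided
Mann–Whitney tests, Benjamini–Hochberg FDR (default 0.05), and a
natural-log fold-change filter (default ln 1.5) on pseudocount-shifted
group means. All three parameters are exposed.

**Concordance.** Two AUC result sets (e.g. tissue vs. GSC comparisons)
share a feature when it is significant in both *and* has the same
direction; Venn counts (a-only / b-only / shared) are reported.
Gene-set overlap analogously requires matching fold-change sign.

**Subtype assignment.** Nearest centroid by Spearman correlation over the
union of signature genes; a signature without explicit centroid values
contributes a membership-indicator centroid. Exact correlation ties and
undefined correlations (constant profiles) yield `"unclassified"`; at
least 10 signature genes must be measured per signature. Signature lists
are user inputs, never hard-coded.

**Reporting plumbing.** Hierarchical clustering uses Ward linkage on
Euclidean sample distances; PCA reports per-component percent variance
(summing to 100) plus the first two component scores.

## Balanced drug efficiency scores

BES is a **reconstruction**: it combines exactly the two information
sources that define transcriptome-based drug scoring — expression of a
drug's target genes and activation of the pathways containing them — but
the precise combination rule is this package's own design, isolated behind
`compute_bes` so an alternative can be swapped in.

For drug *d* with measured targets *T* (weights w ∈ {±1}; −1 encodes a
resistance factor, e.g. MGMT for temozolomide and lomustine — the minimal
encoding by which high expression of a resistance gene lowers a drug's
score):

- gene component `G = mean_{t∈T} w_t ln CNR_t`;
- pathway component `P = mean_{p∈Q} s_dp PAL_p`, where Q holds the scored
  pathways containing ≥ 1 target with nonzero ARR and
  `s_dp = sign(Σ w_t ARR_tp)`; pathways with s = 0 are excluded;
- within each sample, G and P are z-standardized across the drug panel
  (population sd; a zero-sd panel contributes 0) and averaged:
  `BES = (z(G) + z(P))/2`, or z(G) alone when Q is empty.

The z-balancing makes the two components commensurate but also makes BES
**panel-relative**: scores are comparable across samples only for the same
panel, and a panel of ≥ 2 scorable drugs is required. Sample-level
balancing is the default; cohort-level balancing would be an alternative
convention, and the sample-level choice keeps each sample's ranking
self-contained. Patient-level stratification by a drug's score uses a
majority vote of the patient's samples over `BES > cutoff`, with ties
resolved by the sign of the mean (mean = cutoff counts as negative).

## Synthetic cohorts

The generator emulates the *structure* of a longitudinal multi-region
glioblastoma study — normal controls, patients with ndGB and/or recGB
tumors (`paired_fraction` with both), `regions_per_tumor` tissue samples
per tumor, stem-cell cultures for a fraction of tumors — not the biology
of any real dataset.

Per gene and sample, latent ln-expression = per-gene baseline
(N(4, 1) by default, i.e. typical normalized counts around e⁴ ≈ 55)
+ patient + tumor + region (or culture) effects, each a per-gene Gaussian
draw with sd `sigma_patient` (0.3), `sigma_tumor` (0.2), `sigma_region`
(0.1), `sigma_gsc` (0.3) — between-patient spread dominating within-tumor
spread, as in real tumor cohorts. Counts are negative-binomial around
exp(latent) × library size (uniform in 0.7–1.3) with dispersion 0.1, the
noise model under which median-of-ratios normalization is the natural
choice.

**Planting rule.** A pathway planted `recGB-up` at delta shifts each
nonzero-ARR member of recGB samples by `+delta·sign(ARR)`, so the induced
PAL shift has closed-form expectation exactly `+delta` (`−delta` for
`recGB-down`); this is what makes parameter-recovery tests sharp. Planted
single genes shift additively. GSC samples inherit the tumor's effects,
including planted stage effects, plus an independent culture shift — giving
the tissue/GSC concordance analysis a true signal. Optional subtype
planting shifts a tumor's signature genes by `subtype_delta`. Every planted
effect is written to truth tables, and all output is a deterministic
function of the seed.

**What the generator does not emulate:** real pathway topologies and sizes,
gene–gene correlation beyond the shared sample effects, batch structure,
tumor purity variation, or any resemblance to real expression values.
Passing recovery tests therefore demonstrates that the *procedures* are
correct and calibrated under their assumed noise model, not that the
biological findings transfer to any particular dataset.

## Problem sizes and tolerances

Oracle-equivalence checks use 1000 random instances (≤ 10 genes per
pathway; group sizes ≤ 20) at 1e−12. Calibration and recovery studies use
cohorts of 5000 genes, 300 pathways and 20 vs 20 independent tissue
samples — large enough for stable rates, small enough to run in seconds —
with 20 seeded replicates for planted-pathway recovery. The multi-region,
paired default configuration is used for structural tests; the 20 vs 20
single-region configuration is used wherever a two-group comparison with
independent samples is the quantity under study.

## Known limitations

- The BES combination rule is a reconstruction (above); absolute BES
  values carry no meaning outside their panel.
- The DEG caller is rank-based and makes no attempt at count-model
  shrinkage; for small cohorts a negative-binomial GLM framework will be
  more powerful.
- PAL treats pathway membership as a flat weighted set; no topology beyond
  the activator/repressor sign is used.
- CNRs depend on the choice of normal reference; the reference is an
  explicit input everywhere, and tissue and GSC samples are compared to
  the same reference by default.
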