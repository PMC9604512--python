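# Methods

## The analysis model

The pipeline treats post-NAC peripheral blood as a mixture readout of
the patient's immune state and asks two questions of it: (1) do
interferon/complement and cytotoxic transcriptional programs, summarized
as per-sample signature scores, separate outcome groups (pCR, residual
disease without/with recurrence, no NAC)?  (2) does relative cell-type
composition — monocytes in particular — do the same?

The unit pipeline for sequencing data is

```
counts → drop RBC-contamination genes → TPM → log2(x+1) → per-gene z-score
```

Whole-blood and PBMC preparations carry variable erythrocyte carryover;
25 transcripts (hemoglobins, `RN7SL1/2`, `MIR3648-1/2`, `SLC25A37`,
`SLC4A1`, `NRGN`, `SNCA`, `BNIP3L`, `EPB42`, `ALAS2`, `BPGM`, `OSBP2`,
`AC104389.6`, `AC010507.1`, `HBQ1`, `HBZ`, `HBM`, `HBE1`) are removed
**before** TPM so that contaminating reads do not deflate the
per-million scaling of every other gene.  The ordering is observable:
excluding after TPM leaves all retained values changed by the factor
the contamination claimed, and a test asserts the difference.

Log base and pseudocount are conventions, not discoveries: `log2(x+1)`
is used because it is the dominant convention for expression matrices.
z-scores use the sample standard deviation (n−1) and standardize each
gene **across the supplied cohort**.  A consequence worth stating:
scores are comparable within a cohort, not across cohorts, and adding
samples changes every z.  Constant genes get all-zero z (with a logged
warning) rather than NaN.

## Signature scores and PIRS

A signed signature scores a sample as the mean of sign-weighted
z-scores over its genes.  Two normalization choices are deliberate:

* the cytotoxic score divides by its gene count (8) like any other
  signature, keeping the two component scores on one scale before
  subtraction; division by a constant cannot change sample ranking
  within a cohort, but anyone comparing absolute score values against
  conventions that use an unnormalized signed sum should note the
  factor;
* component scores are **not** re-standardized before the subtraction
  `PIRS = IFN/complement − cytotoxic`; the subtraction is taken at
  face value.

Signature genes missing from a matrix (e.g. a targeted panel) are
dropped and the mean renormalized to the found genes; a signature with
no gene present is an error, not a zero.

## Enrichment and the derived IFN/complement signature

Because the IFN/complement signature is cohort-derived rather than
fixed, the package derives it the same way: rank genes, test pathway
sets, take the union of leading edges of the enriched
interferon/complement pathways.

* **Ranking metric** — signal-to-noise `(μ₁−μ₀)/(σ₁+σ₀)` with each
  group SD floored at `max(0.2·|μ|, 0.2)`.  A differential-expression
  model fit (negative-binomial Wald statistics) would be an equally
  defensible ranking; signal-to-noise was chosen as the classic
  preranked-enrichment default, it is fast, and it has no tuning
  parameters.  NES values therefore characterize this ranking, not any
  particular DE model's.
* **Enrichment score** — weighted Kolmogorov–Smirnov running sum,
  hit increment `|metric|^p` normalized over the set (default p = 1),
  miss decrement `1/(N−|set|)`; ES is the running-sum value of maximal
  absolute deviation, ties resolved to the earliest position.  A set
  whose members all have zero metric falls back to unweighted hits.
* **Null model** — gene-set permutation (random same-size sets drawn
  from the ranked genes), not phenotype permutation: it stays valid at
  the small group sizes typical of these cohorts and is fast enough to
  run at every test invocation.  `n_perm` defaults to 1000 (500 in the
  bundled pipeline driver); fewer than 100 is rejected.
* **NES / p / q** — NES divides ES by the mean |null ES| of matching
  sign; p is the same-sign permutation tail with +1 smoothing (its
  floor is `1/(n_same+1)`, roughly `2/n_perm` under an even sign
  split); q is the sign-stratified ratio-of-tails FDR conventional for
  this method, clipped to [0,1] and made monotone in |NES|.  The
  Benjamini–Hochberg step-up is used everywhere else (the statistics
  module), not here.
* **Leading edge and union** — members at ranks ≤ peak for ES > 0
  (≥ peak for ES < 0); the union signature deduplicates and sorts
  lexicographically, all signs +1.  The pipeline driver admits
  pathways with ES > 0 and q < 0.25 into the union (the customary
  exploratory FDR ceiling for this method) and falls back to the named
  interferon/complement family with a warning if none qualifies.

## Deconvolution

Relative-mode fractions come from per-sample non-negative least
squares of linear-scale expression (TPM) on reference profiles over
their shared genes, followed by renormalization to the simplex.  NNLS
was chosen over a support-vector regression as a transparent,
dependency-light estimator whose failure modes are easy to reason
about; the downstream analysis needs only relative fractions, which
the renormalization supplies either way.  Consequences and guards:

* mixtures are linear in linear space, so log-space input is rejected;
* fractions are scale-free: multiplying a sample by c > 0 leaves them
  unchanged (tested to 1e-8);
* if less than 50% of reference genes are present the fit aborts
  rather than silently degrading; an all-zero coefficient vector names
  the offending sample;
* the per-sample residual 2-norm is reported as the goodness-of-fit
  diagnostic; no permutation significance machinery is attached to it.

Collapsing sums fine types into simplified categories (CD4 subsets,
B subsets, NK subsets, macrophage/dendritic subsets → "Other Myeloid",
mast/eosinophil/neutrophil → "Granulocytes").  Types the scheme does
not name — monocytes, CD8 T cells, follicular-helper and γδ T cells —
pass through unchanged, so mass is conserved exactly and collapsing is
idempotent.  A fine type claimed by two categories is an error.

## Statistics

* Wilcoxon rank-sum: exact enumeration when n₁+n₂ ≤ 12 and the pooled
  data are tie-free (enumeration is cheap there); otherwise the normal
  approximation with tie correction and continuity correction.  The
  same switch point governs the signed-rank test for paired pre/post
  changes, where zero differences are dropped by convention.
* AUC is computed by the trapezoidal rule over all thresholds and
  equals the Mann–Whitney U of the positive class over the negative
  divided by n₁n₂, ties half-credited; a test asserts the identity
  exactly on random tied instances.  The positive class is fixed per
  contrast (arm a: pCR, or the non-recurrence pool) so a strong
  marker pointing the "wrong" way reports AUC < 0.5 rather than
  silently flipping.
* The BH-FDR family is one report invocation — all metric × contrast
  rows emitted together.  Which comparisons share a family is a
  reporting choice, so it is configurable rather than hard-coded.
* Cytokine-support (e.g. GCSF) samples are excluded before any outcome
  comparison, since the product itself perturbs monocyte counts.
* One-tailed directions are declared per contrast and carried in every
  report row; the defaults test the "higher in good outcome"
  direction for all metrics.

## The synthetic cohort generator

The generator emulates exactly the structure the analysis assumes, so
recovery tests are meaningful:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 50 | samples per outcome group (int or per-group dict) |
| `n_genes` | 600 | reference genes (≥ 10 × number of cell types) |
| `cell_types` | 6 types | must include Monocytes, CD8_T, NK |
| `base_fractions` | Mono .20, CD8 .15, NK .10, CD4 .25, B .10, Gran .20 | mean blood composition |
| `dirichlet_concentration` | 100 | fraction variability (SD ≈ 0.04 for a 0.2 mean) |
| `monocyte_shift` | pCR +0.05, noNAC −0.05 | additive group shift of the monocyte mean; other types rescale proportionally |
| `ifn_effect` | 1.0 log2 | fold-change of the planted IFN/complement program, applied to the **monocyte contribution** of pCR samples only |
| `cytotoxic_effect` | 1.0 log2 | same for the cytotoxic program in CD8/NK of recurrent samples |
| `nb_dispersion` | 0.1 | φ in var = μ + φμ² |
| `library_size_mean` | 5e5 | expected total counts; sizes are log-normal with σ = 0.3 log2 units around it |
| `rbc_fraction` | 0.05 | library share of the 25 RBC-contamination genes |
| `clinical_noise_sd` | 7.0 pct. points | measurement noise of the clinical monocyte percentage; at the default fraction spread this targets an inferred-vs-clinical Pearson R near 0.5 |
| `clinical_coverage` | 0.7 | fraction of samples with a clinical value (mirrors how often a differential count exists in practice) |
| `cytokine_support_rate` | 0.02 | Bernoulli rate of the exclusion flag |

No fraction-scale effect sizes are reported for the real cohorts, so
the defaults above are the package's chosen study conditions — values
a blood-composition analyst would call realistic — not estimates of
any particular cohort.  They were fixed once and are exercised as-is
by the calibration and power suites.

Reference profiles give each type a disjoint marker block (30× the
shared log-normal baseline, with 2^N(0, 0.4) per-type jitter); the
planted IFN program genes are additionally 20× in monocytes and the
cytotoxic program genes 20× in both CD8 and NK — matching the
cell-type-restricted expression the real signatures show.  Marker
dominance keeps pairwise profile correlations low (asserted < 0.5).
Planted effects act multiplicatively on the designated cell type's
**mixture contribution**, not on bulk expression, so a program's bulk
fold-change scales with that type's fraction — the mechanism the
deconvolution story relies on.

The NanoString-style panel carries the PIRS genes, a 6-point positive
titration ladder, 8 negatives near a Poisson background and 3
housekeepers, with one multiplicative technical factor per sample
(log-normal, σ = 0.3 log2 units, or caller-supplied) and optional
Poisson counting noise.  The normalization chain (positive factor →
mean+2SD background subtraction floored at 1 → housekeeper factor →
log2) follows platform convention, since the procedure's step names are
standard but the formulas are implementation choices.

What the generator does **not** emulate: batch effects, isoform- or
GC-dependent biases, cell-state continua within a type (each type is a
single mean profile), reference/mixture profile mismatch,
longitudinal kinetics beyond an optional paired pre/post toggle (the
monocyte shift applies to the post sample), and biological correlation
between the clinical flag and outcome.  Passing recovery tests
therefore demonstrates internal consistency of the pipeline under its
own assumptions — not robustness to the reference-mismatch and batch
structure of real cohorts, which is the main caveat when carrying
conclusions to real data.

## Problem sizes in the test suite

Statistical suites run at sizes chosen to make their assertions
well-calibrated rather than exhaustive: null calibration uses 500
replicates at n = 20/group on a 120-gene panel (the monocyte-fraction
test does not need a large gene space); power checks use 100 seeds of
the full default cohort (4 × 50 samples, 625 genes) through the honest
pipeline including NNLS deconvolution; oracle-equivalence suites use
200 random instances each.  The 0.15 null-AUC envelope at n = 30/group
is about two standard errors, so it is checked on a handful of seeded
cohorts rather than asserted for every possible draw.

## Known limitations

* NES/q values depend on the ranking metric and the gene-set
  permutation null; they are not numerically interchangeable with
  phenotype-permutation implementations.
* NNLS fractions are a transparent stand-in for regression-based
  deconvolution with batch correction; on real data with an imperfect
  reference the two can differ materially.
* The cohort-relative z-scoring means every score is anchored to its
  cohort; applying a signature to a new cohort re-anchors it.
* Exact Wilcoxon enumeration is only engaged for tie-free samples of
  total size ≤ 12; heavily tied tiny samples use the approximation,
  which is conservative there.
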