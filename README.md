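# pirs — peripheral-blood expression biomarkers after neoadjuvant chemotherapy

Blood drawn after neoadjuvant chemotherapy (NAC) and before surgery
carries transcriptional and cell-composition signals that track
long-term outcome in breast cancer: patients with a pathologic complete
response (pCR) tend to show stronger interferon/complement expression
and more circulating monocytes than patients with residual disease
(RD), and especially than those whose disease later recurs.  `pirs`
implements that analysis as a tested, reusable pipeline for anyone
working with whole-blood or PBMC bulk expression — and pairs it with a
synthetic whole-blood cohort generator with recorded ground truth, so
every stage can be verified without access to patient data.

## What it computes

**Signature scores.** For a cohort matrix z-scored per gene, a signed
signature *G* scores each sample *s* as

```
score_s = (1/|G|) * Σ_{g∈G} sign_g · z_{g,s}
```

The built-in 8-gene cytotoxic signature is
`FGFBP2 + GNLY + GZMB + GZMH + NKG7 + LAG3 + PDCD1 − HLA-G`.
The IFN/complement signature is cohort-derived (below).  The combined
**peripheral immunologic response score** is

```
PIRS = IFN/complement score − cytotoxic score
```

**Leading-edge signature construction.** Genes are ranked by
signal-to-noise between pCR and RD, each pathway gene set gets the
weighted Kolmogorov–Smirnov enrichment score with gene-set-permutation
NES / p / FDR q, and the leading-edge genes (members at or before the
running-sum peak) of the enriched interferon/complement pathways are
unioned and deduplicated into the IFN/complement signature.

**Cell-type deconvolution.** Bulk expression in linear space is fit per
sample by non-negative least squares against cell-type reference
profiles; coefficients are renormalized to sum to 1 (relative mode).
Fine types can be collapsed into simplified categories (CD4 subsets →
CD4 T cells, B subsets → B cells, NK subsets → NK cells, etc.) with
exact mass conservation.

**Outcome statistics.** Wilcoxon rank-sum tests (exact for small
tie-free samples), Benjamini–Hochberg FDR, Pearson correlation of
inferred vs clinically measured monocytes, and ROC/AUC (AUC ≡
U/(n₁n₂), ties half-credited) over configurable outcome contrasts.

**Preprocessing.** A fixed 25-gene red-blood-cell contamination filter
(hemoglobins, `RN7SL1/2`, `ALAS2`, …) applied *before* TPM; TPM from
gene lengths; `log2(x+1)`; per-gene cohort z-scores; and NanoString
nCounter-style normalization (positive spike-in factor → negative-
control background subtraction → housekeeper factor → log2).

## Worked example

```python
from pirs import SimulationConfig
from pirs.pipeline import run_pipeline

cfg = SimulationConfig(n_per_group=25, seed=7)   # 4 outcome groups
res = run_pipeline(cfg, n_perm=500)

print(f"IFN/complement signature: {len(res.ifn_signature)} genes")
print(f"inferred vs clinical monocytes: R = {res.clinical_correlation.r:.2f} "
      f"(n = {res.clinical_correlation.n_pairs} pairs)")
cols = ["metric", "contrast", "p_value", "q_value", "auc"]
print(res.report[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

prints

```
IFN/complement signature: 29 genes
inferred vs clinical monocytes: R = 0.55 (n = 71 pairs)
               metric                   contrast  p_value  q_value     auc
       ifn_complement                  pCR_vs_RD 3.11e-12 3.11e-11       1
            cytotoxic                  pCR_vs_RD        1        1    0.22
                 PIRS                  pCR_vs_RD 1.61e-11 8.07e-11   0.983
    monocyte_fraction                  pCR_vs_RD 1.21e-09 3.03e-09   0.934
clinical_monocyte_pct                  pCR_vs_RD   0.0535   0.0764   0.635
       ifn_complement noRecurrence_vs_recurrence 0.000117 0.000196   0.765
            cytotoxic noRecurrence_vs_recurrence        1        1 0.00766
                 PIRS noRecurrence_vs_recurrence 5.73e-11 1.91e-10   0.964
    monocyte_fraction noRecurrence_vs_recurrence 9.73e-05 0.000195   0.769
clinical_monocyte_pct noRecurrence_vs_recurrence     0.14    0.175   0.597
```

Reading it: the enrichment stage recovered a 29-gene IFN/complement
signature from the planted interferon/complement program; the derived
PIRS separates pCR from RD (AUC 0.98) and non-recurrence from
recurrence (AUC 0.96); deconvolved monocyte fractions do the same (AUC
0.93 / 0.77) and correlate with the simulated clinical monocyte
percentages (R = 0.55); the noisy clinical measurement alone is a much
weaker marker — exactly the ordering the pipeline is designed to
expose.  One-tailed tests point in the pCR-higher direction, so the
cytotoxic score (planted in recurrent samples) shows p ≈ 1 with AUC
well below 0.5.

The same stages are available from a shell:

```sh
pirs simulate   --seed 7 --out-dir cohort/
pirs preprocess --counts cohort/counts.tsv --lengths cohort/gene_lengths.tsv --out-dir prep/
pirs deconvolve --tpm prep/tpm.tsv --reference cohort/reference.tsv --out-dir dec/
pirs run-all    --seed 7 --out-dir all/
```

## Layout

```
src/pirs/
  containers.py     ExpressionMatrix, GeneSignature, ReferenceMatrix
  io.py             delimited matrices, GMT, metadata, YAML config
  preprocess.py     RBC exclusion, TPM, log2, GeneZScorer, NanoString
  signatures.py     SignatureScorer, cytotoxic signature, PIRS
  enrichment.py     ranking, weighted-KS ES, leading edge, NES/FDR
  deconvolution.py  ReferenceDeconvolver (NNLS), collapsing, clinical R
  stats.py          Wilcoxon, BH-FDR, ROC/AUC, biomarker report
  simulate.py       synthetic cohorts + NanoString panels with truth
  pipeline.py       end-to-end orchestration
  cli.py            `pirs` command-line interface
```

`GeneZScorer`, `SignatureScorer` and `ReferenceDeconvolver` follow the
scikit-learn estimator API (fit/transform, `get_params`) and compose
with sklearn pipelines; the module-level functions wrap them.  See
`docs/methods.md` for the model, parameter defaults and limitations.
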