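"""End-to-end analysis on a synthetic cohort.

Chains the stages the way the blood-biomarker study runs them:
cytokine-support exclusion -> RBC gene exclusion -> TPM -> log2 ->
per-gene z-scores; signal-to-noise ranking of pCR vs residual disease
and preranked enrichment over a pathway collection; leading-edge union
-> IFN/complement signature; signature scores and PIRS; relative-mode
deconvolution; correlation of inferred vs clinical monocytes; and the
Wilcoxon/FDR/AUC biomarker report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .deconvolution import compare_inferred_vs_clinical, deconvolve_relative
from .enrichment import nes_and_fdr, union_signature
from .io import filter_cytokine_support
from .preprocess import (compute_tpm, filter_excluded_genes, log_transform,
                         zscore_genes)
from .signatures import CYTOTOXIC_SIGNATURE, compute_pirs, score_signature
from .simulate import (SimulationConfig, SyntheticTruth, default_gene_lengths,
                       generate_cohort, generate_reference_profiles)
from .stats import DEFAULT_CONTRASTS, evaluate_biomarkers
from . import enrichment as _enr

logger = logging.getLogger(__name__)

#: pathway names treated as the IFN/complement family
PATHWAY_FAMILY = ("IFN_GAMMA_LIKE", "IFN_ALPHA_LIKE", "COMPLEMENT_LIKE")


def build_pathway_collection(truth: SyntheticTruth, all_genes,
                             seed: int = 0, n_random_sets: int = 20
                             ) -> dict[str, list[str]]:
    """A hallmark-style gene-set collection for the synthetic cohort.

    Three overlapping pathway sets draw most of their members from the
    planted IFN/complement program (plus random decoys, which a correct
    leading edge should discard), alongside random control sets.
    """
    rng = np.random.default_rng([seed, 4])
    program = list(truth.planted_signature_genes["ifn_complement"])
    pool = [g for g in all_genes if g not in program]
    sizes = {"IFN_GAMMA_LIKE": (25, 10), "IFN_ALPHA_LIKE": (15, 6),
             "COMPLEMENT_LIKE": (10, 5)}
    sets: dict[str, list[str]] = {}
    for name, (n_prog, n_decoy) in sizes.items():
        members = list(rng.choice(program, size=min(n_prog, len(program)),
                                  replace=False))
        members += list(rng.choice(pool, size=n_decoy, replace=False))
        sets[name] = members
    for j in range(n_random_sets):
        sets[f"RANDOM_{j:02d}"] = list(rng.choice(pool, size=20, replace=False))
    return sets


@dataclass
class PipelineResult:
    """Everything the downstream report needs, with truth for recovery checks."""

    meta: pd.DataFrame
    tpm: ExpressionMatrix
    zscores: ExpressionMatrix
    enrichment: list
    ifn_signature: object
    scores: pd.DataFrame           # samples x {ifn_complement, cytotoxic, PIRS}
    fractions: pd.DataFrame        # samples x cell types
    residuals: pd.Series
    clinical_correlation: object
    report: pd.DataFrame
    truth: SyntheticTruth


def run_pipeline(config: SimulationConfig, n_perm: int = 500,
                 use_planted_signature: bool = False) -> PipelineResult:
    """Generate a synthetic cohort and run the full analysis on it.

    With ``use_planted_signature=True`` the IFN/complement signature is
    taken directly from the generator's truth instead of being derived
    by enrichment — useful for isolating scoring/power behavior from
    signature construction.
    """
    reference = generate_reference_profiles(config)
    counts, meta, truth = generate_cohort(config, reference)

    meta = filter_cytokine_support(meta)
    counts = counts.with_data(counts.data.loc[:, meta["sample_id"].tolist()])

    filtered = filter_excluded_genes(counts)
    lengths = default_gene_lengths(filtered.gene_ids, seed=config.seed)
    tpm = compute_tpm(filtered, lengths)
    logm = log_transform(tpm)
    z = zscore_genes(logm)

    # rank pCR vs all residual disease on NAC-treated samples only
    meta_idx = meta.set_index("sample_id")
    nac = meta_idx.loc[meta_idx["outcome"] != "noNAC"]
    labels = nac["outcome"].map(lambda o: "pCR" if o == "pCR" else "RD")
    rank_input = logm.with_data(logm.data.loc[:, labels.index.tolist()])
    ranked = _enr.rank_genes(rank_input, labels, positive="pCR")

    collection = build_pathway_collection(truth, list(logm.data.index),
                                          seed=config.seed)
    enr = nes_and_fdr(collection, ranked, n_perm=n_perm, seed=config.seed)

    if use_planted_signature:
        from .containers import GeneSignature
        ifn_sig = GeneSignature.from_genes(
            "ifn_complement", truth.planted_signature_genes["ifn_complement"])
    else:
        by_name = {r.set_name: r for r in enr}
        chosen = [by_name[n] for n in PATHWAY_FAMILY
                  if n in by_name and by_name[n].es > 0 and by_name[n].q_value < 0.25]
        if not chosen:  # no pathway enriched: fall back to the named family
            chosen = [by_name[n] for n in PATHWAY_FAMILY if n in by_name]
            logger.warning("no pathway passed q < 0.25; using the named family as-is")
        ifn_sig = union_signature([r.leading_edge for r in chosen])

    ifn_scores = score_signature(z, ifn_sig)
    cyt_scores = score_signature(z, CYTOTOXIC_SIGNATURE)
    pirs = compute_pirs(ifn_scores, cyt_scores)
    scores = pd.DataFrame({"ifn_complement": ifn_scores,
                           "cytotoxic": cyt_scores, "PIRS": pirs})

    fractions, residuals = deconvolve_relative(tpm, reference)
    corr = compare_inferred_vs_clinical(fractions, meta)

    features = scores.copy()
    features["monocyte_fraction"] = fractions["Monocytes"]
    features["clinical_monocyte_pct"] = (
        meta_idx["clinical_monocyte_pct"].reindex(features.index))
    report = evaluate_biomarkers(features, meta, DEFAULT_CONTRASTS,
                                 exclude_cytokine_support=False)
    return PipelineResult(meta, tpm, z, enr, ifn_sig, scores, fractions,
                          residuals, corr, report, truth)
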