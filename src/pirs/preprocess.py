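"""Expression preprocessing: gene exclusion, TPM, log2, z-scores, NanoString.

The unit pipeline for sequencing data is counts -> (drop
red-blood-cell contamination genes) -> TPM -> log2(x+1) -> per-gene
z-score.  Exclusion happens *before* TPM so that contaminating reads
do not distort the per-million scaling of the remaining genes.

Whole blood / PBMC preparations carry variable red-blood-cell carryover;
a fixed 25-symbol list of hemoglobin and other erythrocyte transcripts
(`RBC_EXCLUSION_GENES`) is removed by default.

NanoString panels are normalized in the platform's conventional order:
positive spike-in factor, negative-control background subtraction,
housekeeper factor, then log2.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


def _load_exclusion_list() -> tuple[str, ...]:
    text = resources.files("pirs.data").joinpath("rbc_exclusion.txt").read_text()
    genes = tuple(line.strip() for line in text.splitlines() if line.strip())
    if len(genes) != len(set(genes)):
        raise ValueError("exclusion list contains duplicates")
    return genes


#: erythrocyte-contamination transcripts removed before TPM
RBC_EXCLUSION_GENES: tuple[str, ...] = _load_exclusion_list()


def filter_excluded_genes(
    m: ExpressionMatrix, exclusion: tuple[str, ...] | list[str] | None = None
) -> ExpressionMatrix:
    """Drop excluded gene rows from a count matrix (apply before TPM).

    Genes on the list that are absent from the matrix are ignored with a
    log note; present ones are removed and counted in the log.
    """
    if m.unit_tag != "counts":
        raise ValueError(f"exclusion expects counts, got unit_tag={m.unit_tag!r}")
    exclusion = RBC_EXCLUSION_GENES if exclusion is None else tuple(exclusion)
    present = [g for g in exclusion if g in m.data.index]
    absent = len(exclusion) - len(present)
    if absent:
        logger.info("%d exclusion-list genes not present in matrix", absent)
    logger.info("removing %d excluded gene rows", len(present))
    return m.with_data(m.data.drop(index=present))


def compute_tpm(m: ExpressionMatrix, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million from counts and gene lengths (bp).

    TPM_g = 1e6 * (count_g / length_kb_g) / sum_h (count_h / length_kb_h),
    so every sample column sums to one million.
    """
    if m.unit_tag != "counts":
        raise ValueError(f"TPM expects counts, got unit_tag={m.unit_tag!r}")
    missing = [g for g in m.data.index if g not in gene_lengths.index]
    if missing:
        raise ValueError(f"genes without lengths: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    lengths_kb = gene_lengths.loc[m.data.index].to_numpy(float) / 1000.0
    if (lengths_kb <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = m.data.to_numpy(float) / lengths_kb[:, None]
    totals = rate.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        dead = [s for s, z in zip(m.sample_ids, zero) if z]
        raise ValueError(f"all-zero sample column(s): {dead}")
    tpm = pd.DataFrame(1e6 * rate / totals, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(tpm, "tpm")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1)."""
    values = m.data.to_numpy(float)
    if np.nanmin(values) < 0:
        raise ValueError("log transform requires non-negative values")
    out = pd.DataFrame(np.log2(values + 1.0), index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(out, "log2")


class GeneZScorer(TransformerMixin, BaseEstimator):
    """Standardize each gene across the cohort's samples.

    sklearn-style transformer on samples x genes arrays: ``fit`` learns
    each gene's cohort mean and sample standard deviation (ddof=1);
    ``transform`` maps values to z-scores.  Genes with zero variance are
    mapped to all-zero z with a logged warning rather than NaN.

    Because the reference population is the supplied cohort itself,
    scores are comparable within a cohort, not across cohorts.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected 2D samples x genes input")
        if X.shape[0] < 2:
            raise ValueError("z-scoring needs at least 2 samples")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=self.ddof)
        self.constant_mask_ = sd == 0
        if self.constant_mask_.any():
            logger.warning(
                "%d constant gene(s) set to zero z-scores", int(self.constant_mask_.sum())
            )
        self.scale_ = np.where(self.constant_mask_, 1.0, sd)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        Z[:, self.constant_mask_] = 0.0
        return Z


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene cohort z-scores of a log2 matrix (wraps :class:`GeneZScorer`)."""
    Z = GeneZScorer().fit_transform(m.data.to_numpy(float).T).T
    return ExpressionMatrix(pd.DataFrame(Z, index=m.data.index, columns=m.data.columns),
                            "zscore")


def _geomean(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.exp(np.mean(np.log(x), axis=axis))


def nanostring_normalize(
    raw: pd.DataFrame, annotations: pd.Series
) -> ExpressionMatrix:
    """Normalize raw nCounter-style panel counts.

    ``annotations`` maps each gene to a class: ``positive``, ``negative``,
    ``housekeeper`` or ``endogenous``.  Steps, in order:

    1. per-sample positive-control factor = (cohort geometric mean of the
       per-sample positive-control geomeans) / (sample's positive-control
       geomean), applied multiplicatively to all genes;
    2. background = mean + 2*SD of the sample's negative controls,
       subtracted, with results floored at 1;
    3. housekeeper factor computed as in (1) on housekeeper genes, applied;
    4. log2.

    Returns a log2 matrix over the endogenous + housekeeper genes.
    """
    classes = annotations.reindex(raw.index)
    for needed in ("positive", "negative", "housekeeper"):
        if not (classes == needed).any():
            raise ValueError(f"panel is missing {needed} control genes")

    values = raw.to_numpy(float)
    pos = values[(classes == "positive").to_numpy()]
    pos_geo = _geomean(np.maximum(pos, 0.5), axis=0)          # per sample
    pos_factor = _geomean(pos_geo) / pos_geo
    values = values * pos_factor

    neg = values[(classes == "negative").to_numpy()]
    background = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    values = np.maximum(values - background, 1.0)

    hk = values[(classes == "housekeeper").to_numpy()]
    hk_geo = _geomean(np.maximum(hk, 0.5), axis=0)
    hk_factor = _geomean(hk_geo) / hk_geo
    values = values * hk_factor

    keep = classes.isin(["endogenous", "housekeeper"]).to_numpy()
    out = pd.DataFrame(
        np.log2(values[keep]), index=raw.index[keep], columns=raw.columns
    )
    return ExpressionMatrix(out, "log2")
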