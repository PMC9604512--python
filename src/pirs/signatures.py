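"""Signed z-score signature scoring and the combined PIRS.

A signature score for a sample is the mean of the sample's per-gene
z-scores over the signature's genes, each multiplied by its sign:

    score_s = (1/|G|) * sum_{g in G} sign_g * z_{g,s}

The peripheral immunologic response score (PIRS) is the
IFN/complement score minus the cytotoxic score.  The 8-gene cytotoxic
signature (FGFBP2, GNLY, GZMB, GZMH, NKG7, LAG3, PDCD1 positive;
HLA-G negative) ships built in; the IFN/complement signature is
cohort-derived (the union of leading-edge genes from the interferon
and complement pathways) and therefore supplied by the user or by the
enrichment stage rather than hard-coded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)

CYTOTOXIC_SIGNATURE = GeneSignature(
    "cytotoxic",
    (
        ("FGFBP2", 1),
        ("GNLY", 1),
        ("GZMB", 1),
        ("GZMH", 1),
        ("NKG7", 1),
        ("LAG3", 1),
        ("PDCD1", 1),
        ("HLA-G", -1),
    ),
)


def load_default_signatures() -> dict[str, GeneSignature | None]:
    """Built-in signatures: the 8-gene cytotoxic score, plus an empty
    slot for the cohort-derived IFN/complement signature."""
    return {"cytotoxic": CYTOTOXIC_SIGNATURE, "ifn_complement": None}


def signature_overlap(a: GeneSignature, b: GeneSignature) -> set[str]:
    """Genes shared by two signatures (expected empty for the default
    cytotoxic vs a derived IFN/complement signature)."""
    shared = set(a.genes) & set(b.genes)
    if shared:
        logger.warning("signatures %s and %s overlap: %s", a.name, b.name, sorted(shared))
    return shared


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Score samples against signed gene signatures.

    sklearn-style transformer over samples x genes z-score frames.
    ``fit`` resolves each signature's genes against the input columns
    (missing genes are dropped with a warning and the mean renormalized
    to the found genes; a signature with no gene found is an error);
    ``transform`` returns a samples x signatures array of signed-mean
    scores.
    """

    def __init__(self, signatures: list[GeneSignature] | None = None):
        self.signatures = signatures

    def fit(self, X: pd.DataFrame, y=None):
        if self.signatures is None or len(self.signatures) == 0:
            raise ValueError("no signatures supplied")
        if not isinstance(X, pd.DataFrame):
            raise ValueError("SignatureScorer requires a DataFrame with gene columns")
        self.resolved_: list[tuple[str, list[str], np.ndarray]] = []
        for sig in self.signatures:
            found = [g for g in sig.genes if g in X.columns]
            missing = [g for g in sig.genes if g not in X.columns]
            if missing:
                logger.warning(
                    "signature %s: %d/%d genes absent from matrix: %s",
                    sig.name, len(missing), len(sig), missing,
                )
            if not found:
                raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
            signs = np.array([sig.signs[g] for g in found], dtype=float)
            self.resolved_.append((sig.name, found, signs))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "resolved_")
        cols = []
        for _name, found, signs in self.resolved_:
            vals = X.loc[:, found].to_numpy(float)
            cols.append(vals @ signs / len(found))
        return np.column_stack(cols)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "resolved_")
        return np.array([name for name, _, _ in self.resolved_], dtype=object)


def score_signature(z: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Signed-mean z-score of one signature for every sample."""
    if z.unit_tag != "zscore":
        raise ValueError(f"signature scoring expects z-scores, got {z.unit_tag!r}")
    scorer = SignatureScorer([sig]).fit(z.data.T)
    scores = scorer.transform(z.data.T)[:, 0]
    out = pd.Series(scores, index=z.sample_ids, name=sig.name)
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError(f"non-finite scores for signature {sig.name!r}")
    return out


def compute_pirs(ifn: pd.Series, cyt: pd.Series) -> pd.Series:
    """PIRS = IFN/complement score minus cytotoxic score, per sample."""
    if set(ifn.index) != set(cyt.index):
        diff = set(ifn.index) ^ set(cyt.index)
        raise ValueError(f"sample sets differ between scores: {sorted(diff)}")
    pirs = ifn - cyt.reindex(ifn.index)
    pirs.name = "PIRS"
    return pirs
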