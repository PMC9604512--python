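"""Reference-based cell-fraction estimation (relative mode) and collapsing.

Bulk expression is modeled in linear space as a non-negative mixture
of cell-type mean profiles.  Per sample we solve a non-negative least
squares of the sample's expression on the reference profiles over
their shared genes, then renormalize the coefficients to sum to 1
(relative mode: fractions of the cell types in the reference, not of
all cells in the tube).  The per-sample residual norm is reported as
a transparent goodness-of-fit diagnostic.

Fine cell types can then be summed into simplified categories
(`DEFAULT_COLLAPSE_SCHEME` mirrors a standard 22-type leukocyte
reference: CD4 subsets -> CD4 T cells, B subsets -> B cells, NK
subsets -> NK cells, macrophage/dendritic subsets -> Other Myeloid,
mast/eosinophil/neutrophil -> Granulocytes); types not named by the
scheme (monocytes, CD8 T, Tfh, gamma-delta T) pass through unchanged,
so total mass is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix, ReferenceMatrix

#: simplified categories -> constituent fine types (LM22-style names)
DEFAULT_COLLAPSE_SCHEME: dict[str, list[str]] = {
    "CD4 T cells": [
        "T cells CD4 memory activated",
        "T cells CD4 memory resting",
        "T cells CD4 naive",
        "T cells regulatory (Tregs)",
    ],
    "B cells": ["B cells naive", "B cells memory", "Plasma cells"],
    "NK cells": ["NK cells activated", "NK cells resting"],
    "Other Myeloid": [
        "Macrophages M0",
        "Macrophages M1",
        "Macrophages M2",
        "Dendritic cells activated",
        "Dendritic cells resting",
    ],
    "Granulocytes": [
        "Mast cells activated",
        "Mast cells resting",
        "Eosinophils",
        "Neutrophils",
    ],
}


class ReferenceDeconvolver(TransformerMixin, BaseEstimator):
    """Estimate relative cell-type fractions by NNLS against a reference.

    Parameters
    ----------
    reference:
        Cell-type mean profiles (types x genes), linear scale.
    min_overlap:
        Minimum fraction of reference genes that must be present in the
        mixture matrix; below this the fit aborts rather than silently
        degrading.

    ``fit`` resolves the shared genes; ``transform`` takes a
    samples x genes DataFrame of linear-scale expression and returns a
    samples x types array of fractions summing to 1.  The residual
    2-norm of each sample's fit is stored in ``residuals_``.
    """

    def __init__(self, reference: ReferenceMatrix | pd.DataFrame | None = None,
                 min_overlap: float = 0.5):
        self.reference = reference
        self.min_overlap = min_overlap

    def _profiles(self) -> pd.DataFrame:
        if self.reference is None:
            raise ValueError("no reference supplied")
        if isinstance(self.reference, ReferenceMatrix):
            return self.reference.profiles
        return self.reference

    def fit(self, X: pd.DataFrame, y=None):
        profiles = self._profiles()
        if not isinstance(X, pd.DataFrame):
            raise ValueError("deconvolution requires a DataFrame with gene columns")
        shared = [g for g in profiles.columns if g in X.columns]
        overlap = len(shared) / profiles.shape[1]
        if overlap < self.min_overlap:
            raise ValueError(
                f"only {overlap:.0%} of reference genes present in the mixture "
                f"matrix (minimum {self.min_overlap:.0%})"
            )
        self.shared_genes_ = shared
        self.cell_types_ = list(profiles.index)
        self.basis_ = profiles.loc[:, shared].to_numpy(float).T  # genes x types
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "basis_")
        M = X.loc[:, self.shared_genes_].to_numpy(float)
        fractions = np.empty((M.shape[0], self.basis_.shape[1]))
        residuals = np.empty(M.shape[0])
        for i in range(M.shape[0]):
            coef, resid = nnls(self.basis_, M[i])
            total = coef.sum()
            if total <= 0:
                raise ValueError(
                    f"all-zero coefficient vector for sample {X.index[i]!r}"
                )
            fractions[i] = coef / total
            residuals[i] = resid
        self.residuals_ = pd.Series(residuals, index=X.index, name="residual_norm")
        return fractions

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "cell_types_")
        return np.array(self.cell_types_, dtype=object)


def deconvolve_relative(m: ExpressionMatrix, reference: ReferenceMatrix,
                        min_overlap: float = 0.5
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Relative-mode fractions for every sample of a linear-scale matrix.

    Returns ``(fractions, residual_norms)`` with fractions as a
    samples x cell-types DataFrame whose rows sum to 1.
    """
    if m.unit_tag not in ("tpm", "counts"):
        raise ValueError(
            f"deconvolution runs in linear space (tpm or counts), got {m.unit_tag!r}"
        )
    dec = ReferenceDeconvolver(reference, min_overlap=min_overlap).fit(m.data.T)
    fr = dec.transform(m.data.T)
    fractions = pd.DataFrame(fr, index=m.sample_ids, columns=dec.cell_types_)
    return fractions, dec.residuals_


def collapse_cell_types(fractions: pd.DataFrame,
                        scheme: dict[str, list[str]] | None = None
                        ) -> pd.DataFrame:
    """Sum fine-type fractions into simplified categories.

    ``scheme`` maps category -> constituent fine types.  Fine types
    claimed by two categories are an error; types absent from the
    fractions are ignored; types not named by the scheme pass through.
    """
    scheme = DEFAULT_COLLAPSE_SCHEME if scheme is None else scheme
    claimed: dict[str, str] = {}
    for cat, members in scheme.items():
        for t in members:
            if t in claimed:
                raise ValueError(
                    f"fine type {t!r} mapped to both {claimed[t]!r} and {cat!r}"
                )
            claimed[t] = cat
    out: dict[str, np.ndarray] = {}
    for col in fractions.columns:
        target = claimed.get(col, col)
        acc = out.get(target)
        out[target] = fractions[col].to_numpy(float) if acc is None else acc + fractions[col].to_numpy(float)
    return pd.DataFrame(out, index=fractions.index)


@dataclass
class ClinicalCorrelation:
    r: float
    p_value: float
    n_pairs: int
    n_dropped: int


def compare_inferred_vs_clinical(fractions: pd.DataFrame, meta: pd.DataFrame,
                                 cell_type: str = "Monocytes"
                                 ) -> ClinicalCorrelation:
    """Pearson correlation of inferred fractions vs clinical percentages.

    Pairs inferred ``cell_type`` fractions with the metadata's
    ``clinical_monocyte_pct`` (percent of leukocytes); samples with a
    missing clinical value are dropped and counted.
    """
    if cell_type not in fractions.columns:
        raise ValueError(f"cell type {cell_type!r} not in fractions")
    meta_idx = meta.set_index("sample_id")
    clinical = meta_idx["clinical_monocyte_pct"].reindex(fractions.index)
    mask = clinical.notna()
    n_dropped = int((~mask).sum())
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 paired samples, have {int(mask.sum())}")
    r, p = pearsonr(fractions.loc[mask, cell_type], clinical[mask])
    return ClinicalCorrelation(float(r), float(p), int(mask.sum()), n_dropped)
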