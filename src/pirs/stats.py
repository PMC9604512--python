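"""Group-comparison statistics, FDR correction and ROC/AUC evaluation.

The Wilcoxon rank-sum (Mann-Whitney U) test uses exact enumeration
for small tie-free samples (total n <= 12) and the tie- and
continuity-corrected normal approximation otherwise.  Multiple
comparisons within an analysis family are corrected with the
Benjamini-Hochberg step-up.  Biomarker discrimination is summarized
as the area under the ROC curve, equivalent to the Mann-Whitney U of
the positive class divided by n1*n2 (ties get half credit).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .io import filter_cytokine_support

logger = logging.getLogger(__name__)

SIDEDNESS = ("two_tailed", "one_tailed_greater", "one_tailed_less")

_ALTERNATIVES = {
    "two_tailed": "two-sided",
    "one_tailed_greater": "greater",
    "one_tailed_less": "less",
}

#: switch point between exact enumeration and the normal approximation
EXACT_MAX_N = 12


def wilcoxon_rank_sum(x, y, sidedness: str = "two_tailed") -> tuple[float, float]:
    """Mann-Whitney U of x over y and its p-value.

    Exact enumeration when n_x + n_y <= 12 and the pooled data are
    tie-free; otherwise the normal approximation with tie correction
    and continuity correction.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=_ALTERNATIVES[sidedness],
                           method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    positive_class: object


def roc_auc(scores, labels, positive_class) -> ROCResult:
    """ROC curve and trapezoidal AUC with the given positive class.

    Tied scores earn half credit, making the AUC exactly the
    Mann-Whitney U statistic of positives over negatives divided by
    n_pos * n_neg.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = _sk_roc_curve(pos.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(auc, fpr, tpr, positive_class)


@dataclass
class Contrast:
    """One two-arm comparison: which outcomes form each arm, the test
    direction, and which arm is the ROC positive class (always arm a)."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    sidedness: str = "one_tailed_greater"  # a greater than b


DEFAULT_CONTRASTS = (
    Contrast("pCR_vs_RD", ("pCR",), ("RD_nR", "RD_R")),
    Contrast("noRecurrence_vs_recurrence", ("pCR", "RD_nR"), ("RD_R",)),
)


def evaluate_biomarkers(features: pd.DataFrame, meta: pd.DataFrame,
                        contrasts=DEFAULT_CONTRASTS,
                        exclude_cytokine_support: bool = True) -> pd.DataFrame:
    """Wilcoxon p, BH q and AUC for every metric x contrast.

    ``features`` is samples x metrics (signature scores, inferred
    fractions, clinical values...).  Cytokine-support samples are
    excluded first.  Each contrast's arm a is the ROC positive class.
    BH correction runs over the whole emitted family; contrasts with an
    empty arm are skipped with a warning.
    """
    if exclude_cytokine_support:
        meta = filter_cytokine_support(meta)
    meta_idx = meta.set_index("sample_id")
    common = [s for s in features.index if s in meta_idx.index]
    features = features.loc[common]
    outcome = meta_idx.loc[common, "outcome"]

    rows = []
    for contrast in contrasts:
        in_a = outcome.isin(contrast.group_a).to_numpy()
        in_b = outcome.isin(contrast.group_b).to_numpy()
        if in_a.sum() == 0 or in_b.sum() == 0:
            logger.warning("contrast %s has an empty arm; skipped", contrast.name)
            continue
        for metric in features.columns:
            vals = features[metric].to_numpy(float)
            ok = np.isfinite(vals)
            a, b = vals[in_a & ok], vals[in_b & ok]
            if len(a) == 0 or len(b) == 0:
                logger.warning("metric %s has no finite values in an arm of %s; skipped",
                               metric, contrast.name)
                continue
            u, p = wilcoxon_rank_sum(a, b, contrast.sidedness)
            merged = np.concatenate([a, b])
            lab = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
            auc = roc_auc(merged, lab, positive_class=1.0).auc
            rows.append(dict(metric=metric, contrast=contrast.name,
                             n_a=len(a), n_b=len(b), U=u, p_value=p,
                             sidedness=contrast.sidedness, auc=auc))
    report = pd.DataFrame(rows)
    if len(report):
        report["q_value"] = bh_fdr(report["p_value"].to_numpy())
    return report


def paired_change(pre, post, sidedness: str = "two_tailed") -> tuple[float, float]:
    """Median post-minus-pre change and Wilcoxon signed-rank p.

    Zero differences are dropped by convention; fewer than 3 non-zero
    pairs is an error.  Exact null enumeration for <= 12 non-zero
    pairs, normal approximation otherwise.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if len(pre) != len(post):
        raise ValueError("pre and post must be paired (equal length)")
    if len(pre) < 3:
        raise ValueError("need >= 3 pairs")
    diff = post - pre
    nonzero = diff[diff != 0]
    if len(nonzero) < 3:
        raise ValueError(f"need >= 3 non-zero paired differences, have {len(nonzero)}")
    method = "exact" if len(nonzero) <= EXACT_MAX_N else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on exact-with-ties midranks
        res = sps.wilcoxon(nonzero, alternative=_ALTERNATIVES[sidedness], method=method)
    return float(np.median(diff)), float(res.pvalue)
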