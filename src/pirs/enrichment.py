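"""Preranked gene-set enrichment with leading-edge extraction.

Genes are ranked by a signal-to-noise statistic between two sample
groups; each gene set is scored with the weighted Kolmogorov-Smirnov
running sum (hits increment by |metric|^p normalized over the set,
misses decrement by 1/(N - |set|); the enrichment score ES is the
running-sum value of maximal absolute deviation).  Significance comes
from gene-set permutations: random sets of matching size drawn from
the ranked genes give a null ES distribution per set; NES divides ES
by the mean |null ES| of matching sign, p is the permutation tail
probability with +1 smoothing, and q is the sign-stratified
ratio-of-tails false discovery rate conventional for this method.

Leading-edge genes are the set members at or before the peak (for
positive ES; at or after it for negative ES) — the members that drive
the enrichment.  The union of leading edges across related pathways,
deduplicated, forms a compact signature for downstream scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    q_value: float
    leading_edge: list[str]
    peak_index: int  # 1-based rank position of the running-sum peak


def rank_genes(m: ExpressionMatrix, groups: pd.Series | dict,
               positive: str | None = None) -> pd.Series:
    """Rank genes by signal-to-noise between two sample groups.

    metric_g = (mean_1 - mean_0) / (sd_1 + sd_0), with each group SD
    floored at max(0.2 * |group mean|, 0.2) — the classic floor that
    keeps low-variance genes from dominating.  ``positive`` names the
    group treated as group 1 (default: first label encountered).
    Returns a Series of metrics indexed by gene, sorted descending with
    ties broken lexicographically by symbol.
    """
    groups = pd.Series(groups)
    labels = groups.reindex(m.sample_ids)
    if labels.isna().any():
        raise ValueError("group labels missing for some samples")
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    pos = positive if positive is not None else levels[0]
    neg = [l for l in levels if l != pos][0]
    X1 = m.data.loc[:, (labels == pos).to_numpy()].to_numpy(float)
    X0 = m.data.loc[:, (labels == neg).to_numpy()].to_numpy(float)
    if X1.shape[1] < 2 or X0.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    def _mu_sd(X):
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        return mu, np.maximum(sd, np.maximum(0.2 * np.abs(mu), 0.2))

    mu1, sd1 = _mu_sd(X1)
    mu0, sd0 = _mu_sd(X0)
    metric = (mu1 - mu0) / (sd1 + sd0)
    out = pd.Series(metric, index=m.data.index, name="signal_to_noise")
    order = sorted(range(len(out)), key=lambda i: (-out.iloc[i], str(out.index[i])))
    return out.iloc[order]


def enrichment_score(ranked: pd.Series, gene_set, weight_p: float = 1.0
                     ) -> tuple[float, np.ndarray, int]:
    """Weighted-KS enrichment score of one gene set in a ranked list.

    Returns ``(es, running_sum, peak_index)`` with ``peak_index``
    1-based.  Ties in |running sum| resolve to the earliest position.
    """
    genes = np.asarray(ranked.index)
    metric = ranked.to_numpy(float)
    hit = np.isin(genes, list(gene_set))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set has no member in the ranked list")
    N = len(genes)
    if n_hits == N:
        raise ValueError("gene set covers the entire ranked list; misses undefined")
    weights = np.abs(metric) ** weight_p
    hit_total = weights[hit].sum()
    if hit_total == 0:
        # all member metrics are zero: fall back to unweighted hits
        steps = np.where(hit, 1.0 / n_hits, -1.0 / (N - n_hits))
    else:
        steps = np.where(hit, weights / hit_total, -1.0 / (N - n_hits))
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak + 1


def leading_edge(ranked: pd.Series, gene_set, es: float, peak_index: int) -> list[str]:
    """Set members at ranks <= peak (ES > 0) or >= peak (ES < 0), in rank order."""
    if es == 0:
        raise ValueError("leading edge undefined for ES = 0")
    genes = list(ranked.index)
    members = set(gene_set)
    if es > 0:
        window = genes[:peak_index]
    else:
        window = genes[peak_index - 1:]
    return [g for g in window if g in members]


def _null_es(ranked: pd.Series, set_size: int, n_perm: int,
             rng: np.random.Generator, weight_p: float) -> np.ndarray:
    genes = np.asarray(ranked.index)
    metric = ranked.to_numpy(float)
    N = len(genes)
    weights = np.abs(metric) ** weight_p
    miss_step = -1.0 / (N - set_size)
    out = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(N, size=set_size, replace=False)
        hit = np.zeros(N, dtype=bool)
        hit[idx] = True
        hit_total = weights[hit].sum()
        if hit_total == 0:
            steps = np.where(hit, 1.0 / set_size, -1.0 / (N - set_size))
        else:
            steps = np.where(hit, weights / hit_total, miss_step)
        running = np.cumsum(steps)
        out[i] = running[np.argmax(np.abs(running))]
    return out


def nes_and_fdr(gene_sets: dict[str, list[str]], ranked: pd.Series,
                n_perm: int = 1000, seed: int = 0, weight_p: float = 1.0
                ) -> list[EnrichmentResult]:
    """Normalize ES and assign permutation p / FDR q to each gene set.

    Null ES per set come from ``n_perm`` random same-size sets drawn from
    the ranked genes.  NES = ES / mean |null ES of matching sign|;
    p = (1 + #{same-sign nulls with |ES_null| >= |ES|}) / (1 + #same-sign);
    q = sign-stratified ratio of tails over normalized null and observed
    NES, clipped to [0, 1] and made monotone.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    raw: list[dict] = []
    null_nes_pool: list[np.ndarray] = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in ranked.index]
        es, running, peak = enrichment_score(ranked, present, weight_p)
        nulls = _null_es(ranked, len(present), n_perm, rng, weight_p)
        same = nulls[np.sign(nulls) == np.sign(es)] if es != 0 else nulls
        if len(same) == 0:
            logger.warning("gene set %s: no null ES of matching sign; NES undefined", name)
            nes, p = np.nan, np.nan
        else:
            denom = np.abs(same).mean()
            nes = es / denom
            p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + len(same))
        # normalize nulls sign-wise for the FDR pool
        pos, negv = nulls[nulls > 0], nulls[nulls < 0]
        norm = np.concatenate([
            pos / pos.mean() if len(pos) else pos,
            negv / np.abs(negv).mean() if len(negv) else negv,
        ])
        null_nes_pool.append(norm)
        raw.append(dict(name=name, es=es, nes=nes, p=p,
                        le=leading_edge(ranked, present, es, peak) if es != 0 else [],
                        peak=peak))

    all_null = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs_nes = np.array([r["nes"] for r in raw])
    results: list[EnrichmentResult] = []
    for r in raw:
        nes = r["nes"]
        if not np.isfinite(nes):
            q = np.nan
        elif nes >= 0:
            null_tail = (all_null >= nes).sum() / max((all_null >= 0).sum(), 1)
            obs_tail = (obs_nes >= nes).sum() / max((obs_nes >= 0).sum(), 1)
            q = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else np.nan
        else:
            null_tail = (all_null <= nes).sum() / max((all_null < 0).sum(), 1)
            obs_tail = (obs_nes <= nes).sum() / max((obs_nes < 0).sum(), 1)
            q = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else np.nan
        results.append(EnrichmentResult(r["name"], r["es"], nes, r["p"], q,
                                        r["le"], r["peak"]))
    # enforce q monotone in |NES| within each sign
    for sign in (1, -1):
        idx = [i for i, r in enumerate(results)
               if np.isfinite(r.nes) and np.sign(r.nes) == sign]
        idx.sort(key=lambda i: -abs(results[i].nes))
        running_min = np.inf
        for i in idx:
            running_min = min(running_min, results[i].q_value)
            results[i].q_value = running_min
    return results


def union_signature(leading_edges: list[list[str]],
                    name: str = "ifn_complement") -> GeneSignature:
    """Deduplicated union of leading-edge gene lists, all signs +1,
    sorted lexicographically."""
    if not leading_edges:
        raise ValueError("need at least one leading-edge list")
    union = sorted(set().union(*map(set, leading_edges)))
    if not union:
        raise ValueError("union of leading edges is empty")
    logger.info("union signature %s: %d unique genes", name, len(union))
    return GeneSignature.from_genes(name, union, sign=1)
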