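"""Synthetic whole-blood cohorts with known ground truth.

The generator emulates the statistical structure the downstream
analysis assumes, so every stage can be verified against a recorded
truth without any external download:

* bulk expression is a convex mixture of cell-type mean profiles,
  with per-sample fractions drawn from group-specific Dirichlet
  distributions;
* the monocyte mean fraction is shifted by outcome group (by default
  highest in pCR, intermediate in residual disease, lowest without
  neoadjuvant chemotherapy);
* an IFN/complement program is planted in the monocyte contribution
  of pCR samples and a cytotoxic program in the CD8/NK contribution
  of recurrent samples, mirroring the cell-type-restricted expression
  of the two signatures;
* red-blood-cell contamination genes (the standard 25-symbol
  exclusion list) claim a fixed slice of every library;
* counts are negative binomial with variance mu + phi * mu^2 around
  log-normally varying library sizes;
* a NanoString-style panel adds positive/negative spike-ins,
  housekeepers, and a per-sample multiplicative technical factor.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ReferenceMatrix
from .preprocess import RBC_EXCLUSION_GENES

GROUPS = ("pCR", "RD_nR", "RD_R", "noNAC")

_DEFAULT_BASE_FRACTIONS = {
    "Monocytes": 0.20,
    "CD8_T": 0.15,
    "NK": 0.10,
    "CD4_T": 0.25,
    "B_cells": 0.10,
    "Granulocytes": 0.20,
}

#: the 7 positively-weighted cytotoxic-score genes planted in CD8/NK profiles
_CYTOTOXIC_CORE = ("FGFBP2", "GNLY", "GZMB", "GZMH", "NKG7", "LAG3", "PDCD1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``monocyte_shift`` is an additive shift to the monocyte mean
    fraction per outcome group; ``ifn_effect`` / ``cytotoxic_effect``
    are log2 fold-changes applied to the planted programs' expression
    in their designated cell types (monocytes of pCR samples; CD8/NK
    of recurrent samples).  ``nb_dispersion`` is phi in
    var = mu + phi * mu^2.
    """

    n_per_group: int | dict[str, int] = 50
    n_genes: int = 600
    cell_types: tuple[str, ...] = tuple(_DEFAULT_BASE_FRACTIONS)
    base_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE_FRACTIONS))
    dirichlet_concentration: float = 100.0
    monocyte_shift: dict[str, float] = field(
        default_factory=lambda: {"pCR": 0.05, "RD_nR": 0.0, "RD_R": 0.0,
                                 "noNAC": -0.05})
    ifn_effect: float = 1.0
    cytotoxic_effect: float = 1.0
    nb_dispersion: float = 0.1
    library_size_mean: float = 5e5
    rbc_fraction: float = 0.05
    n_ifn_genes: int = 30
    n_cytotoxic_genes: int = 10
    clinical_noise_sd: float = 7.0
    clinical_coverage: float = 0.7
    cytokine_support_rate: float = 0.02
    paired_design: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for required in ("Monocytes", "CD8_T", "NK"):
            if required not in self.cell_types:
                raise ValueError(f"cell_types must include {required!r}")
        if len(self.cell_types) < 6:
            raise ValueError("need Monocytes, CD8_T, NK plus at least 3 other types")
        if set(self.base_fractions) != set(self.cell_types):
            raise ValueError("base_fractions must cover exactly the configured cell types")
        vec = np.array([self.base_fractions[t] for t in self.cell_types])
        if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-8:
            raise ValueError("base_fractions must be non-negative and sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.rbc_fraction < 1:
            raise ValueError("rbc_fraction must be in [0, 1)")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        mono = self.base_fractions["Monocytes"]
        for g, shift in self.monocyte_shift.items():
            if mono + shift < 0 or mono + shift > 1:
                raise ValueError(f"monocyte_shift for {g} leaves an invalid fraction")

    def group_sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_group, dict):
            sizes = {g: int(self.n_per_group.get(g, 0)) for g in GROUPS}
        else:
            sizes = {g: int(self.n_per_group) for g in GROUPS}
        if sum(n > 0 for n in sizes.values()) < 2:
            raise ValueError("at least two outcome groups must be non-empty")
        return sizes

    def null(self) -> "SimulationConfig":
        """Copy of the config with every planted effect switched off."""
        import dataclasses
        return dataclasses.replace(
            self,
            monocyte_shift={g: 0.0 for g in GROUPS},
            ifn_effect=0.0,
            cytotoxic_effect=0.0,
        )


@dataclass
class SyntheticTruth:
    """Recorded ground truth for recovery tests."""

    true_fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    planted_signature_genes: dict[str, list[str]]
    effect_sizes: dict[str, float]


def _gene_names(config: SimulationConfig) -> tuple[list[str], dict[str, list[int]]]:
    """Lay out the reference gene list: per-type marker blocks, then the
    planted cytotoxic and IFN program genes, HLA-G, then filler."""
    K = len(config.cell_types)
    if config.n_genes < 10 * K:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {K} cell types "
            f"(need >= {10 * K} for marker blocks)")
    block = config.n_genes // (2 * K)
    names: list[str] = []
    roles: dict[str, list[int]] = {f"marker_{t}": [] for t in config.cell_types}
    for k, t in enumerate(config.cell_types):
        for j in range(block):
            roles[f"marker_{t}"].append(len(names))
            names.append(f"MK_{t}_{j:03d}")
    cyt_names = list(_CYTOTOXIC_CORE[: config.n_cytotoxic_genes])
    cyt_names += [f"CTX{j:02d}" for j in range(len(cyt_names) + 1,
                                               config.n_cytotoxic_genes + 1)]
    roles["cytotoxic"] = list(range(len(names), len(names) + len(cyt_names)))
    names.extend(cyt_names)
    roles["ifn"] = list(range(len(names), len(names) + config.n_ifn_genes))
    names.extend(f"IFNC{j:02d}" for j in range(1, config.n_ifn_genes + 1))
    roles["hla_g"] = [len(names)]
    names.append("HLA-G")
    fill = config.n_genes - len(names)
    if fill < 0:
        raise ValueError("n_genes too small for the planted programs; increase n_genes")
    names.extend(f"G{j:05d}" for j in range(fill))
    return names, roles


def generate_reference_profiles(config: SimulationConfig) -> ReferenceMatrix:
    """Cell-type mean expression profiles with disjoint marker blocks.

    Every gene has a shared log-normal baseline with mild per-type
    jitter; each type's marker block is boosted 30x in that type, the
    planted cytotoxic program 20x in CD8 and NK, and the planted
    IFN/complement program 20x in monocytes.  Deterministic under the
    config seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    names, roles = _gene_names(config)
    K = len(config.cell_types)
    base = 2.0 ** rng.normal(2.0, 1.5, size=config.n_genes)
    jitter = 2.0 ** rng.normal(0.0, 0.4, size=(K, config.n_genes))
    profiles = base[None, :] * jitter
    for k, t in enumerate(config.cell_types):
        profiles[k, roles[f"marker_{t}"]] *= 30.0
    for t in ("CD8_T", "NK"):
        k = config.cell_types.index(t)
        profiles[k, roles["cytotoxic"]] *= 20.0
    k_mono = config.cell_types.index("Monocytes")
    profiles[k_mono, roles["ifn"]] *= 20.0
    df = pd.DataFrame(profiles, index=list(config.cell_types), columns=names)
    return ReferenceMatrix(df)


def _group_mean_fractions(config: SimulationConfig, group: str) -> np.ndarray:
    """Base fractions with the group's monocyte shift, other types
    rescaled proportionally so the vector still sums to 1."""
    vec = np.array([config.base_fractions[t] for t in config.cell_types], float)
    i = config.cell_types.index("Monocytes")
    shift = config.monocyte_shift.get(group, 0.0)
    new_mono = vec[i] + shift
    rest = 1.0 - vec[i]
    out = vec * ((1.0 - new_mono) / rest if rest > 0 else 0.0)
    out[i] = new_mono
    return out


def generate_cohort(config: SimulationConfig, reference: ReferenceMatrix
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic cohort: counts, metadata, and ground truth.

    Per sample, cell fractions come from the group's Dirichlet; the
    expected expression is the fraction-weighted mixture of reference
    profiles with the planted programs scaled in their designated cell
    types and groups; negative-binomial counts are drawn at the
    configured dispersion around a log-normal library size, with the
    25 red-blood-cell contamination genes taking ``rbc_fraction`` of
    every library.
    """
    missing = [t for t in config.cell_types if t not in reference.cell_type_ids]
    if missing:
        raise ValueError(f"reference does not cover cell types: {missing}")
    rng = np.random.default_rng([config.seed, 1])
    sizes = config.group_sizes()
    names, roles = _gene_names(config)
    if list(reference.gene_ids) != names:
        raise ValueError("reference gene layout does not match the config")
    R = reference.profiles.loc[list(config.cell_types)].to_numpy(float)
    K = len(config.cell_types)
    i_mono = config.cell_types.index("Monocytes")
    i_cd8 = config.cell_types.index("CD8_T")
    i_nk = config.cell_types.index("NK")

    rows = []  # (sample_id, group, timepoint, shifted: bool)
    sid = 0
    for group in GROUPS:
        for _ in range(sizes[group]):
            sid += 1
            if config.paired_design:
                rows.append((f"S{sid:03d}_pre", group, "pre", False))
                rows.append((f"S{sid:03d}_post", group, "post", True))
            else:
                rows.append((f"S{sid:03d}", group, "post", True))

    n_samples = len(rows)
    fractions = np.empty((n_samples, K))
    for j, (_, group, _, shifted) in enumerate(rows):
        mean = (_group_mean_fractions(config, group) if shifted
                else np.array([config.base_fractions[t] for t in config.cell_types]))
        alpha = np.maximum(mean * config.dirichlet_concentration, 1e-6)
        fractions[j] = rng.dirichlet(alpha)

    expected = fractions @ R
    ifn_boost = 2.0 ** config.ifn_effect - 1.0
    cyt_boost = 2.0 ** config.cytotoxic_effect - 1.0
    for j, (_, group, _, _) in enumerate(rows):
        if group == "pCR" and ifn_boost != 0.0:
            expected[j, roles["ifn"]] += (
                fractions[j, i_mono] * R[i_mono, roles["ifn"]] * ifn_boost)
        if group == "RD_R" and cyt_boost != 0.0:
            expected[j, roles["cytotoxic"]] += cyt_boost * (
                fractions[j, i_cd8] * R[i_cd8, roles["cytotoxic"]]
                + fractions[j, i_nk] * R[i_nk, roles["cytotoxic"]])

    # gene sampling proportions: endogenous share plus the RBC slice
    props = expected / expected.sum(axis=1, keepdims=True) * (1.0 - config.rbc_fraction)
    n_rbc = len(RBC_EXCLUSION_GENES)
    rbc_props = np.full((n_samples, n_rbc), config.rbc_fraction / n_rbc)
    all_props = np.hstack([props, rbc_props])
    libsize = config.library_size_mean * 2.0 ** rng.normal(0.0, 0.3, size=n_samples)
    mu = all_props * libsize[:, None]
    r = 1.0 / config.nb_dispersion
    p_nb = r / (r + mu)
    counts = rng.negative_binomial(r, p_nb)

    gene_index = names + list(RBC_EXCLUSION_GENES)
    sample_ids = [r0[0] for r0 in rows]
    matrix = ExpressionMatrix(
        pd.DataFrame(counts.T, index=gene_index, columns=sample_ids), "counts")

    mono_frac = fractions[:, i_mono]
    clinical = 100.0 * mono_frac + rng.normal(0.0, config.clinical_noise_sd, n_samples)
    clinical = np.clip(clinical, 0.0, 100.0)
    observed = rng.random(n_samples) < config.clinical_coverage
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "outcome": [r0[1] for r0 in rows],
        "timepoint": [r0[2] for r0 in rows],
        "cytokine_support": rng.random(n_samples) < config.cytokine_support_rate,
        "clinical_monocyte_pct": np.where(observed, clinical, np.nan),
    })

    truth = SyntheticTruth(
        true_fractions=pd.DataFrame(fractions, index=sample_ids,
                                    columns=list(config.cell_types)),
        planted_signature_genes={
            "ifn_complement": [names[i] for i in roles["ifn"]],
            "cytotoxic": [names[i] for i in roles["cytotoxic"]],
        },
        effect_sizes={
            "ifn_effect": config.ifn_effect,
            "cytotoxic_effect": config.cytotoxic_effect,
            **{f"monocyte_shift[{g}]": s for g, s in config.monocyte_shift.items()},
        },
    )
    return matrix, meta, truth


def default_gene_lengths(gene_ids, seed: int = 0) -> pd.Series:
    """Plausible transcript lengths (bp) for synthetic genes, log-normal
    around ~1.5 kb, deterministic per seed."""
    rng = np.random.default_rng([seed, 3])
    lengths = np.round(2.0 ** rng.normal(10.5, 0.6, size=len(gene_ids))).astype(int)
    return pd.Series(np.maximum(lengths, 200), index=list(gene_ids), dtype=float)


# ---------------------------------------------------------------------------
# NanoString-style panel

_POS_LADDER = {"POS_A": 25600.0, "POS_B": 6400.0, "POS_C": 1600.0,
               "POS_D": 400.0, "POS_E": 100.0, "POS_F": 25.0}
_NEG_BACKGROUND = 12.0
_HK_LEVELS = {"HK_1": 2000.0, "HK_2": 1000.0, "HK_3": 500.0}


def generate_nanostring(config: SimulationConfig,
                        technical_factors: np.ndarray | None = None,
                        noise: bool = True
                        ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Raw NanoString-style panel counts with control annotations.

    The panel holds the PIRS genes (planted IFN/complement program plus
    the 8 cytotoxic-score genes), 6 positive spike-ins on a standard
    titration ladder, 8 negative spike-ins near background, and 3
    housekeepers.  A per-sample multiplicative technical factor (drawn
    log-normal unless supplied) scales every probe; ``noise=False``
    yields the deterministic expected counts, which is useful for
    normalization identities.

    Returns ``(raw_counts, annotations, metadata)``.
    """
    rng = np.random.default_rng([config.seed, 2])
    sizes = config.group_sizes()
    sample_ids, groups = [], []
    sid = 0
    for group in GROUPS:
        for _ in range(sizes[group]):
            sid += 1
            sample_ids.append(f"N{sid:03d}")
            groups.append(group)
    n = len(sample_ids)

    ifn_genes = [f"IFNC{j:02d}" for j in range(1, config.n_ifn_genes + 1)]
    cyt_genes = list(_CYTOTOXIC_CORE) + ["HLA-G"]
    endo = ifn_genes + cyt_genes
    base = pd.Series(2.0 ** rng.normal(8.0, 1.0, size=len(endo)), index=endo)

    mult = pd.DataFrame(1.0, index=endo, columns=sample_ids)
    for j, g in enumerate(groups):
        if g == "pCR":
            mult.loc[ifn_genes, sample_ids[j]] = 2.0 ** config.ifn_effect
        if g == "RD_R":
            mult.loc[list(_CYTOTOXIC_CORE), sample_ids[j]] = 2.0 ** config.cytotoxic_effect

    if technical_factors is None:
        factors = 2.0 ** rng.normal(0.0, 0.3, size=n)
    else:
        factors = np.asarray(technical_factors, float)
        if factors.shape != (n,):
            raise ValueError(f"technical_factors must have shape ({n},)")

    panel_rows = endo + list(_POS_LADDER) + [f"NEG_{j}" for j in range(1, 9)] + list(_HK_LEVELS)
    expected = pd.DataFrame(0.0, index=panel_rows, columns=sample_ids)
    expected.loc[endo] = base.to_numpy()[:, None] * mult.to_numpy()
    for g, level in _POS_LADDER.items():
        expected.loc[g] = level
    expected.loc[[f"NEG_{j}" for j in range(1, 9)]] = _NEG_BACKGROUND
    for g, level in _HK_LEVELS.items():
        expected.loc[g] = level
    expected = expected * factors[None, :]

    if noise:
        raw = pd.DataFrame(rng.poisson(expected.to_numpy()),
                           index=panel_rows, columns=sample_ids).astype(float)
    else:
        raw = expected

    annotations = pd.Series("endogenous", index=panel_rows)
    annotations.loc[list(_POS_LADDER)] = "positive"
    annotations.loc[[f"NEG_{j}" for j in range(1, 9)]] = "negative"
    annotations.loc[list(_HK_LEVELS)] = "housekeeper"

    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "outcome": groups,
        "timepoint": "post",
        "cytokine_support": rng.random(n) < config.cytokine_support_rate,
        "clinical_monocyte_pct": np.nan,
    })
    return raw, annotations, meta
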