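"""Core in-memory containers for the blood-biomarker pipeline.

Expression data travels as a genes x samples :class:`pandas.DataFrame`
wrapped in :class:`ExpressionMatrix`, which carries a unit tag so each
stage can assert it receives the unit it expects (raw counts, TPM,
log2, or per-gene z-scores).  Sample annotations are a plain DataFrame
validated by :func:`validate_metadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNIT_TAGS = ("counts", "tpm", "log2", "zscore")

OUTCOMES = ("pCR", "RD_nR", "RD_R", "noNAC")
TIMEPOINTS = ("pre", "post")

#: metadata columns required by the pipeline
METADATA_COLUMNS = ("sample_id", "outcome", "timepoint", "cytokine_support")


def _find_duplicates(items) -> list:
    seen: set = set()
    dups: list = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared unit.

    Parameters
    ----------
    data:
        DataFrame indexed by gene symbol with one column per sample.
    unit_tag:
        One of ``counts``, ``tpm``, ``log2``, ``zscore``.
    """

    data: pd.DataFrame
    unit_tag: str = "counts"

    def __post_init__(self) -> None:
        if self.unit_tag not in UNIT_TAGS:
            raise ValueError(
                f"unit_tag must be one of {UNIT_TAGS}, got {self.unit_tag!r}"
            )
        dup_genes = _find_duplicates(self.data.index)
        if dup_genes:
            raise ValueError(f"duplicate gene IDs: {dup_genes}")
        dup_samples = _find_duplicates(self.data.columns)
        if dup_samples:
            raise ValueError(f"duplicate sample IDs: {dup_samples}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.unit_tag in ("counts", "tpm") and np.nanmin(values, initial=0) < 0:
            raise ValueError(f"{self.unit_tag} values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, unit_tag: str | None = None) -> "ExpressionMatrix":
        """Return a new matrix with replaced values (and optionally unit)."""
        return ExpressionMatrix(data, unit_tag or self.unit_tag)


@dataclass(frozen=True)
class GeneSignature:
    """A named set of (gene, sign) pairs scored as a signed mean of z-scores."""

    name: str
    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError(f"signature {self.name!r} has no entries")
        genes = [g for g, _ in self.entries]
        dups = _find_duplicates(genes)
        if dups:
            raise ValueError(f"signature {self.name!r} has duplicate genes: {dups}")
        bad = [s for _, s in self.entries if s not in (1, -1)]
        if bad:
            raise ValueError(f"signature {self.name!r} has signs outside {{+1,-1}}: {bad}")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def signs(self) -> dict[str, int]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_genes(cls, name: str, genes, sign: int = 1) -> "GeneSignature":
        return cls(name, tuple((g, sign) for g in genes))


@dataclass
class ReferenceMatrix:
    """Cell-type mean expression profiles (cell types x genes), linear scale."""

    profiles: pd.DataFrame  # index: cell types, columns: genes

    def __post_init__(self) -> None:
        dup_t = _find_duplicates(self.profiles.index)
        if dup_t:
            raise ValueError(f"duplicate cell-type IDs: {dup_t}")
        dup_g = _find_duplicates(self.profiles.columns)
        if dup_g:
            raise ValueError(f"duplicate gene IDs: {dup_g}")
        vals = self.profiles.to_numpy()
        if np.min(vals, initial=0) < 0:
            raise ValueError("reference profiles must be non-negative")
        if (vals.max(axis=1, initial=0) <= 0).any():
            dead = list(self.profiles.index[vals.max(axis=1) <= 0])
            raise ValueError(f"cell types with no positive expression: {dead}")

    @property
    def cell_type_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.columns)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it unchanged.

    Required columns: sample_id, outcome, timepoint, cytokine_support.
    Optional: clinical_monocyte_pct (percent of leukocytes, in [0, 100],
    NaN when not measured), cohort.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    dups = _find_duplicates(meta["sample_id"])
    if dups:
        raise ValueError(f"duplicate sample IDs in metadata: {dups}")
    bad_outcome = sorted(set(meta["outcome"]) - set(OUTCOMES))
    if bad_outcome:
        raise ValueError(f"unknown outcome labels: {bad_outcome}")
    bad_tp = sorted(set(meta["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValueError(f"unknown timepoint labels: {bad_tp}")
    if "clinical_monocyte_pct" in meta.columns:
        vals = meta["clinical_monocyte_pct"].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError("clinical_monocyte_pct outside [0, 100]")
    return meta
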