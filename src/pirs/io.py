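"""Reading and writing the pipeline's file formats.

Expression matrices and metadata are delimited text (tab for ``.tsv`` /
``.txt``, comma for ``.csv``); gene sets use the standard GMT layout
(name, description, then member genes, tab-separated); signed
signatures are two-column tables (symbol, sign).  Configuration is
YAML.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, GeneSignature, validate_metadata

logger = logging.getLogger(__name__)


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, unit_tag: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples delimited matrix.

    The first column holds gene IDs; the header row holds sample IDs.
    Row and column order are preserved.  Duplicated gene IDs or
    non-numeric cells raise ``ValueError`` identifying the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0,
                     float_precision="round_trip")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene IDs in {path.name}: {dup}")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"non-numeric value in {path.name} at gene {gene!r}, sample {sample!r}: "
            f"{df.loc[gene, sample]!r}"
        )
    return ExpressionMatrix(coerced, unit_tag)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write a matrix with shortest round-trip float formatting, so
    write -> read reproduces values bit-exactly."""
    path = Path(path)
    m.data.to_csv(path, sep=_delimiter(path), index_label="gene_id")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered mapping of set name -> gene list.

    Within-set duplicate genes are dropped with a warning; duplicate set
    names or lines with fewer than three fields are errors.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3 "
                    "(name, description, genes...)"
                )
            name, _desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r} at line {lineno}")
            unique = list(dict.fromkeys(g for g in genes if g))
            if len(unique) < len([g for g in genes if g]):
                logger.warning("gene set %s: dropped duplicate genes within set", name)
            sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_signature(path, name: str | None = None) -> GeneSignature:
    """Read a signed signature from two-column text (symbol, sign)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: expected two columns (gene, sign)")
    entries = tuple((str(g), int(s)) for g, s in zip(df.iloc[:, 0], df.iloc[:, 1]))
    return GeneSignature(name or path.stem, entries)


def write_signature(sig: GeneSignature, path) -> None:
    path = Path(path)
    pd.DataFrame(sig.entries, columns=["gene", "sign"]).to_csv(
        path, sep=_delimiter(path), index=False
    )


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_delimiter(path))
    # empty field = not measured; zero is a valid measurement and is kept
    meta["cytokine_support"] = meta["cytokine_support"].astype(bool)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    path = Path(path)
    meta.to_csv(path, sep=_delimiter(path), index=False)


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column (gene, length-in-bp) table into a Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path))
    lengths = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive gene lengths: {bad}")
    return lengths


def filter_cytokine_support(meta: pd.DataFrame) -> pd.DataFrame:
    """Drop samples flagged for cytokine-support products (e.g. GCSF).

    Patients given such products shortly before surgery are excluded
    because the products themselves perturb monocyte counts.  Retained
    samples keep their original order.
    """
    keep = ~meta["cytokine_support"].astype(bool)
    n_removed = int((~keep).sum())
    if n_removed == len(meta):
        logger.warning("all %d samples flagged for cytokine support; none retained", n_removed)
    else:
        logger.info("excluded %d cytokine-support sample(s)", n_removed)
    return meta.loc[keep].copy()


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
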