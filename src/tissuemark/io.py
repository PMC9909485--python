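"""Readers, writers and selection rules for the pipeline's file formats.

Conventions
-----------
* An expression matrix is a :class:`pandas.DataFrame` of non-negative TPM
  values with genes as the index and samples as the columns (GCT
  orientation).
* A sample annotation is a :class:`pandas.DataFrame` indexed by sample ID
  with a mandatory ``tissue`` column; any further columns are free-form
  attributes (sex, age band, death class, detailed site ...).
* All numeric serialization uses 6 significant digits; round-trips are
  lossless at that precision.
* Rows dropped by any reader or filter are warned about through the module
  logger, never silently discarded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: serialization precision (significant digits) for all TSV/GCT output
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants: unique IDs, finite, non-negative."""
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate gene IDs: {dupes}")
    if expr.columns.duplicated().any():
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate sample IDs: {dupes}")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValidationError("expression matrix contains negative values")
    return expr


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Check sample-annotation invariants: unique samples, non-empty tissue."""
    if "tissue" not in annot.columns:
        raise FormatError("annotation lacks a 'tissue' column")
    if annot.index.duplicated().any():
        dupes = annot.index[annot.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate sample IDs: {dupes}")
    if (annot["tissue"].astype(str).str.strip() == "").any():
        raise ValidationError("annotation contains empty tissue labels")
    return annot


# ---------------------------------------------------------------------------
# GCT v1.2
# ---------------------------------------------------------------------------

def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT v1.2 expression file into a genes x samples DataFrame.

    The ``Description`` column is stored in ``df.attrs["description"]``;
    the values themselves are validated to be finite and non-negative.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer GCT dimensions") from exc
        table = pd.read_csv(fh, sep="\t", header=0, dtype={0: str, 1: str})
    if table.shape[0] != n_genes:
        raise FormatError(
            f"{path}: header declares {n_genes} genes but file has {table.shape[0]} rows"
        )
    if table.shape[1] != n_samples + 2:
        raise FormatError(
            f"{path}: header declares {n_samples} samples but file has "
            f"{table.shape[1] - 2} sample columns"
        )
    expr = table.set_index(table.columns[0])
    expr.index = expr.index.astype(str)
    expr.index.name = "gene_id"
    description = expr.iloc[:, 0]
    expr = expr.iloc[:, 1:].astype(float)
    validate_expression(expr)
    expr.attrs["description"] = description.to_dict()
    return expr


def write_gct(expr: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples DataFrame as GCT v1.2 (6 significant digits)."""
    validate_expression(expr)
    path = Path(path)
    desc = expr.attrs.get("description", {})
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, expr.columns)) + "\n")
        for gene, row in zip(expr.index, expr.to_numpy()):
            values = "\t".join(FLOAT_FORMAT % v for v in row)
            fh.write(f"{gene}\t{desc.get(gene, gene)}\t{values}\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Explicit TSV fallback: first column gene IDs, remaining columns samples."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.index.name = "gene_id"
    return validate_expression(expr.astype(float))


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(
    path: str | Path,
    sample_col: str = "sample_id",
    tissue_col: str = "tissue",
) -> pd.DataFrame:
    """Read a sample metadata TSV into an annotation frame.

    Rows with an empty tissue label are dropped with a logged count;
    duplicate sample IDs are an error.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in (sample_col, tissue_col):
        if col not in table.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    table = table.rename(columns={sample_col: "sample_id", tissue_col: "tissue"})
    empty = table["tissue"].isna() | (table["tissue"].str.strip() == "")
    if empty.any():
        logger.warning("%s: dropped %d rows with empty tissue label", path, int(empty.sum()))
        table = table.loc[~empty]
    annot = table.set_index("sample_id")
    return validate_annotation(annot)


def write_metadata(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# tissue-level sample selection
# ---------------------------------------------------------------------------

@dataclass
class TissueFilterConfig:
    """Sample-selection rules applied before any statistics.

    ``min_samples_per_tissue`` keeps only tissues with at least that many
    samples (tissues with fewer are removed, so 100 itself is retained at the
    default). Cultured-fibroblast samples hiding inside a tissue category are
    re-labelled: any sample whose ``fibroblast_attribute`` annotation column
    (every attribute column if ``None``) equals ``fibroblast_source_label``
    gets ``fibroblast_target_label`` as its tissue.
    """

    min_samples_per_tissue: int = 100
    fibroblast_source_label: str = "Cells - Cultured fibroblasts"
    fibroblast_target_label: str = "cultured fibroblast"
    fibroblast_attribute: str | None = None

    def __post_init__(self) -> None:
        if self.min_samples_per_tissue < 1:
            raise ValidationError("min_samples_per_tissue must be >= 1")


def filter_tissues(annot: pd.DataFrame, cfg: TissueFilterConfig) -> pd.DataFrame:
    """Drop samples of tissues with fewer than ``min_samples_per_tissue``."""
    if annot.empty:
        raise ValidationError("annotation is empty")
    counts = annot["tissue"].value_counts()
    keep = counts.index[counts >= cfg.min_samples_per_tissue]
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.warning(
            "dropping %d tissues below %d samples: %s",
            len(dropped), cfg.min_samples_per_tissue, dropped,
        )
    out = annot.loc[annot["tissue"].isin(keep)]
    if out.empty:
        raise EmptyResultError("no tissue meets the minimum sample count")
    return out


def recategorize_samples(annot: pd.DataFrame, cfg: TissueFilterConfig) -> pd.DataFrame:
    """Re-label cultured-fibroblast samples as their own tissue category.

    Matching is annotation-driven (never expression-driven): a sample matches
    when the configured attribute column — or any attribute column, or the
    tissue label itself — equals ``fibroblast_source_label``. Idempotent;
    total sample count is conserved.
    """
    out = annot.copy()
    source = cfg.fibroblast_source_label
    if cfg.fibroblast_attribute is not None:
        if cfg.fibroblast_attribute not in out.columns:
            raise FormatError(f"annotation lacks column {cfg.fibroblast_attribute!r}")
        mask = out[cfg.fibroblast_attribute].astype(str) == source
    else:
        mask = out["tissue"].astype(str) == source
        for col in out.columns:
            if col != "tissue":
                mask |= out[col].astype(str) == source
    if mask.any():
        logger.info(
            "re-categorized %d samples as %r", int(mask.sum()), cfg.fibroblast_target_label
        )
        out.loc[mask, "tissue"] = cfg.fibroblast_target_label
    return out


# ---------------------------------------------------------------------------
# gene symbol selection
# ---------------------------------------------------------------------------

@dataclass
class GeneSymbolRule:
    """Prefix/suffix rule for selecting a gene family by symbol.

    The default drops HGNC-style pseudogenes: keep symbols starting with
    ``OR`` whose last character is not ``P``/``p`` (case-insensitive suffix
    match, so e.g. OR5P2 is kept — the 'P' is not terminal — while OR2A7P is
    dropped).
    """

    required_prefix: str = "OR"
    forbidden_suffix: str = "P"
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if not self.required_prefix:
            raise ValidationError("required_prefix must be non-empty")

    def matches(self, symbol: str) -> bool:
        sym = symbol if self.case_sensitive else symbol.upper()
        prefix = self.required_prefix if self.case_sensitive else self.required_prefix.upper()
        suffix = self.forbidden_suffix if self.case_sensitive else self.forbidden_suffix.upper()
        if not sym.startswith(prefix):
            return False
        if suffix and sym.endswith(suffix):
            return False
        return True

    def as_regex(self) -> re.Pattern:
        flags = 0 if self.case_sensitive else re.IGNORECASE
        pattern = f"^{re.escape(self.required_prefix)}.*(?<!{re.escape(self.forbidden_suffix)})$"
        if not self.forbidden_suffix:
            pattern = f"^{re.escape(self.required_prefix)}"
        return re.compile(pattern, flags)


def select_genes_by_rule(
    gene_ids: Sequence[str],
    rule: GeneSymbolRule,
    allow_lists: Iterable[Sequence[str]] | None = None,
) -> list[str]:
    """Apply a symbol rule to (optionally) the union of explicit gene lists.

    Input order is preserved; the result is the intersection of the rule
    matches with the union of ``allow_lists`` when given.
    """
    if allow_lists is not None:
        allowed: set[str] = set()
        for lst in allow_lists:
            allowed.update(lst)
        pool = [g for g in gene_ids if g in allowed]
    else:
        pool = list(gene_ids)
    return [g for g in pool if rule.matches(g)]


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line, blank lines skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered term -> gene list mapping.

    Term descriptions go to the mapping's ``.attrs``-like side channel: they
    are returned via :func:`read_gmt_descriptions` when needed. Terms with no
    genes are dropped with a warning; duplicate term IDs are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs term and description")
            term = parts[0]
            if term in sets:
                raise ValidationError(f"{path}: duplicate term ID {term!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                logger.warning("%s:%d: term %r has no genes, dropped", path, lineno, term)
                continue
            sets[term] = genes
    return sets


def read_gmt_descriptions(path: str | Path) -> dict[str, str]:
    """Return the term -> description column of a GMT file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                out[parts[0]] = parts[1]
    return out


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term, genes in sets.items():
            desc = descriptions.get(term, term)
            fh.write("\t".join([term, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# generic table output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV with the package-wide float precision."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
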