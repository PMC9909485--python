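"""Hypergeometric over-representation analysis with BH FDR control.

For a query gene set of size n drawn from a universe of size N, a term
annotating K universe genes and overlapping the query in k genes, the
enrichment p-value is the upper tail P[X >= k] of
Hypergeometric(N, K, n) — the observed overlap included, the standard ORA
convention. q-values are Benjamini-Hochberg adjusted over all tested
terms. A term is reported when q <= q_max (default 0.05) and the overlap
count k is at least min_overlap (default 10); both boundaries inclusive.

The universe defaults to the full set of genes that entered the network
analysis (the tested background); restricting it to annotated genes only
is a config switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentConfig", "bh_adjust", "hypergeom_enrich", "filter_report"]


@dataclass
class EnrichmentConfig:
    """Reporting thresholds and universe policy."""

    q_max: float = 0.05
    min_overlap: int = 10
    universe: str = "all-filtered-genes"  # or "annotated-genes"

    def __post_init__(self) -> None:
        if not 0 < self.q_max <= 1:
            raise ValidationError("q_max must lie in (0, 1]")
        if self.min_overlap < 1:
            raise ValidationError("min_overlap must be >= 1")
        if self.universe not in ("all-filtered-genes", "annotated-genes"):
            raise ValidationError(f"unknown universe policy {self.universe!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    query: Sequence[str],
    annotation: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    cfg: EnrichmentConfig | None = None,
    descriptions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Test every term for over-representation in the query set.

    Returns one row per tested term with columns term, description, k, n,
    K, N, p_value, q_value, passes; sorted by (q_value, p_value, term).
    Terms with no universe genes are skipped; query genes outside the
    universe are dropped with a warning.
    """
    cfg = cfg or EnrichmentConfig()
    if not annotation:
        raise ValidationError("annotation is empty")
    universe_set = set(universe)
    if cfg.universe == "annotated-genes":
        annotated = set().union(*[set(g) for g in annotation.values()])
        universe_set &= annotated
    query_set = set(query)
    if not query_set:
        raise ValidationError("query gene set is empty")
    outside = query_set - universe_set
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        query_set -= outside
    if not query_set:
        raise ValidationError("no query gene lies in the universe")
    n_universe = len(universe_set)
    n_query = len(query_set)
    descriptions = descriptions or {}

    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & universe_set
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(term_genes & query_set)
        # upper tail including the observed overlap: P[X >= k] = sf(k - 1)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append((term, descriptions.get(term, term), k, n_query, big_k, n_universe, p))
    if not rows:
        raise ValidationError("no term has genes in the universe")
    table = pd.DataFrame(
        rows, columns=["term", "description", "k", "n", "K", "N", "p_value"]
    )
    table["q_value"] = bh_adjust(table["p_value"])
    table["passes"] = (table["q_value"] <= cfg.q_max) & (table["k"] >= cfg.min_overlap)
    return table.sort_values(["q_value", "p_value", "term"]).reset_index(drop=True)


def filter_report(records: pd.DataFrame, cfg: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Keep records with q <= q_max and overlap >= min_overlap (inclusive)."""
    cfg = cfg or EnrichmentConfig()
    keep = (records["q_value"] <= cfg.q_max) & (records["k"] >= cfg.min_overlap)
    return records.loc[keep].reset_index(drop=True)
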