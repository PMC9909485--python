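"""Weighted co-expression network core: signed adjacency, topological
overlap, module detection, eigengenes and edge export.

The workflow mirrors the standard weighted gene correlation network
analysis recipe:

1. log10(TPM + 1e-4) transform after a detection filter (gene must be
   detected, TPM > 0, in a minimum number of samples);
2. soft-threshold power selected as the smallest candidate whose signed
   adjacency yields an approximately scale-free connectivity distribution
   (sign-corrected R^2 of log10 p(k) vs log10 k over log-spaced bins);
3. signed adjacency ``a_ij = ((1 + cor_ij) / 2) ** beta`` (negative
   correlation maps toward 0);
4. unsigned topological overlap similarity
   ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``;
5. average-linkage hierarchical clustering of ``1 - TOM`` with a static cut
   at a fixed fraction (default 0.75) of the tallest merge; clusters below
   ``min_module_size`` are left "unassigned";
6. modules summarized by eigengenes (first principal component of the
   standardized module submatrix, oriented along the module mean profile)
   and merged while eigengene dissimilarity ``1 - cor`` falls below the
   merge height;
7. edges with TOM above a cutoff (default 0.025) exported for external
   viewers (SIF / weighted TSV).

Module labels are color names in decreasing module-size order, following
the field's convention so that references like "the black module" carry
over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import EmptyResultError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MODULE_COLORS",
    "UNASSIGNED",
    "PreprocessConfig",
    "NetworkConfig",
    "ModulePartition",
    "preprocess",
    "pearson_correlation",
    "adjacency_from_correlation",
    "adjacency_signed",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "export_edges",
    "write_sif",
    "tissue_fold_profile",
    "CoexpressionNetwork",
]

#: label for genes not assigned to any module (grey-equivalent)
UNASSIGNED = "unassigned"

#: module color names, assigned in decreasing module-size order
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


@dataclass
class PreprocessConfig:
    """Detection filter and log transform ahead of network construction.

    ``min_detected_samples`` may be an absolute count (int) or a fraction of
    the selected samples (float in (0, 1)). Detection means TPM > 0.
    """

    pseudocount: float = 1e-4
    min_detected_samples: int | float = 650

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")

    def threshold(self, n_samples: int) -> int:
        m = self.min_detected_samples
        if isinstance(m, float) and 0 < m < 1:
            return int(np.ceil(m * n_samples))
        return int(m)


@dataclass
class NetworkConfig:
    """Knobs of adjacency, soft-threshold fit, clustering and export."""

    candidate_powers: Sequence[int] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.8
    n_connectivity_bins: int = 10
    tom_edge_cutoff: float = 0.025
    min_module_size: int = 30
    merge_height: float = 0.25
    cut_height_fraction: float = 0.75
    soft_power: int | None = None  # overrides pick_soft_threshold when set

    def __post_init__(self) -> None:
        if not 0 <= self.tom_edge_cutoff < 1:
            raise ValidationError("tom_edge_cutoff must lie in [0, 1)")
        if not 0 <= self.merge_height <= 1:
            raise ValidationError("merge_height must lie in [0, 1]")


@dataclass
class ModulePartition:
    """Gene -> module assignment plus merge provenance."""

    labels: pd.Series  # index: gene IDs, values: module label strings
    merge_history: list[dict] = field(default_factory=list)

    def modules(self) -> list[str]:
        """Module labels (unassigned excluded), largest first."""
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return list(counts.index)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    expr: pd.DataFrame,
    cfg: PreprocessConfig | None = None,
    annot: pd.DataFrame | None = None,
    tissue_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Detection-filter and log10-transform a genes x samples TPM matrix."""
    cfg = cfg or PreprocessConfig()
    if tissue_subset is not None:
        if annot is None:
            raise ValidationError("tissue_subset requires an annotation")
        keep = annot.index[annot["tissue"].isin(tissue_subset)]
        keep = [s for s in expr.columns if s in set(keep)]
        if not keep:
            raise EmptyResultError("tissue subset selects no samples")
        expr = expr[keep]
    threshold = cfg.threshold(expr.shape[1])
    detected = (expr.to_numpy() > 0).sum(axis=1)
    mask = detected >= threshold
    if not mask.any():
        raise EmptyResultError(
            f"no gene is detected in >= {threshold} of {expr.shape[1]} samples"
        )
    dropped = int((~mask).sum())
    if dropped:
        logger.info("detection filter removed %d of %d genes", dropped, expr.shape[0])
    return np.log10(expr.loc[mask] + cfg.pseudocount)


# ---------------------------------------------------------------------------
# adjacency and soft threshold
# ---------------------------------------------------------------------------

def pearson_correlation(logexpr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation; zero-variance genes get correlation 0."""
    x = np.asarray(logexpr, dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance genes: correlations set to 0", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def adjacency_from_correlation(cor: np.ndarray, beta: int) -> np.ndarray:
    """Signed adjacency ``((1 + cor) / 2) ** beta`` from a correlation matrix."""
    if beta < 1:
        raise ValidationError("soft power beta must be >= 1")
    adj = ((1.0 + np.asarray(cor, dtype=float)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def adjacency_signed(logexpr: pd.DataFrame | np.ndarray, beta: int) -> np.ndarray:
    """Signed adjacency of a genes x samples log-expression matrix."""
    return adjacency_from_correlation(pearson_correlation(logexpr), beta)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Sign-corrected R^2 and slope of log10 p(k) vs log10 k.

    Connectivities are histogrammed into ``n_bins`` log-spaced bins
    (equal width in log10 k between the smallest positive and the largest
    connectivity); empty bins are dropped before the regression.
    """
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        raise ValidationError("degenerate connectivity: all values equal")
    positive = k[k > 0]
    if positive.size < 3:
        raise ValidationError("too few positive connectivities for the scale-free fit")
    lo, hi = positive.min(), positive.max()
    if np.isclose(lo, hi):
        raise ValidationError("degenerate connectivity: all values equal")
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    dk, pk = [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        dk.append(mean_k)
        pk.append(sel.sum() / k.size)
    if len(dk) < 3:
        raise ValidationError("too few usable connectivity bins for the scale-free fit")
    lx, ly = np.log10(dk), np.log10(pk)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    if slope > 0:
        r2 = -r2
    return float(r2), float(slope)


def pick_soft_threshold(
    logexpr: pd.DataFrame,
    cfg: NetworkConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power: smallest candidate reaching the R^2 target.

    Returns (beta, fit table). When no candidate reaches the target the
    argmax-R^2 power is returned and the table's ``reached_target`` column
    is all-False (a warning is logged).
    """
    cfg = cfg or NetworkConfig()
    powers = list(cfg.candidate_powers)
    if len(powers) < 3:
        raise ValidationError("need at least 3 candidate powers")
    if logexpr.shape[0] < 20:
        raise ValidationError("soft-threshold fit needs at least 20 genes")
    cor = pearson_correlation(logexpr)
    base = (1.0 + cor) / 2.0
    rows = []
    for power in powers:
        adj = base ** power
        np.fill_diagonal(adj, 1.0)
        k = adj.sum(axis=0) - 1.0
        r2, slope = scale_free_fit(k, cfg.n_connectivity_bins)
        rows.append({"power": power, "r_squared": r2, "slope": slope,
                     "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    table["reached_target"] = table["r_squared"] >= cfg.scale_free_r2_target
    hits = table.index[table["reached_target"]]
    if len(hits):
        beta = int(table.loc[hits[0], "power"])
    else:
        beta = int(table.loc[table["r_squared"].idxmax(), "power"])
        logger.warning(
            "no power reaches scale-free R^2 >= %.2f; using argmax power %d "
            "(max R^2 = %.3f)", cfg.scale_free_r2_target, beta,
            table["r_squared"].max(),
        )
    return beta, table


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap of a signed adjacency matrix.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``k_i = sum_{u != i} a_iu``; the diagonal is 1 by convention.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValidationError("adjacency values must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValidationError("adjacency must have unit diagonal")
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    shared = a @ a - 2.0 * a  # (i,j) entry: sum over u != i,j of a_iu a_uj
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return (tom + tom.T) / 2.0


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _color_labels(raw: np.ndarray, gene_ids: Sequence[str], min_size: int) -> pd.Series:
    """Map raw cluster numbers to color names, largest module first.

    Ties in size break toward the cluster containing the earliest input
    gene, making the labeling deterministic and order-reproducible.
    """
    series = pd.Series(raw, index=list(gene_ids))
    sizes = series.value_counts()
    order = sorted(
        sizes.index,
        key=lambda c: (-sizes[c], int(np.argmax(series.to_numpy() == c))),
    )
    mapping = {}
    next_color = 0
    for cluster in order:
        if sizes[cluster] < min_size:
            mapping[cluster] = UNASSIGNED
        else:
            if next_color < len(MODULE_COLORS):
                mapping[cluster] = MODULE_COLORS[next_color]
            else:
                mapping[cluster] = f"module_{next_color + 1}"
            next_color += 1
    return series.map(mapping)


def detect_modules(
    tom: np.ndarray,
    gene_ids: Sequence[str],
    cfg: NetworkConfig | None = None,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The tree is cut at ``cut_height_fraction`` (default 0.75) of the tallest
    merge; clusters smaller than ``min_module_size`` become "unassigned".
    The fraction sits between the bottom-of-tree heights where coherent
    modules assemble and the top-of-tree region where unrelated genes
    accrete, so unstructured input yields no module at all.
    """
    cfg = cfg or NetworkConfig()
    n = len(gene_ids)
    if n < cfg.min_module_size:
        logger.warning("fewer genes (%d) than min_module_size (%d): all unassigned",
                       n, cfg.min_module_size)
        return ModulePartition(pd.Series(UNASSIGNED, index=list(gene_ids)))
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    cut = cfg.cut_height_fraction * z[:, 2].max()
    raw = fcluster(z, t=cut, criterion="distance")
    labels = _color_labels(raw, gene_ids, cfg.min_module_size)
    return ModulePartition(labels=labels)


# ---------------------------------------------------------------------------
# eigengenes and merging
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengene(
    logexpr: pd.DataFrame,
    partition: ModulePartition,
) -> pd.DataFrame:
    """First principal component per module (modules x samples, unit norm).

    Each module's gene x sample submatrix is standardized per gene; the
    eigengene is the leading right singular vector, sign-oriented to
    correlate positively with the module's mean standardized profile. A
    single-gene module's eigengene is that gene's standardized profile
    scaled to unit norm.
    """
    rows = {}
    for module in partition.modules():
        members = partition.members(module)
        sub = _standardize_rows(logexpr.loc[members].to_numpy(dtype=float))
        if sub.shape[0] == 1:
            vec = sub[0]
            norm = np.linalg.norm(vec)
            rows[module] = vec / norm if norm > 0 else vec
            continue
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        eig = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        rows[module] = eig
    return pd.DataFrame(rows, index=logexpr.columns).T


def merge_modules(
    logexpr: pd.DataFrame,
    partition: ModulePartition,
    merge_height: float = 0.25,
) -> tuple[ModulePartition, pd.DataFrame]:
    """Iteratively merge modules with eigengene dissimilarity < merge_height.

    Each pass clusters the current eigengenes (average linkage on 1 - cor),
    merges groups falling below the height, recomputes eigengenes, and
    repeats to a fixed point. Returns the merged partition (labels refreshed
    to size order) and its eigengenes. ``merge_height = 0`` is the identity.
    """
    labels = partition.labels.copy()
    history = list(partition.merge_history)
    while True:
        current = ModulePartition(labels, history)
        eig = module_eigengene(logexpr, current)
        mods = list(eig.index)
        if len(mods) < 2 or merge_height <= 0:
            break
        cor = np.corrcoef(eig.to_numpy())
        dissim = 1.0 - np.clip(cor, -1.0, 1.0)
        np.fill_diagonal(dissim, 0.0)
        z = linkage(squareform(dissim, checks=False), method="average")
        groups = fcluster(z, t=merge_height, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        for gid in sorted(set(groups)):
            members = [mods[i] for i in range(len(mods)) if groups[i] == gid]
            if len(members) < 2:
                continue
            sizes = labels.value_counts()
            target = max(members, key=lambda m: (sizes.get(m, 0), m))
            history.append({"merged": sorted(members), "into": target})
            labels[labels.isin(members)] = target
    # refresh color names in size order after merging
    final = ModulePartition(labels, history)
    named = labels.copy()
    for rank, module in enumerate(final.modules()):
        new = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        named[labels == module] = new
    final = ModulePartition(named, history)
    eig = module_eigengene(logexpr, final)
    return final, eig


# ---------------------------------------------------------------------------
# edge export and per-tissue fold profile
# ---------------------------------------------------------------------------

def export_edges(
    tom: np.ndarray,
    gene_ids: Sequence[str],
    cutoff: float = 0.025,
) -> pd.DataFrame:
    """Undirected edge list (gene1, gene2, tom) with TOM strictly above cutoff.

    Nodes without any retained edge simply never appear in the list.
    """
    if not 0 <= cutoff < 1:
        raise ValidationError("cutoff must lie in [0, 1)")
    tom = np.asarray(tom, dtype=float)
    iu, ju = np.triu_indices(tom.shape[0], k=1)
    keep = tom[iu, ju] > cutoff
    genes = np.asarray(list(gene_ids), dtype=object)
    return pd.DataFrame({
        "gene1": genes[iu[keep]],
        "gene2": genes[ju[keep]],
        "tom": tom[iu[keep], ju[keep]],
    })


def write_sif(edges: pd.DataFrame, path: str | Path, relation: str = "tom") -> None:
    """Write an edge list in simple-interaction format for network viewers."""
    with open(path, "w") as fh:
        for g1, g2 in zip(edges.iloc[:, 0], edges.iloc[:, 1]):
            fh.write(f"{g1}\t{relation}\t{g2}\n")


def tissue_fold_profile(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    genes: Sequence[str] | None = None,
    pseudocount: float = 1e-4,
) -> pd.DataFrame:
    """Genes x tissues log2 fold of per-tissue mean over the cross-tissue mean.

    Per gene: mean TPM within each tissue; reference = mean of the
    per-tissue means; value = log2((tissue mean + pc) / (reference + pc)).
    """
    if genes is not None:
        expr = expr.loc[list(genes)]
    tissues = annot.loc[expr.columns, "tissue"]
    if tissues.nunique() < 2:
        raise ValidationError("fold profile needs at least two tissues")
    means = expr.T.groupby(tissues.values).mean().T  # genes x tissues
    reference = means.mean(axis=1)
    return np.log2(means.add(pseudocount).div(reference + pseudocount, axis=0))


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class CoexpressionNetwork(ClusterMixin, BaseEstimator):
    """Signed co-expression network and module clustering, sklearn-style.

    ``fit(X)`` expects log-scale expression with samples as rows and genes
    as columns (a DataFrame keeps gene names); use :func:`preprocess` on a
    raw TPM matrix first. The estimator picks the soft power (unless
    ``soft_power`` is set), builds signed adjacency and unsigned TOM,
    clusters, merges modules, and exposes:

    Attributes
    ----------
    power_ : int                 selected soft-threshold power
    fit_table_ : DataFrame       per-power scale-free fit diagnostics
    tom_ : ndarray               topological overlap matrix (rows/columns in
                                 ``tom_gene_order_``, the lexicographic gene
                                 order used internally for bit-reproducibility)
    partition_ : ModulePartition merged gene -> module assignment
    labels_ : ndarray            module label per input gene (column order)
    eigengenes_ : DataFrame      modules x samples eigengene matrix
    merge_history_ : list        record of module merges
    """

    def __init__(
        self,
        soft_power: int | None = None,
        candidate_powers: Sequence[int] = tuple(range(1, 21)),
        scale_free_r2_target: float = 0.8,
        tom_edge_cutoff: float = 0.025,
        min_module_size: int = 30,
        merge_height: float = 0.25,
        cut_height_fraction: float = 0.75,
    ):
        self.soft_power = soft_power
        self.candidate_powers = candidate_powers
        self.scale_free_r2_target = scale_free_r2_target
        self.tom_edge_cutoff = tom_edge_cutoff
        self.min_module_size = min_module_size
        self.merge_height = merge_height
        self.cut_height_fraction = cut_height_fraction

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            candidate_powers=self.candidate_powers,
            scale_free_r2_target=self.scale_free_r2_target,
            tom_edge_cutoff=self.tom_edge_cutoff,
            min_module_size=self.min_module_size,
            merge_height=self.merge_height,
            cut_height_fraction=self.cut_height_fraction,
            soft_power=self.soft_power,
        )

    def fit(self, X, y=None):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            genes = list(X.columns)
            logexpr = X.T
        else:
            arr = np.asarray(X, dtype=float)
            genes = [f"x{i}" for i in range(arr.shape[1])]
            logexpr = pd.DataFrame(arr.T, index=genes)
        # canonical gene order: makes the fit bit-reproducible under input
        # permutations (ties in clustering would otherwise flip on fp noise)
        canonical = sorted(genes)
        logexpr = logexpr.loc[canonical]
        if cfg.soft_power is not None:
            self.power_ = int(cfg.soft_power)
            self.fit_table_ = None
        else:
            self.power_, self.fit_table_ = pick_soft_threshold(logexpr, cfg)
        adj = adjacency_signed(logexpr, self.power_)
        self.tom_ = tom_similarity(adj)
        self.tom_gene_order_ = canonical
        partition = detect_modules(self.tom_, canonical, cfg)
        if partition.modules():
            partition, eig = merge_modules(logexpr, partition, cfg.merge_height)
        else:
            eig = pd.DataFrame(index=pd.Index([], dtype=object), columns=logexpr.columns)
        self.partition_ = partition
        self.labels_ = partition.labels.loc[genes].to_numpy()
        self.eigengenes_ = eig
        self.merge_history_ = partition.merge_history
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.n_features_in_ = len(genes)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def edges(self, cutoff: float | None = None) -> pd.DataFrame:
        """Thresholded TOM edge list of the fitted network."""
        cutoff = self.tom_edge_cutoff if cutoff is None else cutoff
        return export_edges(self.tom_, self.tom_gene_order_, cutoff)
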