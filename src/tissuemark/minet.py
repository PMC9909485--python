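"""Conservative maximum-MI network inference (c3net-style) for one module.

The algorithm keeps, for every gene, at most one edge: the link to its
highest-mutual-information partner, provided that MI survives a
permutation-based significance cut. The union of these per-gene picks is an
undirected network whose connected components segment a co-expression
module into sub-networks.

Two MI estimators are provided (the choice matters little for monotone
dependence):

* ``gaussian_rank`` (default): ranks are mapped to normal scores and
  ``MI = -0.5 * ln(1 - rho^2)`` with ``rho`` their Pearson correlation —
  the exact MI of a bivariate Gaussian, robust and invariant under strictly
  monotone transforms of either input. For |rho| -> 1 the estimate is
  capped by clipping ``rho^2`` at ``1 - 1e-12`` (~13.8 nats).
* ``binned``: plug-in MI over an equal-frequency 2-D histogram with
  Miller-Madow bias correction, floored at 0; bin count defaults to
  ceil(sqrt(n / 5)) per axis so each joint cell keeps ~5 expected counts.

The significance threshold pools MI values computed against permuted gene
vectors and takes their (1 - alpha) quantile; everything is deterministic
given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MIEstimatorConfig",
    "MINetwork",
    "mutual_information",
    "mi_matrix",
    "mi_cutoff",
    "c3net",
    "subnetwork_of",
    "C3Net",
]

#: cap applied to the gaussian_rank estimate for perfectly dependent inputs
RHO_SQ_CEILING = 1.0 - 1e-12


@dataclass
class MIEstimatorConfig:
    """Estimator and significance settings for the MI network."""

    estimator: str = "gaussian_rank"
    bins: int | None = None  # binned only; default ceil(sqrt(n / 5))
    n_permutations: int = 100
    alpha: float = 0.01
    max_null_pairs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.estimator not in ("gaussian_rank", "binned"):
            raise ValidationError(f"unknown MI estimator {self.estimator!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_permutations < 20:
            raise ValidationError("need at least 20 permutations")


@dataclass
class MINetwork:
    """Result container: per-gene max-MI edges and connected components."""

    edges: pd.DataFrame           # columns gene1, gene2, mi (gene1 < gene2)
    components: pd.Series         # gene -> integer component id
    threshold: float

    def component_sizes(self) -> pd.Series:
        """Component sizes, largest first (ties by component id)."""
        return self.components.value_counts().sort_values(ascending=False)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x)
    return stats.norm.ppf(ranks / (len(x) + 1.0))


def _mi_gaussian_rank(x: np.ndarray, y: np.ndarray) -> float:
    rho = np.corrcoef(_normal_scores(x), _normal_scores(y))[0, 1]
    rho_sq = min(float(rho) ** 2, RHO_SQ_CEILING)
    return -0.5 * math.log1p(-rho_sq)


def _mi_binned(x: np.ndarray, y: np.ndarray, bins: int | None) -> float:
    n = len(x)
    # default keeps >= ~5 expected counts per joint cell, where the
    # Miller-Madow correction is effective; sqrt(n) bins per axis would
    # leave the 2-D histogram too sparse and the estimate badly biased
    b = bins or max(2, int(math.ceil(math.sqrt(n / 5.0))))
    # equal-frequency bin assignment via rank quantiles
    qx = np.searchsorted(np.quantile(x, np.linspace(0, 1, b + 1))[1:-1], x, side="right")
    qy = np.searchsorted(np.quantile(y, np.linspace(0, 1, b + 1))[1:-1], y, side="right")
    joint = np.zeros((b, b))
    np.add.at(joint, (qx, qy), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())
    # Miller-Madow: MI_mm = MI + (Kx + Ky - Kxy - 1) / (2n), K = occupied cells
    kx, ky, kxy = int((px > 0).sum()), int((py > 0).sum()), int(nz.sum())
    mi += (kx + ky - kxy - 1) / (2.0 * n)
    return max(mi, 0.0)


def mutual_information(x, y, cfg: MIEstimatorConfig | None = None) -> float:
    """Pairwise mutual information in nats (see module docstring)."""
    cfg = cfg or MIEstimatorConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length vectors")
    if len(x) < 10:
        raise ValidationError("MI estimation needs at least 10 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input vector: MI set to 0")
        return 0.0
    if cfg.estimator == "gaussian_rank":
        return _mi_gaussian_rank(x, y)
    return _mi_binned(x, y, cfg.bins)


def mi_matrix(logexpr: pd.DataFrame, cfg: MIEstimatorConfig | None = None) -> pd.DataFrame:
    """Symmetric genes x genes MI matrix (diagonal 0 by convention)."""
    cfg = cfg or MIEstimatorConfig()
    if logexpr.shape[0] < 3:
        raise ValidationError("MI matrix needs at least 3 genes")
    x = logexpr.to_numpy(dtype=float)
    genes = list(logexpr.index)
    n_genes = len(genes)
    if cfg.estimator == "gaussian_rank":
        flat = np.array([np.ptp(row) == 0 for row in x])
        if flat.any():
            logger.warning("%d constant genes: MI rows set to 0", int(flat.sum()))
        scores = np.vstack([
            _normal_scores(row) if not f else np.zeros(x.shape[1])
            for row, f in zip(x, flat)
        ])
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(scores)
        rho = np.nan_to_num(rho, nan=0.0)
        rho_sq = np.minimum(rho ** 2, RHO_SQ_CEILING)
        mi = -0.5 * np.log1p(-rho_sq)
        mi[flat, :] = 0.0
        mi[:, flat] = 0.0
    else:
        mi = np.zeros((n_genes, n_genes))
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                mi[i, j] = mi[j, i] = mutual_information(x[i], x[j], cfg)
    np.fill_diagonal(mi, 0.0)
    return pd.DataFrame(mi, index=genes, columns=genes)


def mi_cutoff(logexpr: pd.DataFrame, cfg: MIEstimatorConfig | None = None) -> float:
    """Permutation-null MI threshold: pooled (1 - alpha) quantile.

    Each permutation shuffles one gene's sample vector and scores it against
    a set of partner genes; the pooled null MI values (capped at
    ``max_null_pairs``) yield the quantile. Deterministic given the seed.
    """
    cfg = cfg or MIEstimatorConfig()
    rng = np.random.default_rng(cfg.seed)
    x = logexpr.to_numpy(dtype=float)
    n_genes = x.shape[0]
    if n_genes < 2:
        raise ValidationError("cutoff estimation needs at least 2 genes")
    per_perm = max(1, min(n_genes - 1, cfg.max_null_pairs // cfg.n_permutations))
    null: list[float] = []
    for _ in range(cfg.n_permutations):
        g = int(rng.integers(n_genes))
        shuffled = rng.permutation(x[g])
        partners = rng.choice(
            [j for j in range(n_genes) if j != g],
            size=per_perm, replace=False,
        )
        for j in partners:
            null.append(mutual_information(shuffled, x[j], cfg))
    return float(np.quantile(null, 1.0 - cfg.alpha))


def c3net(mi: pd.DataFrame, threshold: float) -> MINetwork:
    """Keep each gene's maximal-MI neighbor above the threshold.

    Sub-threshold MI is zeroed; every gene then contributes the single edge
    to its argmax-MI partner (ties resolved toward the lexicographically
    smallest gene ID); the deduplicated union is the network. Components
    come from union-find on the resulting undirected graph.
    """
    m = mi.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
        raise ValidationError("MI matrix must be square and symmetric")
    genes = list(mi.index)
    picked: set[tuple[int, int]] = set()
    for i in range(len(genes)):
        row = m[i].copy()
        row[i] = -np.inf
        best = row.max()
        if best <= threshold:
            continue
        candidates = np.flatnonzero(row == best)
        j = min(candidates, key=lambda c: genes[c])
        picked.add((i, j) if genes[i] < genes[j] else (j, i))
    rows = sorted(
        ((genes[i], genes[j], m[i, j]) for i, j in picked),
        key=lambda r: (r[0], r[1]),
    )
    edges = pd.DataFrame(rows, columns=["gene1", "gene2", "mi"])
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from(zip(edges["gene1"], edges["gene2"]))
    comp_id = {}
    # deterministic component numbering: by decreasing size, then first member
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    for k, comp in enumerate(comps):
        for g in comp:
            comp_id[g] = k
    components = pd.Series({g: comp_id[g] for g in genes}, name="component")
    components.index.name = "gene"
    return MINetwork(edges=edges, components=components, threshold=float(threshold))


def subnetwork_of(network: MINetwork, gene: str) -> dict:
    """Report the component containing ``gene`` and its size rank.

    Returns a dict with the component id, member genes, size, 1-based size
    rank, and whether the component is (co-)largest.
    """
    if gene not in network.components.index:
        raise ValidationError(f"gene {gene!r} not in network")
    cid = int(network.components[gene])
    members = list(network.components.index[network.components == cid])
    sizes = network.component_sizes()
    size = len(members)
    rank = int((sizes > size).sum()) + 1
    return {
        "component": cid,
        "members": members,
        "size": size,
        "rank": rank,
        "is_largest": size == int(sizes.max()),
    }


class C3Net(BaseEstimator):
    """Maximum-MI network inference as a scikit-learn style estimator.

    ``fit(X)`` expects log-scale expression with samples as rows and genes
    as columns (the same log10(TPM + 1e-4) matrix used for co-expression
    modules, restricted to one module's genes).

    Parameters mirror :class:`MIEstimatorConfig`; ``threshold`` overrides
    the permutation cutoff when set.

    Attributes
    ----------
    mi_matrix_ : DataFrame     symmetric pairwise MI
    threshold_ : float         significance cutoff actually applied
    network_ : MINetwork       edges + components container
    edges_ : DataFrame         (gene1, gene2, mi) rows
    labels_ : ndarray          component id per input gene (column order)
    """

    def __init__(
        self,
        estimator: str = "gaussian_rank",
        bins: int | None = None,
        n_permutations: int = 100,
        alpha: float = 0.01,
        threshold: float | None = None,
        random_state: int = 0,
    ):
        self.estimator = estimator
        self.bins = bins
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.threshold = threshold
        self.random_state = random_state

    def _config(self) -> MIEstimatorConfig:
        return MIEstimatorConfig(
            estimator=self.estimator,
            bins=self.bins,
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            logexpr = X.T
        else:
            arr = np.asarray(X, dtype=float)
            logexpr = pd.DataFrame(arr.T, index=[f"x{i}" for i in range(arr.shape[1])])
        self.mi_matrix_ = mi_matrix(logexpr, cfg)
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
        else:
            self.threshold_ = mi_cutoff(logexpr, cfg)
        self.network_ = c3net(self.mi_matrix_, self.threshold_)
        self.edges_ = self.network_.edges
        genes = list(logexpr.index)
        self.labels_ = self.network_.components.loc[genes].to_numpy()
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.n_features_in_ = len(genes)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
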