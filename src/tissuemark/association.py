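"""Composite tissue-association screen: Wilcoxon + fold change + LDA ROC-AUC.

A gene is called "highly expressed" in a tissue when, comparing that
tissue's samples against all remaining samples (one-vs-rest):

* the two-sided Wilcoxon rank-sum p-value is below ``p_max`` (default 1e-10),
* the fold change of group means (with a small pseudocount on both sides)
  is at least ``fc_min`` (default 25), and
* the ROC-AUC of a one-feature linear-discriminant score, target tissue as
  the positive class, is at least ``auc_min`` (default 0.85).

Fold change uses group *means* with pseudocount 1e-4 on numerator and
denominator: sparsely expressed receptor genes have median 0 in most
tissues, which would make a median-based ratio degenerate. The LDA AUC is
computed by resubstitution; for a single feature the discriminant score is a
monotone (affine) transform of the expression value, so the AUC equals the
rank-based Mann-Whitney AUC or its complement depending on the sign of the
fitted discriminant direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CriteriaConfig",
    "wilcoxon_one_vs_rest",
    "fold_change",
    "lda_auc",
    "tissue_zscore",
    "TissueAssociation",
    "call_associations",
]


@dataclass
class CriteriaConfig:
    """Thresholds of the composite criterion."""

    p_max: float = 1e-10
    fc_min: float = 25.0
    auc_min: float = 0.85
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValidationError("p_max must lie in (0, 1)")
        if self.fc_min <= 0:
            raise ValidationError("fc_min must be positive")
        if not 0.5 <= self.auc_min <= 1:
            raise ValidationError("auc_min must lie in [0.5, 1]")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")


def _split(values: np.ndarray, labels: np.ndarray, target: str) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask = labels == target
    x, y = values[mask], values[~mask]
    if x.size == 0 or y.size == 0:
        raise ValidationError(f"one-vs-rest split for {target!r} leaves an empty group")
    return x, y


def wilcoxon_one_vs_rest(values, labels, target: str) -> float:
    """Two-sided Wilcoxon rank-sum p for target tissue vs pooled rest.

    Exact enumeration when both groups have <= 12 samples and the pooled
    values are untied; otherwise the normal approximation with tie and
    continuity corrections. Identical constant samples give p = 1.
    """
    x, y = _split(values, labels, target)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    untied = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 12 and y.size <= 12 and untied) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def fold_change(values, labels, target: str, pseudocount: float = 1e-4) -> float:
    """(mean target + pseudocount) / (mean rest + pseudocount)."""
    x, y = _split(values, labels, target)
    return float((x.mean() + pseudocount) / (y.mean() + pseudocount))


def lda_auc(values, labels, target: str) -> float:
    """Resubstitution ROC-AUC of a one-feature linear discriminant score.

    The discriminant direction is the pooled-within-class-variance
    coefficient ``(mean_target - mean_rest) / s2_pooled``; a monotone
    transform of the feature, so the AUC is computed by the rank
    (Mann-Whitney) method and flipped when the direction is negative.
    Degenerate inputs: zero pooled variance reduces the score to the class
    constants (AUC 1, 0, or 0.5 on equality); equal class means give a
    constant score and AUC 0.5.
    """
    x, y = _split(values, labels, target)
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))  # mid-ranks for ties
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc_rank = u1 / (n1 * n2)

    diff = x.mean() - y.mean()
    # pooled within-class variance (denominator of the LDA coefficient)
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    dof = n1 + n2 - 2
    s2 = ss / dof if dof > 0 else 0.0
    if s2 == 0.0:
        if diff > 0:
            return 1.0
        if diff < 0:
            return 0.0
        return 0.5
    if diff == 0.0:
        return 0.5
    return float(auc_rank if diff > 0 else 1.0 - auc_rank)


def tissue_zscore(
    expr: pd.DataFrame, annot: pd.DataFrame, genes: list[str] | None = None
) -> pd.DataFrame:
    """Genes x tissues z-scores of per-tissue median expression.

    Per gene: median TPM within each tissue, then a z-score across tissues
    using the sample (n-1) standard deviation; rows constant across tissues
    map to all zeros.
    """
    if genes is not None:
        expr = expr.loc[genes]
    tissues = annot.loc[expr.columns, "tissue"]
    if tissues.nunique() < 2:
        raise ValidationError("z-scores need at least two tissues")
    medians = expr.T.groupby(tissues.values).median().T  # genes x tissues
    centered = medians.sub(medians.mean(axis=1), axis=0)
    sd = medians.std(axis=1, ddof=1)
    z = centered.div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z


class TissueAssociation(BaseEstimator):
    """Per-gene, per-tissue composite marker screen (one-vs-rest).

    A scikit-learn style estimator: ``fit(X, y)`` with ``X`` of shape
    (n_samples, n_genes) — TPM values, a DataFrame keeps gene names — and
    ``y`` the per-sample tissue labels.

    Parameters
    ----------
    p_max, fc_min, auc_min, pseudocount
        Thresholds of the composite criterion, see :class:`CriteriaConfig`.

    Attributes
    ----------
    results_ : DataFrame
        One row per (gene, tissue): p_value, fold_change, lda_auc, passes.
    marker_genes_ : list[str]
        Genes passing in at least one tissue.
    marker_tissues_ : list[str]
        Tissues with at least one passing gene.
    """

    def __init__(
        self,
        p_max: float = 1e-10,
        fc_min: float = 25.0,
        auc_min: float = 0.85,
        pseudocount: float = 1e-4,
    ):
        self.p_max = p_max
        self.fc_min = fc_min
        self.auc_min = auc_min
        self.pseudocount = pseudocount

    def _config(self) -> CriteriaConfig:
        return CriteriaConfig(self.p_max, self.fc_min, self.auc_min, self.pseudocount)

    def fit(self, X, y):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            genes = list(X.columns)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            genes = [f"x{i}" for i in range(values.shape[1])]
        if values.shape[1] == 0:
            raise ValidationError("gene subset is empty")
        labels = np.asarray(y)
        if labels.shape[0] != values.shape[0]:
            raise ValidationError("X and y have different sample counts")
        tissues = sorted(pd.unique(labels))
        records = []
        for j, gene in enumerate(genes):
            col = values[:, j]
            for tissue in tissues:
                p = wilcoxon_one_vs_rest(col, labels, tissue)
                fc = fold_change(col, labels, tissue, cfg.pseudocount)
                auc = lda_auc(col, labels, tissue)
                passes = (p < cfg.p_max) and (fc >= cfg.fc_min) and (auc >= cfg.auc_min)
                records.append((gene, tissue, p, fc, auc, passes))
        self.results_ = pd.DataFrame(
            records, columns=["gene", "tissue", "p_value", "fold_change", "lda_auc", "passes"]
        )
        passing = self.results_[self.results_["passes"]]
        self.marker_genes_ = sorted(passing["gene"].unique())
        self.marker_tissues_ = sorted(passing["tissue"].unique())
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.n_features_in_ = len(genes)
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Return the pass/fail matrix (genes x tissues) of the fitted screen."""
        check_is_fitted(self, "results_")
        return self.results_.pivot(index="gene", columns="tissue", values="passes")


def call_associations(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    genes: list[str] | None = None,
    cfg: CriteriaConfig | None = None,
) -> pd.DataFrame:
    """Run the composite screen on a genes x samples TPM matrix.

    Thin wrapper over :class:`TissueAssociation` for the genes-as-rows file
    orientation; returns the per-(gene, tissue) association table.
    """
    cfg = cfg or CriteriaConfig()
    if genes is not None:
        missing = set(genes) - set(expr.index)
        if missing:
            raise ValidationError(f"genes not in matrix: {sorted(missing)[:5]}")
        expr = expr.loc[genes]
    if expr.shape[0] == 0:
        raise ValidationError("gene subset is empty")
    labels = annot.loc[expr.columns, "tissue"].to_numpy()
    est = TissueAssociation(cfg.p_max, cfg.fc_min, cfg.auc_min, cfg.pseudocount)
    est.fit(expr.T, labels)
    return est.results_
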