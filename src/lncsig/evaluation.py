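"""Classifier evaluation: confusion metrics, ROC/AUC, clustering association.

ABC is the positive class throughout, so sensitivity is the fraction of ABC
samples predicted ABC and specificity the fraction of GCB samples predicted
GCB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from lncsig.errors import ValidationError


@dataclass(frozen=True)
class ConfusionSummary:
    """Two-class confusion counts with derived proportions."""

    n_abc: int
    n_gcb: int
    correct_abc: int
    correct_gcb: int

    @property
    def accuracy(self) -> float:
        return (self.correct_abc + self.correct_gcb) / (self.n_abc + self.n_gcb)

    @property
    def sensitivity(self) -> float:
        return self.correct_abc / self.n_abc

    @property
    def specificity(self) -> float:
        return self.correct_gcb / self.n_gcb

    def percent(self, metric: str) -> float:
        """Metric as a percentage rounded to one decimal (reporting convention)."""
        return round(100.0 * getattr(self, metric), 1)


def confusion_from_counts(correct_abc: int, n_abc: int, correct_gcb: int, n_gcb: int) -> ConfusionSummary:
    """Build a summary from per-class correct/total counts."""
    if not (0 <= correct_abc <= n_abc and 0 <= correct_gcb <= n_gcb):
        raise ValidationError("correct counts must lie within class totals")
    if n_abc == 0 or n_gcb == 0:
        raise ValidationError("both class totals must be positive")
    return ConfusionSummary(n_abc=n_abc, n_gcb=n_gcb, correct_abc=correct_abc, correct_gcb=correct_gcb)


def confusion_metrics(predicted: pd.Series, truth: pd.Series) -> ConfusionSummary:
    """Confusion summary of predicted vs true subtype labels (aligned by id)."""
    predicted, truth = pd.Series(predicted), pd.Series(truth)
    unmatched = predicted.index.symmetric_difference(truth.index)
    if len(unmatched):
        raise ValidationError(f"unmatched sample id(s): {list(unmatched[:5])}")
    predicted = predicted.reindex(truth.index)
    if not truth.isin(["ABC", "GCB"]).all():
        raise ValidationError("truth labels must be ABC or GCB")
    is_abc = truth == "ABC"
    if is_abc.all() or (~is_abc).all():
        raise ValidationError("both classes must be present in the truth")
    return ConfusionSummary(
        n_abc=int(is_abc.sum()),
        n_gcb=int((~is_abc).sum()),
        correct_abc=int((predicted[is_abc] == "ABC").sum()),
        correct_gcb=int((predicted[~is_abc] == "GCB").sum()),
    )


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve with ABC as positive class.

    Computed as the Mann–Whitney concordance probability via mid-ranks, so
    tied scores count one half. Scores must be oriented so that larger means
    more ABC-like.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth == "ABC"
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def hierarchical_cluster(matrix: pd.DataFrame, n_clusters: int = 2) -> pd.Series:
    """Cluster *samples* on the signature genes (euclidean, complete linkage).

    The dendrogram is cut to ``n_clusters``; labels are 1-based cluster ids
    indexed by sample id. Agglomeration order on exactly tied distances
    follows the lowest observation index, so the result is deterministic.
    """
    if matrix.shape[1] < n_clusters:
        raise ValidationError("fewer samples than requested clusters")
    z = linkage(matrix.T.to_numpy(dtype=float), method="complete", metric="euclidean")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=matrix.columns.rename("sample_id"), name="cluster")


def chi_square_association(labels_a, labels_b, *, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of association between two label vectors.

    No continuity correction by default (expected counts are large in the
    intended uses). Raises on any zero row/column margin.
    """
    table = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b)).to_numpy()
    return chi_square_from_table(table, correction=correction)


def chi_square_from_table(table, *, correction: bool = False) -> tuple[float, float]:
    """Chi-square statistic and p for a contingency table with positive margins."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)
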