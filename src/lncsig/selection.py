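"""Cross-validated signature-size selection and frequency-based gene picking.

The candidate pool (the differentially expressed lncRNAs) is fixed; inside
each training fold the candidates are re-ranked by absolute signal-to-noise
ratio computed on the training samples only, and for every candidate size N a
weighted-voting model on the fold's top-N genes classifies the held-out fold.
With 5 folds and 100 permutations the procedure yields 500 fold-level ranking
lists and an error curve

    average_error_N = (sum of misclassified held-out samples over all
                       permutations and folds) / permutations,

i.e. the mean number of misclassified cohort samples per cross-validation
round. The signature size k is the smallest N whose average error is within
``tolerance`` misclassified samples of the curve minimum, and the k signature
genes are the genes most frequently appearing in the top-k of the 500 ranking
lists (ties broken by better mean rank, then gene id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from lncsig.errors import ValidationError
from lncsig.voting import snr

logger = logging.getLogger(__name__)


@dataclass
class CVSelectionResult:
    """Error curve, fold-level rankings and (once chosen) the signature."""

    error_curve: dict[int, float]
    accuracy_curve: dict[int, float]
    fold_rankings: list[list[str]]
    seed: int
    n_samples: int
    chosen_k: int | None = None
    selected_genes: list[tuple[str, int]] | None = field(default=None)

    @property
    def selected_gene_ids(self) -> list[str]:
        if self.selected_genes is None:
            raise ValidationError("signature not selected yet")
        return [g for g, _ in self.selected_genes]


def cv_error_curve(
    matrix: pd.DataFrame,
    labels: pd.Series,
    candidate_genes: list[str],
    n_values: list[int] | None = None,
    folds: int = 5,
    permutations: int = 100,
    seed: int = 0,
) -> CVSelectionResult:
    """Cross-validated misclassification curve over candidate signature sizes.

    Each permutation draws a fresh stratified ``folds``-fold split of the
    cohort. Gene ranking and model fitting use training samples only; the
    held-out fold is scored for every N in ``n_values`` (default: 1 ..
    number of candidates). Deterministic given ``seed``.
    """
    labels = pd.Series(labels).reindex(matrix.columns)
    if labels.isna().any() or not labels.isin(["ABC", "GCB"]).all():
        raise ValidationError("labels must be ABC or GCB for every matrix sample")
    absent = [g for g in candidate_genes if g not in matrix.index]
    if absent:
        raise ValidationError(f"candidate gene(s) not in matrix: {absent[:5]}")
    if not candidate_genes:
        raise ValidationError("empty candidate gene pool")
    if n_values is None:
        n_values = list(range(1, len(candidate_genes) + 1))
    if max(n_values) > len(candidate_genes):
        raise ValidationError("max(n_values) exceeds the candidate pool size")
    y = (labels == "ABC").to_numpy()
    class_min = min(int(y.sum()), int((~y).sum()))
    if class_min < folds:
        raise ValidationError(
            f"impossible stratification: smallest class has {class_min} samples for {folds} folds"
        )

    values = matrix.loc[candidate_genes].to_numpy(dtype=float)
    gene_ids = np.asarray(candidate_genes)
    n_values = sorted(set(int(n) for n in n_values))
    total_errors = {n: 0 for n in n_values}
    fold_rankings: list[list[str]] = []

    fold_seeds = np.random.SeedSequence(seed).generate_state(permutations)
    for perm in range(permutations):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(fold_seeds[perm]))
        for train_idx, test_idx in splitter.split(values.T, y):
            order, w, b = _rank_fold(values, y, train_idx, gene_ids)
            fold_rankings.append([gene_ids[i] for i in order])
            margins = _cumulative_margins(values, order, w, b, test_idx)
            majority_abc = y[train_idx].sum() > (~y[train_idx]).sum()
            y_test = y[test_idx]
            for n in n_values:
                depth = min(n, len(order))
                m = margins[depth - 1]
                pred_abc = np.where(m == 0, majority_abc, m > 0)
                total_errors[n] += int((pred_abc != y_test).sum())

    error_curve = {n: total_errors[n] / permutations for n in n_values}
    n_samples = matrix.shape[1]
    accuracy_curve = {n: 1.0 - e / n_samples for n, e in error_curve.items()}
    return CVSelectionResult(
        error_curve=error_curve,
        accuracy_curve=accuracy_curve,
        fold_rankings=fold_rankings,
        seed=seed,
        n_samples=n_samples,
    )


def _rank_fold(values, y, train_idx, gene_ids):
    """Rank candidates by |SNR| on the training fold; drop unusable genes."""
    xa = values[:, train_idx][:, y[train_idx]]
    xg = values[:, train_idx][:, ~y[train_idx]]
    w = snr(xa.mean(axis=1), xg.mean(axis=1), xa.std(axis=1, ddof=1), xg.std(axis=1, ddof=1))
    w = np.atleast_1d(w)
    b = (xa.mean(axis=1) + xg.mean(axis=1)) / 2.0
    usable = np.isfinite(w) & (w != 0)
    if not usable.any():
        raise ValidationError("no usable candidate gene in a training fold")
    idx = np.flatnonzero(usable)
    # deterministic order: |w| descending, gene id ascending on exact ties
    order = idx[np.lexsort((gene_ids[idx], -np.abs(w[idx])))]
    return order, w, b


def _cumulative_margins(values, order, w, b, test_idx):
    """Margins V_ABC − V_GCB of the top-N models for all N, via a cumsum."""
    e = values[np.ix_(order, test_idx)]
    d = e - b[order][:, None]
    # sign(w)*d determines the receiving class; |w|*|d| is the magnitude
    contrib = np.abs(w[order])[:, None] * np.abs(d) * np.sign(np.sign(w[order])[:, None] * d)
    return np.cumsum(contrib, axis=0)


def choose_k(error_curve: dict[int, float], tolerance: float = 1.0) -> int:
    """Smallest signature size whose error is within ``tolerance`` of the minimum.

    ``tolerance`` is in misclassified-sample units; the default of one sample
    formalises "a balance between accuracy and signature size": growing the
    signature past k buys back less than one misclassified sample per round.
    """
    if not error_curve:
        raise ValidationError("empty error curve")
    floor = min(error_curve.values()) + tolerance
    return min(n for n, e in sorted(error_curve.items()) if e <= floor)


def frequency_rank(fold_rankings: list[list[str]], k: int) -> list[tuple[str, int]]:
    """The k genes most frequently in the top-k of the fold-level rankings.

    Frequency of a gene = number of ranking lists whose top-k contains it.
    Ties are broken by better (smaller) mean rank across the lists where the
    gene appears, then lexicographically by gene id. Returns ``(gene_id,
    frequency)`` pairs with nonincreasing frequencies.
    """
    if not fold_rankings:
        raise ValidationError("no fold rankings")
    distinct = {g for ranking in fold_rankings for g in ranking}
    if k > len(distinct):
        raise ValidationError(f"k={k} exceeds the {len(distinct)} distinct ranked genes")
    counts: dict[str, int] = {}
    rank_sums: dict[str, list[float]] = {}
    for ranking in fold_rankings:
        for pos, g in enumerate(ranking, start=1):
            rank_sums.setdefault(g, []).append(pos)
            if pos <= k:
                counts[g] = counts.get(g, 0) + 1
    mean_rank = {g: float(np.mean(r)) for g, r in rank_sums.items()}
    ordered = sorted(distinct, key=lambda g: (-counts.get(g, 0), mean_rank[g], g))
    return [(g, counts.get(g, 0)) for g in ordered[:k]]


def select_signature(
    matrix: pd.DataFrame,
    labels: pd.Series,
    candidate_genes: list[str],
    n_values: list[int] | None = None,
    folds: int = 5,
    permutations: int = 100,
    tolerance: float = 1.0,
    seed: int = 0,
) -> CVSelectionResult:
    """Run the full selection: error curve → choose k → frequency-rank genes."""
    result = cv_error_curve(matrix, labels, candidate_genes, n_values, folds, permutations, seed)
    result.chosen_k = choose_k(result.error_curve, tolerance)
    result.selected_genes = frequency_rank(result.fold_rankings, result.chosen_k)
    logger.info("select_signature: chose k=%d from %d candidates", result.chosen_k, len(candidate_genes))
    return result
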