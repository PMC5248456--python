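"""lncRNA–mRNA co-expression: per-signature-gene top correlated mRNAs.

For every signature lncRNA the Pearson correlation with each mRNA profile is
computed across the shared samples; the mRNAs are ranked by r descending and
the top fraction (default 0.5%, ceil-rounded) kept per lncRNA. Only
positively correlated mRNAs enter the deduplicated union used downstream for
functional inference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lncsig.errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.005


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length, nonconstant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("vectors must have equal length")
    if len(x) < 3:
        raise ValidationError("correlation needs at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CoexpressionResult:
    """Per-lncRNA top co-expressed mRNA tables and their positive union."""

    tables: dict[str, pd.DataFrame]  # lncRNA id -> (mrna_id, r, rank)
    union_positive: list[str]
    fraction: float
    list_length: int


def top_coexpressed(
    lnc_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    fraction: float = DEFAULT_FRACTION,
) -> CoexpressionResult:
    """Rank mRNAs by correlation with each signature lncRNA; keep the top slice.

    Both matrices must cover the same samples (any order). Each per-lncRNA
    list has exactly ``ceil(fraction * n_mrna)`` entries, ties broken by mRNA
    id; ``union_positive`` collects mRNAs with r > 0 in at least one list.
    Constant mRNA rows (undefined correlation) are excluded with a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must lie in (0, 1)")
    if set(lnc_matrix.columns) != set(mrna_matrix.columns):
        raise ValidationError("lncRNA and mRNA matrices cover different samples")
    mrna_matrix = mrna_matrix[lnc_matrix.columns]
    n = lnc_matrix.shape[1]
    if n < 3:
        raise ValidationError("correlation needs at least 3 shared samples")
    n_mrna = mrna_matrix.shape[0]
    list_length = math.ceil(fraction * n_mrna)

    lnc = lnc_matrix.to_numpy(dtype=float)
    mrna = mrna_matrix.to_numpy(dtype=float)
    lnc_sd = lnc.std(axis=1, ddof=1)
    mrna_sd = mrna.std(axis=1, ddof=1)
    if (lnc_sd == 0).any():
        bad = list(lnc_matrix.index[lnc_sd == 0][:3])
        raise ValidationError(f"constant signature lncRNA row(s): {bad}")
    usable = mrna_sd > 0
    if not usable.all():
        logger.warning("top_coexpressed: excluded %d constant mRNA row(s)", int((~usable).sum()))

    zl = (lnc - lnc.mean(axis=1, keepdims=True)) / lnc_sd[:, None]
    zm = np.zeros_like(mrna)
    zm[usable] = (mrna[usable] - mrna[usable].mean(axis=1, keepdims=True)) / mrna_sd[usable, None]
    corr = zl @ zm.T / (n - 1)
    corr[:, ~usable] = -np.inf  # excluded rows can never be selected

    mrna_ids = np.asarray(mrna_matrix.index)
    tables: dict[str, pd.DataFrame] = {}
    union: set[str] = set()
    for i, lnc_id in enumerate(lnc_matrix.index):
        order = np.lexsort((mrna_ids, -corr[i]))[:list_length]
        r = corr[i][order]
        tables[lnc_id] = pd.DataFrame(
            {"mrna_id": mrna_ids[order], "r": r, "rank": np.arange(1, len(order) + 1)}
        )
        union.update(mrna_ids[order][r > 0])
    return CoexpressionResult(
        tables=tables,
        union_positive=sorted(union),
        fraction=fraction,
        list_length=list_length,
    )
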