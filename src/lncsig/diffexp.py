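"""Differential screening of lncRNAs between the two subtypes.

Each gene is tested with an unpaired two-tailed pooled-variance (Student)
t-test between ABC and GCB samples; p-values are corrected by the
Benjamini–Hochberg step-up procedure over all tested genes, and a gene passes
the screen when ``p < p_threshold`` and ``FDR < fdr_threshold`` (defaults
0.01 and 0.15).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncsig.errors import ValidationError

logger = logging.getLogger(__name__)

P_THRESHOLD = 0.01
FDR_THRESHOLD = 0.15


def pooled_t_test(x, y) -> tuple[float, float]:
    """Equal-variance two-sample t-test; returns ``(t, two-sided p)``.

    ``df = len(x) + len(y) - 2``. Raises :class:`ValidationError` if either
    group has fewer than 2 observations or the pooled variance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    pooled = ((len(x) - 1) * sx2 + (len(y) - 1) * sy2) / (len(x) + len(y) - 2)
    if pooled == 0:
        raise ValidationError("zero pooled variance: t-statistic undefined")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_lncrnas(
    matrix: pd.DataFrame,
    labels: pd.Series,
    p_threshold: float = P_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Screen every gene for differential expression between ABC and GCB.

    Parameters
    ----------
    matrix
        Gene-by-sample expression (z-score units).
    labels
        Subtype per sample (``ABC``/``GCB``), indexed by sample id; must cover
        every matrix column and contain both classes.

    Returns
    -------
    DataFrame with one row per gene: ``mean_abc``, ``mean_gcb``,
    ``t_statistic``, ``p_value``, ``fdr``, ``direction`` and ``passes``.
    Genes whose pooled variance is zero cannot be tested; they get NaN
    statistics, never pass, and are excluded from the BH family (an untested
    hypothesis carries no p-value). FDR is computed over all tested genes.
    """
    labels = pd.Series(labels)
    missing = matrix.columns.difference(labels.index)
    if len(missing):
        raise ValidationError(f"labels missing for {len(missing)} sample(s)")
    lab = labels.reindex(matrix.columns)
    if not lab.isin(["ABC", "GCB"]).all():
        raise ValidationError("labels must be ABC or GCB for every sample")
    is_abc = (lab == "ABC").to_numpy()
    n_abc, n_gcb = int(is_abc.sum()), int((~is_abc).sum())
    if n_abc < 2 or n_gcb < 2:
        raise ValidationError("both classes need at least 2 samples")

    values = matrix.to_numpy(dtype=float)
    xa, xg = values[:, is_abc], values[:, ~is_abc]
    mean_abc, mean_gcb = xa.mean(axis=1), xg.mean(axis=1)
    va, vg = xa.var(axis=1, ddof=1), xg.var(axis=1, ddof=1)
    df = n_abc + n_gcb - 2
    pooled = ((n_abc - 1) * va + (n_gcb - 1) * vg) / df
    tested = pooled > 0

    t = np.full(len(matrix), np.nan)
    p = np.full(len(matrix), np.nan)
    se = np.sqrt(pooled[tested] * (1.0 / n_abc + 1.0 / n_gcb))
    t[tested] = (mean_abc[tested] - mean_gcb[tested]) / se
    p[tested] = 2.0 * stats.t.sf(np.abs(t[tested]), df)

    fdr = np.full(len(matrix), np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(p[tested])
    n_untested = int((~tested).sum())
    if n_untested:
        logger.warning("differential_lncrnas: %d gene(s) with zero pooled variance not tested", n_untested)

    passes = np.zeros(len(matrix), dtype=bool)
    passes[tested] = (p[tested] < p_threshold) & (fdr[tested] < fdr_threshold)
    result = pd.DataFrame(
        {
            "mean_abc": mean_abc,
            "mean_gcb": mean_gcb,
            "t_statistic": t,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(mean_abc > mean_gcb, "up_ABC", "up_GCB"),
            "passes": passes,
        },
        index=matrix.index,
    )
    result.loc[~tested, "direction"] = pd.NA
    result.index.name = "gene_id"
    return result
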