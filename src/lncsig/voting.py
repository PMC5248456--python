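"""Weighted-voting subtype classifier with signal-to-noise gene weights.

For every signature gene *L* the training cohort yields class means and
standard deviations (μ_ABC, μ_GCB, σ_ABC, σ_GCB). The gene's weight is its
signal-to-noise ratio

    w_L = (μ_ABC − μ_GCB) / (σ_ABC + σ_GCB)          (mode="sum", default)
    w_L = (μ_ABC − μ_GCB) / (σ_ABC − σ_GCB)          (mode="difference")

and its decision boundary is the midpoint b_L = (μ_ABC + μ_GCB)/2. A test
sample with expression e_L casts, per gene, a vote of magnitude
|w_L|·|e_L − b_L|; the vote accrues to ABC when sign(w_L)·(e_L − b_L) > 0, to
GCB when negative, and to neither when the sample sits exactly on the
boundary. The class with the larger vote total V wins; the continuous score
(V_ABC − V_GCB)/(V_ABC + V_GCB) in [−1, 1] orders samples for ROC analysis,
and prob_abc = V_ABC/(V_ABC + V_GCB).

``mode="sum"`` is the classical signal-to-noise denominator and the package
default; the ``difference`` denominator is retained for comparison runs but
is undefined (and drops genes) whenever the two class standard deviations
coincide.

A trained model can be *restricted* to the subset of its genes present on
another platform without re-estimating any parameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from lncsig.errors import ValidationError

logger = logging.getLogger(__name__)

MODEL_COLUMNS = ["mu_abc", "mu_gcb", "sigma_abc", "sigma_gcb", "w", "b"]


def snr(mu_abc, mu_gcb, sigma_abc, sigma_gcb, mode: str = "sum"):
    """Signal-to-noise weight of one gene (or arrays of genes).

    Returns NaN where the denominator is zero; such genes are unusable and
    dropped at training time.
    """
    if mode not in ("sum", "difference"):
        raise ValidationError(f"unknown snr mode {mode!r}; expected 'sum' or 'difference'")
    mu_abc = np.asarray(mu_abc, dtype=float)
    mu_gcb = np.asarray(mu_gcb, dtype=float)
    denom = (
        np.asarray(sigma_abc, dtype=float) + np.asarray(sigma_gcb, dtype=float)
        if mode == "sum"
        else np.asarray(sigma_abc, dtype=float) - np.asarray(sigma_gcb, dtype=float)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom != 0, (mu_abc - mu_gcb) / np.where(denom == 0, 1.0, denom), np.nan)
    return w if w.ndim else float(w)


@dataclass
class WeightedVotingModel:
    """A fitted signature: per-gene statistics, weights and boundaries.

    ``stats`` is indexed by gene id with columns ``mu_abc``, ``mu_gcb``,
    ``sigma_abc``, ``sigma_gcb``, ``w``, ``b``. ABC is the positive class.
    ``majority_class`` (the larger training class) breaks exact vote ties.
    """

    stats: pd.DataFrame
    mode: str = "sum"
    positive_class: str = "ABC"
    majority_class: str = "GCB"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.stats.index)

    def __len__(self) -> int:
        return len(self.stats)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialise the model (stable key order); optionally write to a file."""
        payload = {
            "mode": self.mode,
            "positive_class": self.positive_class,
            "majority_class": self.majority_class,
            "genes": [
                {"gene_id": g, **{c: float(row[c]) for c in MODEL_COLUMNS}}
                for g, row in self.stats.iterrows()
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "WeightedVotingModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        stats = pd.DataFrame(payload["genes"]).set_index("gene_id")[MODEL_COLUMNS]
        return cls(
            stats=stats,
            mode=payload["mode"],
            positive_class=payload["positive_class"],
            majority_class=payload["majority_class"],
        )


@dataclass
class PredictionResult:
    """Vote totals and decision for one sample."""

    sample_id: str
    v_abc: float
    v_gcb: float
    predicted: str
    score: float = field(init=False)
    prob_abc: float = field(init=False)

    def __post_init__(self):
        total = self.v_abc + self.v_gcb
        self.score = (self.v_abc - self.v_gcb) / total if total > 0 else 0.0
        self.prob_abc = (self.score + 1.0) / 2.0


def train(
    matrix: pd.DataFrame,
    labels: pd.Series,
    genes: Iterable[str] | None = None,
    mode: str = "sum",
) -> WeightedVotingModel:
    """Fit per-gene class statistics and weights on a labelled cohort.

    Class standard deviations use the sample convention (ddof=1). Genes with
    an undefined weight (zero denominator) are dropped with a warning; an
    empty usable set raises :class:`ValidationError`.
    """
    labels = pd.Series(labels).reindex(matrix.columns)
    if labels.isna().any() or not labels.isin(["ABC", "GCB"]).all():
        raise ValidationError("labels must be ABC or GCB for every matrix sample")
    if genes is not None:
        genes = list(genes)
        absent = [g for g in genes if g not in matrix.index]
        if absent:
            raise ValidationError(f"gene(s) not in matrix: {absent[:5]}")
        matrix = matrix.loc[genes]
    is_abc = (labels == "ABC").to_numpy()
    if is_abc.sum() < 2 or (~is_abc).sum() < 2:
        raise ValidationError("both classes need at least 2 training samples")

    values = matrix.to_numpy(dtype=float)
    xa, xg = values[:, is_abc], values[:, ~is_abc]
    stats = pd.DataFrame(
        {
            "mu_abc": xa.mean(axis=1),
            "mu_gcb": xg.mean(axis=1),
            "sigma_abc": xa.std(axis=1, ddof=1),
            "sigma_gcb": xg.std(axis=1, ddof=1),
        },
        index=matrix.index,
    )
    stats["w"] = snr(stats["mu_abc"], stats["mu_gcb"], stats["sigma_abc"], stats["sigma_gcb"], mode)
    stats["b"] = (stats["mu_abc"] + stats["mu_gcb"]) / 2.0
    usable = np.isfinite(stats["w"].to_numpy())
    if not usable.all():
        logger.warning("train: dropped %d gene(s) with undefined weight", int((~usable).sum()))
        stats = stats.loc[usable]
    if stats.empty:
        raise ValidationError("no usable genes: every weight is undefined")
    majority = "ABC" if is_abc.sum() > (~is_abc).sum() else "GCB"
    return WeightedVotingModel(stats=stats, mode=mode, majority_class=majority)


def vote_components(model: WeightedVotingModel, matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample vote totals ``(v_abc, v_gcb)`` for a gene-by-sample matrix."""
    missing = [g for g in model.gene_ids if g not in matrix.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} model gene(s) missing from matrix (e.g. {missing[:3]}); "
            "use restrict_model first"
        )
    e = matrix.loc[model.gene_ids].to_numpy(dtype=float)
    w = model.stats["w"].to_numpy()[:, None]
    b = model.stats["b"].to_numpy()[:, None]
    d = e - b
    magnitude = np.abs(w) * np.abs(d)
    signed = np.sign(w) * d
    v_abc = np.where(signed > 0, magnitude, 0.0).sum(axis=0)
    v_gcb = np.where(signed < 0, magnitude, 0.0).sum(axis=0)
    return v_abc, v_gcb


def predict_samples(model: WeightedVotingModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Classify every column of ``matrix``.

    Returns a DataFrame indexed by sample id with columns ``v_abc``,
    ``v_gcb``, ``predicted``, ``score`` and ``prob_abc``. Exact vote ties
    (measure-zero) go to the majority training class with a logged warning.
    """
    v_abc, v_gcb = vote_components(model, matrix)
    ties = v_abc == v_gcb
    if ties.any():
        logger.warning("predict: %d tied sample(s) assigned to %s", int(ties.sum()), model.majority_class)
    predicted = np.where(v_abc > v_gcb, "ABC", np.where(v_abc < v_gcb, "GCB", model.majority_class))
    total = v_abc + v_gcb
    score = np.divide(v_abc - v_gcb, total, out=np.zeros_like(total), where=total > 0)
    return pd.DataFrame(
        {
            "v_abc": v_abc,
            "v_gcb": v_gcb,
            "predicted": predicted,
            "score": score,
            "prob_abc": (score + 1.0) / 2.0,
        },
        index=matrix.columns.rename("sample_id"),
    )


def predict(model: WeightedVotingModel, expression: Mapping[str, float] | pd.Series,
            sample_id: str = "sample") -> PredictionResult:
    """Classify a single sample given its expression values by gene id."""
    expression = pd.Series(expression, dtype=float)
    frame = expression.to_frame(name=sample_id)
    result = predict_samples(model, frame).iloc[0]
    return PredictionResult(
        sample_id=sample_id,
        v_abc=float(result["v_abc"]),
        v_gcb=float(result["v_gcb"]),
        predicted=str(result["predicted"]),
    )


def restrict_model(model: WeightedVotingModel, available_genes: Iterable[str]) -> WeightedVotingModel:
    """Restrict the signature to genes measured on another platform.

    Stored weights and boundaries are kept verbatim — no re-estimation.
    Restriction to all model genes is the identity; an empty intersection is
    an error.
    """
    available = set(available_genes)
    keep = [g for g in model.gene_ids if g in available]
    if not keep:
        raise ValidationError("no overlap between model genes and available genes")
    if len(keep) < len(model):
        logger.info("restrict_model: %d of %d signature genes retained", len(keep), len(model))
    return WeightedVotingModel(
        stats=model.stats.loc[keep].copy(),
        mode=model.mode,
        positive_class=model.positive_class,
        majority_class=model.majority_class,
    )
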