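"""End-to-end orchestration: discovery and validation runs.

``run_discovery`` executes the full chain on a labelled cohort —
differential screen → cross-validated signature-size selection →
frequency-based gene picking → weighted-voting training → in-cohort
prediction, confusion/ROC metrics, clustering association and survival
contrasts — and optionally writes every stage's numeric table. Given the same
config and seed the written outputs are byte-identical.

``run_validation`` applies a frozen model to further cohorts, automatically
restricting the signature to the genes a cohort measures (no re-estimation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lncsig.errors import NoCandidatesError, PipelineError, ValidationError
from lncsig import diffexp as de
from lncsig import selection as sel
from lncsig import voting
from lncsig.evaluation import (
    chi_square_association,
    confusion_metrics,
    hierarchical_cluster,
    roc_auc,
)
from lncsig.io import FLOAT_FORMAT
from lncsig.survival import cox_fit, group_survival_table, log_rank

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs of a discovery/validation run (defaults = study settings)."""

    p_threshold: float = 0.01
    fdr_threshold: float = 0.15
    folds: int = 5
    permutations: int = 100
    n_values: list[int] | None = None
    tolerance: float = 1.0
    snr_mode: str = "sum"
    coexpression_fraction: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p_threshold < 1 or not 0 < self.fdr_threshold < 1:
            raise ValidationError("thresholds must lie in (0, 1)")
        if self.folds < 2:
            raise ValidationError("folds must be at least 2")
        if self.permutations < 1:
            raise ValidationError("permutations must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass
class DiscoveryResult:
    diffexp: pd.DataFrame
    candidates: list[str]
    cv: sel.CVSelectionResult
    model: voting.WeightedVotingModel
    predictions: pd.DataFrame
    confusion: object
    auc: float
    cluster_chi2: tuple[float, float] | None
    survival: dict = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)


@dataclass
class ValidationResult:
    cohort: str
    n_signature_genes: int
    predictions: pd.DataFrame
    confusion: object
    auc: float
    survival: dict = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)


def stratified_split(
    annotation: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Split sample ids into two cohorts preserving the subtype ratio."""
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    first: list[str] = []
    second: list[str] = []
    for _, sub in annotation.groupby("subtype", sort=True, dropna=False):
        ids = list(sub.index)
        rng.shuffle(ids)
        cut = int(round(fraction * len(ids)))
        first.extend(ids[:cut])
        second.extend(ids[cut:])
    return sorted(first), sorted(second)


def run_discovery(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> DiscoveryResult:
    """Discover a signature on a labelled cohort; optionally write all stages."""
    config = config or PipelineConfig()
    labelled = annotation[annotation["subtype"].isin(["ABC", "GCB"])]
    if labelled["subtype"].nunique() < 2:
        raise PipelineError("discovery: cohort does not contain both subtypes")
    matrix = matrix[list(labelled.index)]
    labels = labelled["subtype"]
    logger.info("discovery: %d genes x %d labelled samples", *matrix.shape)

    try:
        de_table = de.differential_lncrnas(matrix, labels, config.p_threshold, config.fdr_threshold)
    except ValidationError as exc:
        raise PipelineError(f"diffexp: {exc}") from exc
    candidates = list(de_table.index[de_table["passes"]])
    if not candidates:
        raise NoCandidatesError(
            "diffexp: no candidates — no lncRNA passed the differential screen"
        )
    logger.info("diffexp: %d candidate(s) pass p<%g, FDR<%g", len(candidates),
                config.p_threshold, config.fdr_threshold)

    n_values = config.n_values or list(range(1, len(candidates) + 1))
    n_values = [n for n in n_values if n <= len(candidates)]
    cv = sel.select_signature(
        matrix,
        labels,
        candidates,
        n_values=n_values,
        folds=config.folds,
        permutations=config.permutations,
        tolerance=config.tolerance,
        seed=config.seed,
    )

    model = voting.train(matrix, labels, genes=cv.selected_gene_ids, mode=config.snr_mode)
    predictions = voting.predict_samples(model, matrix)
    confusion = confusion_metrics(predictions["predicted"], labels)
    auc = roc_auc(predictions["score"], labels.to_numpy())

    cluster_chi2 = None
    try:
        clusters = hierarchical_cluster(matrix.loc[model.gene_ids], n_clusters=2)
        cluster_chi2 = chi_square_association(clusters.to_numpy(), labels.to_numpy())
    except ValidationError as exc:  # degenerate small cohorts
        logger.warning("clustering association skipped: %s", exc)

    survival = _survival_block(labelled, predictions)

    result = DiscoveryResult(
        diffexp=de_table,
        candidates=candidates,
        cv=cv,
        model=model,
        predictions=predictions,
        confusion=confusion,
        auc=auc,
        cluster_chi2=cluster_chi2,
        survival=survival,
    )
    if outdir is not None:
        result.outputs = _write_discovery(result, config, Path(outdir))
    return result


def run_validation(
    model: voting.WeightedVotingModel,
    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict[str, ValidationResult]:
    """Apply a frozen signature model to one or more validation cohorts.

    The model is restricted (without refitting) to each cohort's measured
    genes; a cohort with zero signature-gene overlap is an error.
    """
    config = config or PipelineConfig()
    results: dict[str, ValidationResult] = {}
    for name, (matrix, annotation) in cohorts.items():
        overlap = [g for g in model.gene_ids if g in matrix.index]
        if not overlap:
            raise PipelineError(f"validation[{name}]: zero signature-gene overlap")
        local = voting.restrict_model(model, overlap) if len(overlap) < len(model) else model
        if len(overlap) < len(model):
            logger.info("validation[%s]: model restricted to %d of %d genes",
                        name, len(overlap), len(model))
        labelled = annotation[annotation["subtype"].isin(["ABC", "GCB"])]
        predictions = voting.predict_samples(local, matrix[list(labelled.index)])
        confusion = confusion_metrics(predictions["predicted"], labelled["subtype"])
        auc = roc_auc(predictions["score"], labelled["subtype"].to_numpy())
        survival = _survival_block(labelled, predictions)
        res = ValidationResult(
            cohort=name,
            n_signature_genes=len(local),
            predictions=predictions,
            confusion=confusion,
            auc=auc,
            survival=survival,
        )
        if outdir is not None:
            res.outputs = _write_validation(res, config, Path(outdir) / name)
        results[name] = res
    return results


def _survival_block(annotation: pd.DataFrame, predictions: pd.DataFrame) -> dict:
    """KM summaries, log-rank and univariate Cox of the predicted groups."""
    block: dict = {}
    pred = predictions["predicted"].reindex(annotation.index)
    groups = np.where(pred == "ABC", "ABC-like", "GCB-like")
    for endpoint in ("os", "pfs"):
        tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
        if tcol not in annotation.columns or ecol not in annotation.columns:
            continue
        ok = annotation[[tcol, ecol]].notna().all(axis=1).to_numpy()
        times = annotation.loc[ok, tcol].to_numpy(dtype=float)
        events = annotation.loc[ok, ecol].to_numpy(dtype=float)
        g = groups[ok]
        if len(pd.unique(g)) < 2 or len(times) == 0 or events.sum() == 0:
            logger.warning("survival[%s]: contrast not testable (one group or no events)", endpoint)
            block[endpoint] = {"testable": False}
            continue
        stat, p = log_rank(times, events, g)
        cox = cox_fit(times, events, pd.DataFrame({"predicted_abc": (g == "ABC-like").astype(float)}))[0]
        block[endpoint] = {
            "testable": True,
            "table": group_survival_table(times, events, g),
            "logrank_statistic": stat,
            "logrank_p": p,
            "cox": cox,
        }
    return block


# --------------------------------------------------------------------------
# output writing

def _header(config: PipelineConfig) -> str:
    return f"# lncsig config_hash={config.config_hash} seed={config.seed}\n"


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = True) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header(config))
        frame.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index, lineterminator="\n")
    return path


def _metrics_frame(cohort: str, confusion, auc: float) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cohort": cohort,
                "n_abc": confusion.n_abc,
                "n_gcb": confusion.n_gcb,
                "correct_abc": confusion.correct_abc,
                "correct_gcb": confusion.correct_gcb,
                "accuracy_pct": confusion.percent("accuracy"),
                "sensitivity_pct": confusion.percent("sensitivity"),
                "specificity_pct": confusion.percent("specificity"),
                "auc": round(auc, 4),
            }
        ]
    )


def _survival_frames(survival: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    km_rows, cox_rows = [], []
    for endpoint, blk in survival.items():
        if not blk.get("testable"):
            km_rows.append({"endpoint": endpoint, "group": "NA", "n": 0, "events": 0,
                            "median_months": "NA", "rate_60mo": "NA",
                            "logrank_statistic": "NA", "logrank_p": "NA"})
            continue
        for _, row in blk["table"].iterrows():
            km_rows.append({"endpoint": endpoint, **row.to_dict(),
                            "logrank_statistic": blk["logrank_statistic"],
                            "logrank_p": blk["logrank_p"]})
        cox_rows.append({"endpoint": endpoint, "mode": "univariate", **blk["cox"].as_dict()})
    return pd.DataFrame(km_rows), pd.DataFrame(cox_rows)


def _write_discovery(result: DiscoveryResult, config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    outputs["diffexp"] = _write_tsv(result.diffexp, outdir / "diffexp.tsv", config)
    curve = pd.DataFrame(
        {
            "n_genes": list(result.cv.error_curve),
            "average_error": [result.cv.error_curve[n] for n in result.cv.error_curve],
            "accuracy": [result.cv.accuracy_curve[n] for n in result.cv.error_curve],
        }
    )
    outputs["cv_curve"] = _write_tsv(curve, outdir / "cv_curve.tsv", config, index=False)
    signature = {
        "chosen_k": result.cv.chosen_k,
        "selected_genes": [
            {"gene_id": g, "frequency": int(f)} for g, f in result.cv.selected_genes
        ],
        "n_candidates": len(result.candidates),
        "seed": result.cv.seed,
        "config": config.to_dict(),
    }
    outputs["signature"] = outdir / "signature.json"
    outputs["signature"].write_text(json.dumps(signature, indent=2, sort_keys=True) + "\n")
    outputs["model"] = outdir / "model.json"
    result.model.to_json(outputs["model"])
    outputs["predictions"] = _write_tsv(result.predictions, outdir / "predictions.tsv", config)
    outputs["metrics"] = _write_tsv(
        _metrics_frame("discovery", result.confusion, result.auc),
        outdir / "metrics.tsv", config, index=False,
    )
    km, cox = _survival_frames(result.survival)
    outputs["survival"] = _write_tsv(km, outdir / "survival.tsv", config, index=False)
    if len(cox):
        outputs["cox"] = _write_tsv(cox, outdir / "cox.tsv", config, index=False)
    return outputs


def _write_validation(result: ValidationResult, config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    outputs["predictions"] = _write_tsv(result.predictions, outdir / "predictions.tsv", config)
    outputs["metrics"] = _write_tsv(
        _metrics_frame(result.cohort, result.confusion, result.auc),
        outdir / "metrics.tsv", config, index=False,
    )
    km, cox = _survival_frames(result.survival)
    outputs["survival"] = _write_tsv(km, outdir / "survival.tsv", config, index=False)
    if len(cox):
        outputs["cox"] = _write_tsv(cox, outdir / "cox.tsv", config, index=False)
    return outputs
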