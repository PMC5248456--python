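"""Expression-matrix and clinical-table IO plus the in-scope preprocessing tail.

Expression matrices are plain pandas DataFrames with gene (or probe) ids on the
index and sample ids on the columns, holding z-scored log2 intensities.
Clinical annotation is a DataFrame indexed by sample id with the columns listed
in :data:`ANNOTATION_COLUMNS`; missing cells stay missing (``NaN``) and are
never imputed here.

The two preprocessing operations that remain in scope once arrays have been
normalised upstream are :func:`collapse_probes` (mean over multiple probes of
one gene) and :func:`zscore_rows` (per-gene z-scaling within a cohort).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from lncsig.errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: float formatting used for every TSV the package writes
FLOAT_FORMAT = "%.6g"

ANNOTATION_COLUMNS = [
    "subtype",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "age_ge60",
    "gender",
    "stage_34",
    "ldh_high",
    "extranodal_ge2",
    "ecog_ge2",
]

_BINARY_COLUMNS = [
    "os_event",
    "pfs_event",
    "age_ge60",
    "stage_34",
    "ldh_high",
    "extranodal_ge2",
    "ecog_ge2",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample expression TSV into a DataFrame.

    The first column (``gene_id`` or ``probe_id``) becomes the index; the
    remaining header fields are sample ids. Raises :class:`ParseError` (with a
    1-based line number where applicable) on duplicate ids, ragged rows or
    non-numeric cells.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}:1: expected at least one sample column")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"{path}:1: duplicate sample id(s): {', '.join(dup)}")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric expression cell ({exc})") from None
    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dup_genes = sorted({g for g in gene_ids if g in seen or seen.add(g)})
        raise ParseError(f"{path}: duplicate gene id(s): {', '.join(dup_genes)}")
    matrix = pd.DataFrame(np.asarray(rows, dtype=float), index=gene_ids, columns=samples)
    matrix.index.name = header[0]
    if not np.isfinite(matrix.to_numpy()).all():
        raise ParseError(f"{path}: non-finite expression values")
    return matrix


def write_expression(matrix: pd.DataFrame, path: str | Path, *, id_column: str = "gene_id") -> None:
    """Write an expression DataFrame as a TSV (floats at 6 significant digits)."""
    _check_matrix(matrix)
    out = matrix.copy()
    out.index.name = id_column
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a clinical annotation TSV indexed by ``sample_id``.

    Empty cells are kept as missing. Event indicators must be 0/1 and survival
    times nonnegative; violations raise :class:`ValidationError`.
    """
    path = Path(path)
    ann = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if "sample_id" not in ann.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    ann = ann.replace("", np.nan).set_index("sample_id")
    if ann.index.duplicated().any():
        dup = sorted(ann.index[ann.index.duplicated()].unique())
        raise ParseError(f"{path}: duplicate sample id(s): {', '.join(dup)}")
    for col in ("os_months", "pfs_months") + tuple(_BINARY_COLUMNS):
        if col in ann.columns:
            try:
                ann[col] = ann[col].astype(float)
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric value in column {col} ({exc})") from None
    validate_annotation(ann)
    return ann


def validate_annotation(ann: pd.DataFrame) -> None:
    """Check annotation invariants: labels, 0/1 indicators, nonnegative times."""
    if "subtype" in ann.columns:
        bad = ann["subtype"].dropna()[~ann["subtype"].dropna().isin(["ABC", "GCB"])]
        if len(bad):
            raise ValidationError(
                f"invalid subtype value(s) {sorted(bad.unique())}; expected ABC/GCB or missing"
            )
    for col in _BINARY_COLUMNS:
        if col in ann.columns:
            vals = ann[col].dropna()
            if not vals.isin([0.0, 1.0]).all():
                raise ValidationError(f"column {col} must be 0/1; got {sorted(vals.unique())}")
    for col in ("os_months", "pfs_months"):
        if col in ann.columns and (ann[col].dropna() < 0).any():
            raise ValidationError(f"column {col} contains negative times")
    if "gender" in ann.columns:
        vals = ann["gender"].dropna()
        if not vals.isin(["M", "F"]).all():
            raise ValidationError(f"column gender must be M/F; got {sorted(vals.unique())}")


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    """Write a clinical annotation table; missing values become empty cells."""
    validate_annotation(ann)
    out = ann.copy()
    out.index.name = "sample_id"
    # binary indicators as integers, not 1.0, for readable files
    for col in _BINARY_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="", lineterminator="\n")


def collapse_probes(matrix: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level by averaging probe rows.

    Probes absent from ``probe_map`` are dropped (their count is logged);
    single-probe genes pass through unchanged. Gene order follows the first
    appearance of each gene among the mapped probes.
    """
    _check_matrix(matrix)
    if any(not g for g in probe_map.values()):
        raise ValidationError("probe map contains an empty gene id")
    mapped = [p for p in matrix.index if p in probe_map]
    if not mapped:
        raise ValidationError("no probe in the matrix is present in the probe map")
    dropped = len(matrix) - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", dropped)
    genes = pd.Series([probe_map[p] for p in mapped], index=mapped, name="gene_id")
    collapsed = matrix.loc[mapped].groupby(genes, sort=False).mean()
    collapsed.index.name = "gene_id"
    return collapsed


def zscore_rows(matrix: pd.DataFrame, *, ddof: int = 1) -> pd.DataFrame:
    """Z-scale every gene row to mean 0 / standard deviation 1.

    Uses the sample standard deviation (``ddof=1``) by default; pass ``ddof=0``
    for the population convention. Constant rows cannot be scaled and are
    mapped to all-zeros with a logged warning, which gives them zero weight in
    every downstream stage.
    """
    _check_matrix(matrix)
    if matrix.shape[1] < 2:
        raise ValidationError("z-scoring requires at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("zscore_rows: %d constant row(s) set to zeros", int(constant.sum()))
    sd[sd == 0] = 1.0
    scaled = (values - mean) / sd
    scaled[constant, :] = 0.0
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("degenerate expression matrix (no genes or no samples)")
    if matrix.index.duplicated().any():
        raise ValidationError("duplicate gene ids in matrix")
    if matrix.columns.duplicated().any():
        raise ValidationError("duplicate sample ids in matrix")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValidationError("matrix contains non-finite values")
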