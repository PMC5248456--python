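"""Survival association of predicted subtype groups.

Kaplan–Meier curves, the log-rank test, and uni-/multivariate Cox
proportional-hazards fits (Efron tie handling, Wald confidence intervals),
plus the stratified analyses that probe whether the signature's prognostic
value is independent of clinical factors. Estimation is delegated to
``lifelines``; this module fixes the conventions (rates read from the
right-continuous step function, complete-case covariate handling, per-stratum
testability rules) and the tabular output shapes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from lncsig.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class KaplanMeierEstimate:
    """Product-limit survival estimate with a rate lookup."""

    fitter: KaplanMeierFitter
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (value after events ≤ t)."""
        return float(self.fitter.predict(t))

    @property
    def median(self) -> float | None:
        """Median survival in months, or ``None`` when never reached (S > 0.5)."""
        m = self.fitter.median_survival_time_
        return None if np.isinf(m) else float(m)

    @property
    def step_function(self) -> pd.Series:
        return self.fitter.survival_function_.iloc[:, 0]


@dataclass
class CoxFit:
    """One proportional-hazards coefficient with Wald inference."""

    covariate: str
    coef: float
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float
    n_used: int
    n_events: int

    def as_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "coef": self.coef,
            "hazard_ratio": self.hazard_ratio,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "n_events": self.n_events,
        }


def kaplan_meier(times, events) -> KaplanMeierEstimate:
    """Kaplan–Meier estimate of one group's survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if len(times) == 0:
        raise ValidationError("empty survival input")
    if (times < 0).any():
        raise ValidationError("negative survival times")
    if not np.isin(events, [0.0, 1.0]).all():
        raise ValidationError("event indicators must be 0/1")
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    return KaplanMeierEstimate(fitter=fitter, n=len(times), n_events=int(events.sum()))


def log_rank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi-square statistic, p)`` at df=1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    times,
    events,
    covariates: pd.DataFrame,
    mode: str = "univariate",
    ties: str = "efron",
) -> list[CoxFit]:
    """Cox proportional-hazards regression of survival on covariates.

    ``mode="univariate"`` fits one single-covariate model per column;
    ``mode="multivariate"`` fits one joint model. Rows with any missing value
    among the covariates entering a fit are dropped (complete-case, logged).
    Raises :class:`ValidationError` when no events remain or the partial
    likelihood is monotone (complete separation), naming the covariate(s).
    """
    if mode not in ("univariate", "multivariate"):
        raise ValidationError("mode must be 'univariate' or 'multivariate'")
    if ties != "efron":
        raise ValidationError("only Efron tie handling is implemented")
    covariates = pd.DataFrame(covariates)
    frame = covariates.copy()
    frame["_time"] = np.asarray(times, dtype=float)
    frame["_event"] = np.asarray(events, dtype=float)
    groups = [[c] for c in covariates.columns] if mode == "univariate" else [list(covariates.columns)]
    fits: list[CoxFit] = []
    for cols in groups:
        sub = frame[cols + ["_time", "_event"]].dropna()
        dropped = len(frame) - len(sub)
        if dropped:
            logger.info("cox_fit(%s): dropped %d incomplete row(s)", ",".join(cols), dropped)
        if sub["_event"].sum() == 0:
            raise ValidationError(f"no events among complete cases for covariate(s) {cols}")
        cph = CoxPHFitter()
        try:
            cph.fit(
                sub,
                duration_col="_time",
                event_col="_event",
                fit_options={"step_size": 0.95},
            )
        except ConvergenceError as exc:
            raise ValidationError(
                f"Cox fit failed (likely complete separation) for covariate(s) {cols}: {exc}"
            ) from None
        summary = cph.summary
        for cov in cols:
            row = summary.loc[cov]
            fits.append(
                CoxFit(
                    covariate=str(cov),
                    coef=float(row["coef"]),
                    hazard_ratio=float(row["exp(coef)"]),
                    ci95_low=float(np.exp(row["coef lower 95%"])),
                    ci95_high=float(np.exp(row["coef upper 95%"])),
                    p_value=float(row["p"]),
                    n_used=len(sub),
                    n_events=int(sub["_event"].sum()),
                )
            )
    return fits


def group_survival_table(times, events, groups, horizons=(60.0,)) -> pd.DataFrame:
    """Per-group KM summary: n, events, median (or NR) and S(t) at horizons."""
    frame = pd.DataFrame({"time": np.asarray(times, float), "event": np.asarray(events, float),
                          "group": np.asarray(groups)})
    rows = []
    for level, sub in frame.groupby("group", sort=True):
        km = kaplan_meier(sub["time"], sub["event"])
        row = {
            "group": level,
            "n": km.n,
            "events": km.n_events,
            "median_months": km.median if km.median is not None else "NR",
        }
        for h in horizons:
            row[f"rate_{int(h)}mo"] = km.survival_at(h)
        rows.append(row)
    return pd.DataFrame(rows)


def stratified_analysis(
    times,
    events,
    predicted_groups,
    strata,
) -> dict:
    """Survival contrast of predicted groups within each stratum level.

    For every level of ``strata`` (e.g. age ≥60 yes/no) the predicted ABC-like
    vs GCB-like contrast is re-tested: KM summaries, log-rank, and a
    univariate Cox fit of predicted-ABC. A stratum in which only one predicted
    group occurs is reported as not testable. Samples with a missing stratum
    value are excluded.
    """
    frame = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=float),
            "pred": np.asarray(predicted_groups),
            "stratum": pd.Series(np.asarray(strata)).values,
        }
    ).dropna(subset=["stratum"])
    results: dict = {}
    for level, sub in frame.groupby("stratum", sort=True):
        if sub["pred"].nunique() < 2:
            results[level] = {"testable": False, "n": len(sub)}
            continue
        stat, p = log_rank(sub["time"], sub["event"], sub["pred"])
        cox = cox_fit(
            sub["time"],
            sub["event"],
            pd.DataFrame({"predicted_abc": (sub["pred"] == "ABC").astype(float)}),
        )[0]
        results[level] = {
            "testable": True,
            "n": len(sub),
            "km": group_survival_table(sub["time"], sub["event"], sub["pred"]),
            "logrank_statistic": stat,
            "logrank_p": p,
            "cox": cox,
        }
    return results
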