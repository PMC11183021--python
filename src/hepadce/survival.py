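"""Recurrence-free survival by nomogram risk group and surgical approach.

Kaplan-Meier product-limit curves (lifelines) with the convention that events
precede censorings at tied times; log-rank tests across risk groups and,
within a risk group, between anatomical (AR) and non-anatomical (NAR)
resection.  Medians that the follow-up never reaches are reported as
"not reached" rather than extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .perfusion import InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: S(t) step function with at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


@dataclass(frozen=True)
class SurvivalSummary:
    median: float | None  # None = not reached
    median_label: str
    rate_at_horizon: float
    horizon: float
    logrank_statistic: float | None = None
    logrank_p: float | None = None


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate; ties handled events-before-censorings."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise InvalidInputError("empty survival input")
    if np.any(times < 0):
        raise InvalidInputError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"].to_numpy()
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].reindex(grid).to_numpy(dtype=float)
    observed = table["observed"].reindex(grid).fillna(0).to_numpy(dtype=float)
    return SurvivalCurve(
        times=grid,
        survival=sf,
        at_risk=at_risk,
        n_events=observed,
        censor_times=np.sort(times[~events]),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank test across k groups: chi-square statistic with k-1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups)
    if np.unique(groups).size < 2:
        raise InvalidInputError("need >= 2 groups")
    if not events.any():
        raise InvalidInputError("no events observed; log-rank undefined")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def rfs_summary(curve: SurvivalCurve, horizon_months: float = 24.0) -> SurvivalSummary:
    """Median RFS (or "not reached") and the survival rate at a horizon."""
    below = curve.survival <= 0.5
    if below.any():
        median = float(curve.times[below][0])
        label = f"{median:g}"
    else:
        median = None
        label = f"not reached (> {curve.times[-1]:g})"
    return SurvivalSummary(
        median=median,
        median_label=label,
        rate_at_horizon=curve.survival_at(horizon_months),
        horizon=horizon_months,
    )


def compare_strategies(
    cohort: pd.DataFrame,
    risk_group: str,
    factor_col: str = "surgery",
    time_col: str = "rfs_months",
    event_col: str = "event",
    group_col: str = "risk_group",
    horizon_months: float = 24.0,
):
    """AR-vs-NAR comparison within one nomogram risk group.

    Returns ``{level: SurvivalSummary}`` plus the log-rank result under key
    ``"logrank"``; a stratum missing one factor level is skipped (None) with
    a log message.
    """
    stratum = cohort[cohort[group_col] == risk_group]
    levels = stratum[factor_col].unique()
    if len(levels) < 2:
        logger.info(
            "risk group %s: only %s present, AR-vs-NAR comparison skipped",
            risk_group, list(levels),
        )
        return None
    chi2, p = logrank_test(
        stratum[time_col], stratum[event_col], stratum[factor_col]
    )
    out: dict[str, SurvivalSummary] = {}
    for level in sorted(levels):
        arm = stratum[stratum[factor_col] == level]
        curve = km_estimate(arm[time_col], arm[event_col])
        summary = rfs_summary(curve, horizon_months)
        out[str(level)] = SurvivalSummary(
            median=summary.median,
            median_label=summary.median_label,
            rate_at_horizon=summary.rate_at_horizon,
            horizon=summary.horizon,
            logrank_statistic=chi2,
            logrank_p=p,
        )
    out["logrank"] = (chi2, p)
    return out
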