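"""Discrimination, calibration and clinical-utility metrics for risk models.

ROC curves are empirical over the observed score values; the AUC is the
trapezoid integral, which with half-credit for ties equals the normalised
Mann-Whitney U statistic.  AUC confidence intervals and paired model
comparisons use DeLong's placement-value variance.  Operating cutoffs
maximise Youden's J.  Calibration is assessed by the Hosmer-Lemeshow
deciles-of-risk test and binned reliability curves; clinical utility by
decision-curve net benefit NB(pt) = TP/N - (FP/N) * pt / (1 - pt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .perfusion import InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidInputError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class CalibrationResult:
    n_groups: int
    observed: np.ndarray
    expected: np.ndarray
    group_sizes: np.ndarray
    statistic: float
    p_value: float


@dataclass(frozen=True)
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise InvalidInputError("both classes must be present")
    return labels


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Placement values (V10, V01) and AUC for one score vector."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def roc_curve_auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """Empirical ROC with trapezoid AUC and a DeLong-variance Wald CI.

    Subjects with score >= threshold are called positive; thresholds run over
    the unique observed scores (plus +inf for the all-negative corner), so
    tied scores contribute half-credit and the trapezoid AUC equals
    U / (n1 * n0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pos = labels.sum()
    neg = labels.size - pos
    sens = np.array([(scores[labels] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~labels] < t).mean() for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    _, v10, v01 = _delong_components(scores, labels)
    var_pos = v10.var(ddof=1) / pos if pos > 1 else 0.0
    var_neg = v01.var(ddof=1) / neg if neg > 1 else 0.0
    var = var_pos + var_neg
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
    )


def youden_threshold(roc: RocResult) -> tuple[float, float]:
    """Cutoff maximising J = sensitivity + specificity - 1 (ties: smallest).

    Only finite (observed-score) thresholds are candidates.
    """
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise InvalidInputError("degenerate ROC")
    thr = roc.thresholds[finite]
    j = roc.sensitivities[finite] + roc.specificities[finite] - 1.0
    best_j = j.max()
    cutoff = thr[np.isclose(j, best_j)].min()
    return float(cutoff), float(best_j)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong comparison of two AUCs on the same subjects.

    Returns ``(delta_auc, z, p)`` with a two-sided normal p-value.  A zero
    variance of the difference (e.g. identical score vectors) is reported as
    ``z = 0, p = 1`` when the AUCs agree, NaN otherwise.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise InvalidInputError("paired scores must align with labels")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m = v10_a.size
    n = v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        if np.isclose(delta, 0):
            return float(delta), 0.0, 1.0
        logger.warning("DeLong variance of the AUC difference is zero")
        return float(delta), np.nan, np.nan
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(delta), float(z), float(p)


# ---------------------------------------------------------------------------
# Confusion metrics / calibration / decision curves
# ---------------------------------------------------------------------------


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy / sensitivity / specificity / PPV / NPV as % (2 decimals).

    A metric whose denominator is zero is returned as NaN (missing).
    """
    def pct(num, den):
        return round(100.0 * num / den, 2) if den > 0 else float("nan")

    c = counts
    return {
        "accuracy": pct(c.tp + c.tn, c.n),
        "sensitivity": pct(c.tp, c.tp + c.fn),
        "specificity": pct(c.tn, c.tn + c.fp),
        "ppv": pct(c.tp, c.tp + c.fp),
        "npv": pct(c.tn, c.tn + c.fn),
    }


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionCounts:
    """Counts for the rule: positive iff score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


def hosmer_lemeshow(probs, labels, n_groups: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow deciles-of-risk goodness-of-fit test.

    Groups are quantile bins of the predicted probabilities (empty/duplicate
    bins are merged and logged); the statistic is
    sum (O_g - E_g)^2 / (E_g (1 - E_g / n_g)) on chi-square with g - 2 df.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(float)
    if probs.size < n_groups:
        raise InvalidInputError("need at least one observation per group")
    if np.any((probs <= 0) | (probs >= 1)):
        raise InvalidInputError("probabilities must lie in (0, 1)")
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, n_groups + 1)))
    if edges.size - 1 < n_groups:
        logger.info("Hosmer-Lemeshow: merged to %d bins (tied quantiles)", edges.size - 1)
    bins = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, edges.size - 2)
    g = edges.size - 1
    obs = np.zeros(g)
    exp = np.zeros(g)
    sizes = np.zeros(g, dtype=int)
    for i in range(g):
        in_bin = bins == i
        sizes[i] = in_bin.sum()
        obs[i] = labels[in_bin].sum()
        exp[i] = probs[in_bin].sum()
    keep = sizes > 0
    obs, exp, sizes = obs[keep], exp[keep], sizes[keep]
    g = keep.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - exp) ** 2 / (exp * (1 - exp / sizes))
    stat = float(np.nansum(terms))
    df = g - 2
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return CalibrationResult(
        n_groups=int(g), observed=obs, expected=exp, group_sizes=sizes,
        statistic=stat, p_value=p,
    )


def calibration_curve(probs, labels, n_bins: int = 10):
    """Binned reliability pairs: (mean predicted, observed fraction) per bin.

    Quantile bins; returns arrays suitable for plotting against the diagonal.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(float)
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # constant predictions collapse to a single bin
        return np.array([probs.mean()]), np.array([labels.mean()])
    bins = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, edges.size - 2)
    mean_pred, obs_frac = [], []
    for i in range(edges.size - 1):
        in_bin = bins == i
        if not in_bin.any():
            continue
        mean_pred.append(probs[in_bin].mean())
        obs_frac.append(labels[in_bin].mean())
    return np.asarray(mean_pred), np.asarray(obs_frac)


def decision_curve(
    probs, labels, thresholds: np.ndarray | None = None
) -> DecisionCurve:
    """Net benefit of the model vs treat-all / treat-none across thresholds.

    NB(pt) = TP/N - (FP/N) * pt/(1-pt) under the rule "treat if prob >= pt".
    Thresholds default to 0.01..0.99 in steps of 0.01; pt = 1 is excluded.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    n = labels.size
    prev = labels.mean()
    nb = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        pred = probs >= pt
        tp = np.sum(pred & labels) / n
        fp = np.sum(pred & ~labels) / n
        nb[i] = tp - fp * pt / (1 - pt)
    treat_all = prev - (1 - prev) * thresholds / (1 - thresholds)
    return DecisionCurve(
        thresholds=thresholds,
        net_benefit=nb,
        treat_all=treat_all,
        treat_none=np.zeros_like(thresholds),
    )
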