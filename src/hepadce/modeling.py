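"""MVI prediction models: group tests, logistic regression, C_DCE, nomogram.

Model families mirror the clinical analysis: a clinical-radiological (CR)
model from AFP band, corona enhancement and TTPVI; intra-tumoral, peritumoral
and pooled DCE models from the perfusion features; and a combined model on
{AFP, corona, TTPVI, C_DCE}.  Candidate predictors pass a univariate screen
(p < 0.05) before entering each multivariable logistic fit.

``C_DCE`` is the published combined DCE score, the linear predictor of the
two independent perfusion features::

    C_DCE = -10.052 + 0.026 * Ft_T + 0.170 * ART_P

The published point-based nomogram is available as a fixed preset::

    RS = 208 + {0, 14, 33}_AFP + 19*corona + 18*TTPVI + 11*C_DCE

with AFP bands <=20 / 20-400 / >400 ng/mL, high-risk (HMVI) defined by
RS > 232.3, and a logistic points-to-probability mapping calibrated on two
published worked examples (RS 258.948 -> 0.989, RS 208.228 -> 0.009).
A nomogram can also be rebuilt from any fitted combined model by the standard
0-100 point scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .perfusion import InvalidInputError

logger = logging.getLogger(__name__)

# Published C_DCE coefficients (intercept, Ft_T, ART_P).
CDCE_INTERCEPT = -10.052
CDCE_FT_T_COEF = 0.026
CDCE_ART_P_COEF = 0.170

#: AFP band labels in banding order: 0 = <=20, 1 = 20-400, 2 = >400 ng/mL.
AFP_BAND_LABELS = ("<=20", "20-400", ">400")

#: Published worked examples (risk score, MVI probability) used to calibrate
#: the preset points-to-probability mapping.
PRESET_CALIBRATION_PAIRS = ((258.948, 0.989), (208.228, 0.009))


def afp_band(afp_ng_ml: float) -> int:
    """AFP band index: 0 for <=20, 1 for (20, 400], 2 for >400 ng/mL."""
    if not np.isfinite(afp_ng_ml) or afp_ng_ml < 0:
        raise InvalidInputError("AFP must be a non-negative number")
    if afp_ng_ml <= 20:
        return 0
    if afp_ng_ml <= 400:
        return 1
    return 2


def compute_cdce(ft_t, art_p):
    """Combined DCE score from total tumoral flow and peritumoral ART.

    Vectorised; missing inputs propagate to a missing output.
    """
    return CDCE_INTERCEPT + CDCE_FT_T_COEF * np.asarray(ft_t) + (
        CDCE_ART_P_COEF * np.asarray(art_p)
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str  # "mann-whitney" | "chi-square" | "fisher" | "t" | "skipped"
    statistic: float
    p_value: float
    reason: str | None = None


def compare_groups(
    df: pd.DataFrame,
    variable: str,
    group_col: str = "mvi",
    continuous: bool | None = None,
) -> GroupComparison:
    """Two-group comparison of one variable between MVI-positive/negative.

    Continuous variables use the two-sided Mann-Whitney U test (exact when
    both groups have <= 20 untied observations, normal approximation
    otherwise), matching median/IQR reporting of skewed perfusion features.
    Categorical variables use chi-square with Fisher's exact fallback when a
    2x2 table has any expected count below 5.  Constant variables are skipped
    with a reason rather than tested.
    """
    groups = df[group_col].astype(bool)
    x = df.loc[groups, variable]
    y = df.loc[~groups, variable]
    if len(x) == 0 or len(y) == 0:
        raise InvalidInputError("both groups must be non-empty")
    values = df[variable]
    if values.nunique(dropna=True) <= 1:
        return GroupComparison(variable, "skipped", np.nan, np.nan, "constant variable")
    if continuous is None:
        continuous = pd.api.types.is_float_dtype(values) or values.nunique() > 5

    if continuous:
        xv, yv = x.dropna().to_numpy(float), y.dropna().to_numpy(float)
        pooled = np.concatenate([xv, yv])
        exact = max(len(xv), len(yv)) <= 20 and np.unique(pooled).size == pooled.size
        res = stats.mannwhitneyu(
            xv, yv, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return GroupComparison(variable, "mann-whitney", float(res.statistic), float(res.pvalue))

    table = pd.crosstab(df[variable], groups).to_numpy()
    chi2, p, _, expected = stats.chi2_contingency(table)
    if (expected < 5).any():
        if table.shape == (2, 2):
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            return GroupComparison(variable, "fisher", float(odds), float(p))
        logger.info("%s: expected counts < 5 in a %sx%s table; chi-square kept",
                    variable, *table.shape)
    return GroupComparison(variable, "chi-square", float(chi2), float(p))


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """A fitted logistic regression with named coefficients."""

    variables: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    converged: bool
    separation: bool = False
    cov_params: pd.DataFrame | None = None

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.intercept, dtype=float)
        for name in self.variables:
            eta += self.coefficients[name] * X[name].to_numpy(float)
        return eta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))

    def standard_errors(self) -> dict[str, float]:
        if self.cov_params is None:
            raise InvalidInputError("covariance not available")
        se = np.sqrt(np.diag(self.cov_params))
        return dict(zip(self.cov_params.columns, se))


def fit_logistic(X: pd.DataFrame, y, tol: float = 1e-10, maxiter: int = 100) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS.

    Fits a binomial GLM with logit link (statsmodels; iteratively reweighted
    least squares).  Complete or quasi-complete separation is detected from
    fitted probabilities saturating at the observed classes or diverging
    coefficient norms, and returned as a flagged model rather than silently.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise InvalidInputError("outcome must be binary 0/1")
    if X.shape[1] > 0 and (X.nunique() <= 1).any():
        raise InvalidInputError("constant predictor column")
    design = sm.add_constant(X.astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                tol=tol, maxiter=maxiter
            )
        except PerfectSeparationError:
            separation = True
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                tol=tol, maxiter=25
            )
    params = fit.params
    probs = fit.predict(design)
    if np.max(np.abs(params.to_numpy())) > 50 or np.all(
        np.abs(probs - y) < 1e-6
    ):
        separation = True
    if separation:
        logger.warning("logistic fit flagged: separation detected")
    names = tuple(X.columns)
    return LogisticModel(
        variables=names,
        coefficients={n: float(params[n]) for n in names},
        intercept=float(params["const"]),
        converged=bool(fit.converged) and not separation,
        separation=separation,
        cov_params=fit.cov_params(),
    )


# ---------------------------------------------------------------------------
# Nomogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Nomogram:
    """Point-based representation of the combined MVI model.

    ``afp_points`` are the increments for the three AFP bands; ``cdce_slope``
    is points per unit C_DCE.  ``prob_slope``/``prob_intercept`` define the
    logit-linear points-to-probability mapping p = expit(a + b * RS).
    ``calibration`` records how that mapping was obtained.
    """

    baseline_points: float = 208.0
    afp_points: tuple[float, float, float] = (0.0, 14.0, 33.0)
    corona_points: float = 19.0
    ttpvi_points: float = 18.0
    cdce_slope: float = 11.0
    risk_cutoff: float = 232.3
    prob_slope: float | None = None
    prob_intercept: float | None = None
    calibration: str = "uncalibrated"

    def as_dict(self) -> dict:
        return {
            "baseline_points": self.baseline_points,
            "afp_points": list(self.afp_points),
            "corona_points": self.corona_points,
            "ttpvi_points": self.ttpvi_points,
            "cdce_slope": self.cdce_slope,
            "risk_cutoff": self.risk_cutoff,
            "prob_slope": self.prob_slope,
            "prob_intercept": self.prob_intercept,
            "calibration": self.calibration,
        }


def _two_point_logit_solve(pairs) -> tuple[float, float]:
    (rs1, p1), (rs2, p2) = pairs
    logit = lambda p: np.log(p / (1 - p))
    b = (logit(p1) - logit(p2)) / (rs1 - rs2)
    a = logit(p1) - b * rs1
    return float(a), float(b)


def preset_nomogram() -> Nomogram:
    """The published nomogram with its preset-derived probability mapping."""
    a, b = _two_point_logit_solve(PRESET_CALIBRATION_PAIRS)
    return Nomogram(prob_slope=b, prob_intercept=a, calibration="preset-derived")


def nomogram_points(
    nomo: Nomogram,
    afp_band_idx: int,
    corona: bool,
    ttpvi: bool,
    c_dce: float,
):
    """Total risk score (unrounded); report ``round()`` of it for display."""
    afp_band_idx = np.asarray(afp_band_idx)
    if np.any((afp_band_idx < 0) | (afp_band_idx > 2)):
        raise InvalidInputError("unknown AFP band")
    afp_pts = np.asarray(nomo.afp_points)[afp_band_idx]
    rs = (
        nomo.baseline_points
        + afp_pts
        + nomo.corona_points * np.asarray(corona, dtype=float)
        + nomo.ttpvi_points * np.asarray(ttpvi, dtype=float)
        + nomo.cdce_slope * np.asarray(c_dce, dtype=float)
    )
    return rs if rs.ndim else float(rs)


def points_to_probability(nomo: Nomogram, rs):
    """Predicted MVI probability for a risk score via the calibrated mapping."""
    if nomo.prob_slope is None or nomo.prob_intercept is None:
        raise InvalidInputError("nomogram probability mapping not calibrated")
    eta = nomo.prob_intercept + nomo.prob_slope * np.asarray(rs, dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    return p if p.ndim else float(p)


def stratify_risk(rs, cutoff: float = 232.3):
    """HMVI iff RS strictly exceeds the cutoff, else LMVI."""
    rs = np.asarray(rs, dtype=float)
    out = np.where(rs > cutoff, "HMVI", "LMVI")
    return out if out.ndim else str(out)


def preset_combined_coefficients(nomo: Nomogram | None = None) -> dict[str, float]:
    """Logistic coefficients implied by the preset nomogram's point scale.

    With p = expit(a + b*RS) and RS linear in the predictors, each predictor's
    logistic coefficient is b times its point increment; the intercept is
    a + b * baseline points.
    """
    nomo = nomo or preset_nomogram()
    b = nomo.prob_slope
    return {
        "intercept": nomo.prob_intercept + b * nomo.baseline_points,
        "afp_band_1": b * nomo.afp_points[1],
        "afp_band_2": b * nomo.afp_points[2],
        "corona": b * nomo.corona_points,
        "ttpvi": b * nomo.ttpvi_points,
        "c_dce": b * nomo.cdce_slope,
    }


def nomogram_from_model(
    model: LogisticModel, X: pd.DataFrame, risk_cutoff: float | None = None
) -> Nomogram:
    """Rebuild a nomogram from a fitted combined model by 0-100 scaling.

    The predictor with the largest |coefficient| x observed range spans 100
    points; every coefficient maps to points at the common scale, AFP dummies
    are folded into the band increments, and the probability mapping follows
    exactly from the model (b = 1/scale).
    """
    required = {"afp_band_1", "afp_band_2", "corona", "ttpvi", "c_dce"}
    if set(model.variables) != required:
        raise InvalidInputError("combined model must use the standard predictors")
    ranges = {
        name: float(X[name].max() - X[name].min()) or 1.0 for name in model.variables
    }
    span = max(abs(model.coefficients[n]) * ranges[n] for n in model.variables)
    scale = 100.0 / span  # points per logit
    pts = {n: model.coefficients[n] * scale for n in model.variables}
    baseline = 100.0  # display origin; the probability mapping absorbs it
    b = 1.0 / scale
    a = model.intercept - b * baseline
    nomo = Nomogram(
        baseline_points=baseline,
        afp_points=(0.0, pts["afp_band_1"], pts["afp_band_2"]),
        corona_points=pts["corona"],
        ttpvi_points=pts["ttpvi"],
        cdce_slope=pts["c_dce"],
        risk_cutoff=risk_cutoff if risk_cutoff is not None else 232.3,
        prob_slope=b,
        prob_intercept=a,
        calibration="refit",
    )
    return nomo


# ---------------------------------------------------------------------------
# Cohort split and model suite
# ---------------------------------------------------------------------------


def stratified_split(
    df: pd.DataFrame, ratio: float = 0.7, seed: int = 0, label_col: str = "mvi"
) -> pd.Series:
    """Random 'training'/'validation' assignment stratified by the label."""
    if not 0 < ratio < 1:
        raise InvalidInputError("split ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split = pd.Series("validation", index=df.index, dtype=object)
    for _, idx in df.groupby(df[label_col].astype(bool)).groups.items():
        idx = np.asarray(idx)
        n_train = int(round(ratio * idx.size))
        chosen = rng.choice(idx, size=n_train, replace=False)
        split.loc[chosen] = "training"
    return split


def combined_design(df: pd.DataFrame) -> pd.DataFrame:
    """Design matrix for the combined model: AFP dummies, corona, TTPVI, C_DCE."""
    return pd.DataFrame(
        {
            "afp_band_1": (df["afp_band"] == 1).astype(float),
            "afp_band_2": (df["afp_band"] == 2).astype(float),
            "corona": df["corona"].astype(float),
            "ttpvi": df["ttpvi"].astype(float),
            "c_dce": df["c_dce"].astype(float),
        },
        index=df.index,
    )


INTRA_FEATURES = tuple(f"{p}_T" for p in ("ART", "Fa", "Fp", "Ft", "DV", "MTT"))
PERI_FEATURES = tuple(f"{p}_P" for p in ("ART", "Fa", "Fp", "Ft", "DV", "MTT"))
CR_FEATURES = ("afp_band", "corona", "ttpvi")


@dataclass
class ModelSuite:
    """The five logistic model families plus the nomogram."""

    screens: dict[str, list[GroupComparison]]
    models: dict[str, LogisticModel | None]
    cdce_model: LogisticModel | None
    nomogram: Nomogram

    def predict_proba(self, name: str, df: pd.DataFrame) -> np.ndarray:
        model = self.models[name]
        if model is None:
            raise InvalidInputError(f"model family '{name}' was skipped")
        if name == "combined":
            X = combined_design(df)
        else:
            X = _design_columns(df, model.variables)
        return model.predict_proba(X)


def _screen(df: pd.DataFrame, candidates, alpha: float) -> tuple[list, list]:
    comps = []
    selected = []
    for var in candidates:
        continuous = var not in CR_FEATURES
        comp = compare_groups(df, var, continuous=continuous)
        comps.append(comp)
        if np.isfinite(comp.p_value) and comp.p_value < alpha:
            selected.append(var)
    return comps, selected


def _family_design(df: pd.DataFrame, variables) -> pd.DataFrame:
    cols = {}
    for var in variables:
        if var == "afp_band":
            cols["afp_band_1"] = (df["afp_band"] == 1).astype(float)
            cols["afp_band_2"] = (df["afp_band"] == 2).astype(float)
        else:
            cols[var] = df[var].astype(float)
    return pd.DataFrame(cols, index=df.index)


def _design_columns(df: pd.DataFrame, variables) -> pd.DataFrame:
    """Resolve fitted design columns (incl. AFP dummies) from a cohort table."""
    cols = {}
    for name in variables:
        if name == "afp_band_1":
            cols[name] = (df["afp_band"] == 1).astype(float)
        elif name == "afp_band_2":
            cols[name] = (df["afp_band"] == 2).astype(float)
        else:
            cols[name] = df[name].astype(float)
    return pd.DataFrame(cols, index=df.index)


def build_model_suite(
    train: pd.DataFrame,
    alpha: float = 0.05,
    nomogram_mode: str = "preset",
) -> ModelSuite:
    """Screen predictors and fit the CR / intra / peri / DCE / combined models.

    Each family's candidates pass a univariate screen at ``alpha``; a family
    with no significant candidate is skipped with a log message.  ``C_DCE``
    is recomputed from the DCE family's fitted linear predictor when that
    family converges, otherwise from the published coefficients already in
    the ``c_dce`` column.  ``nomogram_mode`` selects the published preset
    ("preset") or a rebuild from the fitted combined model ("refit").
    """
    if train.empty or train["mvi"].nunique() < 2:
        raise InvalidInputError("training split must contain both classes")
    y = train["mvi"].astype(float).to_numpy()
    screens: dict[str, list[GroupComparison]] = {}
    models: dict[str, LogisticModel | None] = {}

    families = {
        "cr": CR_FEATURES,
        "intra": INTRA_FEATURES,
        "peri": PERI_FEATURES,
        "dce": INTRA_FEATURES + PERI_FEATURES,
    }
    for name, candidates in families.items():
        comps, selected = _screen(train, candidates, alpha)
        screens[name] = comps
        if not selected:
            logger.info("model family '%s': no significant candidates, skipped", name)
            models[name] = None
            continue
        models[name] = fit_logistic(_family_design(train, selected), y)

    cdce_model = models.get("dce")
    work = train.copy()
    if cdce_model is not None and cdce_model.converged:
        X_dce = work[list(cdce_model.variables)].astype(float)
        work["c_dce"] = cdce_model.linear_predictor(X_dce)
    elif "c_dce" not in work:
        raise InvalidInputError("no DCE model and no precomputed c_dce column")

    comps, selected = _screen(
        work, ("afp_band", "corona", "ttpvi", "c_dce"), alpha
    )
    screens["combined"] = comps
    if not selected:
        logger.info("combined family: no significant candidates, skipped")
        models["combined"] = None
    else:
        models["combined"] = fit_logistic(combined_design(work), y)

    if nomogram_mode == "preset" or models["combined"] is None:
        nomo = preset_nomogram()
    elif nomogram_mode == "refit":
        nomo = nomogram_from_model(models["combined"], combined_design(work))
    else:
        raise InvalidInputError("nomogram_mode must be 'preset' or 'refit'")
    return ModelSuite(screens=screens, models=models, cdce_model=cdce_model, nomogram=nomo)
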