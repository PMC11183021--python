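"""Intra-/peritumoral region construction, feature aggregation and agreement.

The peritumoral region is the shell of liver tissue within a fixed physical
distance (default 10 mm) of the tumor margin: voxels whose Euclidean distance
to the tumor is at most the radius, excluding the tumor itself and clipped to
the liver mask.  Distances are computed in millimetres so anisotropic voxel
spacing is honoured, and the dilation is 3-D.

Per-patient features are the means of the six perfusion parameter maps over
each region ("-T" intra-tumoral, "-P" peritumoral); measurements from two
readers are averaged.  Inter-observer agreement uses ICC(2,1) (two-way random
effects, absolute agreement, single measures) for continuous features and
Cohen's kappa for categorical ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .perfusion import PARAM_NAMES, InvalidInputError

logger = logging.getLogger(__name__)

#: Feature order used throughout: six parameters x {tumoral, peritumoral}.
FEATURE_NAMES = tuple(f"{p}_T" for p in PARAM_NAMES) + tuple(
    f"{p}_P" for p in PARAM_NAMES
)


@dataclass(frozen=True)
class MaskSet:
    """Liver / tumor / peritumoral binary volumes on a shared grid."""

    liver: np.ndarray
    tumor: np.ndarray
    peritumoral: np.ndarray | None
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        liver = np.asarray(self.liver, dtype=bool)
        tumor = np.asarray(self.tumor, dtype=bool)
        if tumor.shape != liver.shape:
            raise InvalidInputError("masks must share one grid")
        if np.any(tumor & ~liver):
            raise InvalidInputError("tumor must lie within the liver")
        peri = self.peritumoral
        if peri is not None:
            peri = np.asarray(peri, dtype=bool)
            if peri.shape != liver.shape:
                raise InvalidInputError("masks must share one grid")
            if np.any(peri & tumor):
                raise InvalidInputError("peritumoral region overlaps tumor")
            if np.any(peri & ~liver):
                raise InvalidInputError("peritumoral region outside liver")
        object.__setattr__(self, "liver", liver)
        object.__setattr__(self, "tumor", tumor)
        object.__setattr__(self, "peritumoral", peri)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))


@dataclass(frozen=True)
class BiRegionalFeatures:
    """Twelve per-patient features: parameter means suffixed _T and _P."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(FEATURE_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown feature names: {sorted(unknown)}")

    def get(self, name: str) -> float:
        return self.values.get(name, np.nan)

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values.get(k, np.nan) for k in FEATURE_NAMES})


@dataclass(frozen=True)
class AgreementResult:
    """Inter-observer agreement statistic with its 95% CI."""

    statistic: str  # "ICC" or "kappa"
    estimate: float
    ci_low: float
    ci_high: float
    flagged: bool = False
    reason: str | None = None


# ---------------------------------------------------------------------------
# Region construction and aggregation
# ---------------------------------------------------------------------------


def dilate_peritumoral_mask(
    tumor: np.ndarray,
    liver: np.ndarray,
    spacing_mm: tuple[float, float, float],
    radius_mm: float = 10.0,
) -> np.ndarray:
    """Peritumoral shell: liver voxels within ``radius_mm`` of the tumor.

    Uses a physical-distance Euclidean transform (anisotropic spacing
    respected); the tumor itself is excluded and the result clipped to the
    liver, so the shell never extends past the organ boundary.
    """
    tumor = np.asarray(tumor, dtype=bool)
    liver = np.asarray(liver, dtype=bool)
    if radius_mm <= 0:
        raise InvalidInputError("radius must be positive")
    if not tumor.any():
        raise InvalidInputError("empty tumor mask")
    dist = ndimage.distance_transform_edt(~tumor, sampling=spacing_mm)
    return (dist <= radius_mm) & ~tumor & liver


def aggregate_roi_means(
    maps: dict[str, np.ndarray], masks: MaskSet
) -> BiRegionalFeatures:
    """Mean of each parameter map over the tumoral and peritumoral regions.

    Only valid (finite) voxels enter each mean; a region with zero valid
    voxels yields a missing (NaN) feature.  The fraction of missing voxels is
    logged per region.
    """
    if masks.peritumoral is None:
        raise InvalidInputError("mask set lacks a peritumoral region")
    values: dict[str, float] = {}
    for region, suffix in ((masks.tumor, "T"), (masks.peritumoral, "P")):
        if not region.any():
            raise InvalidInputError("empty region in mask set")
        for name in PARAM_NAMES:
            vox = np.asarray(maps[name])[region]
            good = np.isfinite(vox)
            if not good.any():
                values[f"{name}_{suffix}"] = np.nan
                continue
            missing = 1.0 - good.mean()
            if missing:
                logger.info(
                    "%s_%s: %.1f%% voxels missing in region", name, suffix, 100 * missing
                )
            values[f"{name}_{suffix}"] = float(vox[good].mean())
    return BiRegionalFeatures(values)


def average_observers(
    obs1: BiRegionalFeatures,
    obs2: BiRegionalFeatures,
    policy: str = "use_available",
) -> BiRegionalFeatures:
    """Element-wise mean of two readers' feature sets.

    With ``policy="use_available"`` (default) a value missing for one reader
    falls back to the other's (logged); ``policy="strict"`` propagates the
    missing value.  Missing on both sides stays missing.
    """
    out: dict[str, float] = {}
    for name in FEATURE_NAMES:
        a, b = obs1.get(name), obs2.get(name)
        if np.isfinite(a) and np.isfinite(b):
            out[name] = 0.5 * (a + b)
        elif policy == "use_available" and (np.isfinite(a) or np.isfinite(b)):
            out[name] = a if np.isfinite(a) else b
            logger.info("feature %s available from one reader only", name)
        else:
            out[name] = np.nan
    return BiRegionalFeatures(out)


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------


def icc_two_way(ratings: np.ndarray, alpha: float = 0.05) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is an (n subjects, k raters) table.  The point estimate comes
    from the mean-squares decomposition and the CI from the F-based interval
    with Satterthwaite degrees of freedom (Shrout & Fleiss case 2; McGraw &
    Wong ICC(A,1)).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidInputError("need >= 2 subjects and >= 2 raters")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return AgreementResult("ICC", np.nan, np.nan, np.nan, True, "zero total variance")
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    # F-based CI with interpolated df (McGraw & Wong, 1996)
    if mse <= 0:
        return AgreementResult("ICC", float(icc), float(icc), float(icc))
    fj = msc / mse
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return AgreementResult("ICC", float(icc), float(icc), float(icc))
    v_num = (a * fj + b) ** 2
    v_den = a**2 * fj**2 / (k - 1) + b**2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return AgreementResult("ICC", float(icc), float(lower), float(upper))


def cohens_kappa(labels1, labels2, alpha: float = 0.05) -> AgreementResult:
    """Cohen's kappa for two raters: (po - pe) / (1 - pe).

    ``pe`` is the chance agreement from the marginal products.  Undefined
    (flagged) when both raters are constant with the same value (pe = 1).
    The CI is the standard large-sample Wald interval.
    """
    a = np.asarray(labels1)
    b = np.asarray(labels2)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("label vectors must be 1-D and equal length")
    n = a.size
    if n == 0:
        raise InvalidInputError("empty label vectors")
    cats = np.union1d(a, b)
    po = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    pe = float(np.sum(pa * pb))
    if pe >= 1.0:
        return AgreementResult("kappa", np.nan, np.nan, np.nan, True, "pe = 1")
    kappa = (po - pe) / (1 - pe)
    se = np.sqrt(po * (1 - po) / n) / (1 - pe)
    z = stats.norm.ppf(1 - alpha / 2)
    return AgreementResult(
        "kappa", float(kappa), float(max(-1.0, kappa - z * se)),
        float(min(1.0, kappa + z * se)),
    )
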