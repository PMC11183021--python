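"""Dual-input single-compartment hepatic perfusion quantification from DCE-MRI.

The liver receives blood from both the hepatic artery and the portal vein, so
tissue enhancement is modelled with two vascular input functions feeding a
single well-mixed tissue compartment::

    dCt/dt = fa * Ca(t - tau_a) + fp * Cp(t - tau_p) - k2 * Ct(t),   Ct(0) = 0

where ``Ca``/``Cp`` are the arterial and portal-venous tracer concentrations
(mM), ``fa``/``fp`` the arterial and portal-venous plasma flows per unit tissue
volume (1/s, i.e. mL blood / s / mL tissue) and ``k2`` the efflux rate (1/s).
The six reported parameters follow from the fitted rates (tissue density is
taken as 1 g/mL so "per 100 g" and "per 100 mL" coincide):

=====  =============================  =========================
ART    arterial fraction              100 * Fa / Ft        (%)
Fa     arterial flow                  6000 * fa   (mL/min/100 g)
Fp     portal-venous flow             6000 * fp   (mL/min/100 g)
Ft     total flow                     Fa + Fp     (mL/min/100 g)
DV     distribution volume            100 * (fa + fp) / k2 (%)
MTT    mean transit time              1 / k2 = 60 * DV / Ft (s)
=====  =============================  =========================

Baseline T1 is estimated voxel-wise from variable-flip-angle (VFA) spoiled
gradient-echo (SPGR) acquisitions, the dynamic signal is converted to tracer
concentration by full SPGR inversion, and the kinetic parameters are fitted by
bounded nonlinear least squares with an exact (piecewise-linear-input)
convolution forward model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Names of the six perfusion parameters, in reporting order.
PARAM_NAMES = ("ART", "Fa", "Fp", "Ft", "DV", "MTT")

#: mL/min/100 g  ->  mL/s/mL tissue (density 1 g/mL).
FLOW_SCALE = 6000.0


class InvalidInputError(ValueError):
    """Raised when an operation receives input violating its contract."""


class InsufficientDataError(InvalidInputError):
    """Raised when too few observations are available for an estimate."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputFunctions:
    """Arterial and portal-venous concentration-time curves on a shared grid.

    Parameters
    ----------
    time_s : array
        Sample times in seconds, strictly increasing.
    ca_mM, cp_mM : array
        Arterial / portal-venous tracer concentration (mM), non-negative.
    """

    time_s: np.ndarray
    ca_mM: np.ndarray
    cp_mM: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        ca = np.asarray(self.ca_mM, dtype=float)
        cp = np.asarray(self.cp_mM, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise InvalidInputError("time grid must be 1-D with >= 2 samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time grid must be strictly increasing")
        if ca.shape != t.shape or cp.shape != t.shape:
            raise InvalidInputError("input curves must match the time grid")
        if np.any(ca < -1e-12) or np.any(cp < -1e-12):
            raise InvalidInputError("concentrations must be non-negative")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "ca_mM", ca)
        object.__setattr__(self, "cp_mM", cp)


@dataclass(frozen=True)
class PerfusionParams:
    """The six dual-input perfusion parameters (reporting units).

    ``art`` %, ``fa``/``fp``/``ft`` mL/min/100 g, ``dv`` %, ``mtt`` s.
    ``art`` and ``mtt`` are NaN when ``ft == 0`` (undefined).
    """

    art: float
    fa: float
    fp: float
    ft: float
    dv: float
    mtt: float

    @classmethod
    def from_flows(cls, fa: float, fp: float, dv: float) -> "PerfusionParams":
        """Build from flows (mL/min/100 g) and distribution volume (%)."""
        ft, art, dv_out, mtt = derive_secondary_params(
            fa, fp, k2_from_flows(fa, fp, dv)
        )
        return cls(art=art, fa=fa, fp=fp, ft=ft, dv=dv, mtt=mtt)

    @classmethod
    def from_rates(cls, fa_s: float, fp_s: float, k2_s: float) -> "PerfusionParams":
        """Build from kinetic rates in 1/s (``fa_s``, ``fp_s`` flows per mL)."""
        fa = fa_s * FLOW_SCALE
        fp = fp_s * FLOW_SCALE
        ft, art, dv, mtt = derive_secondary_params(fa, fp, k2_s)
        return cls(art=art, fa=fa, fp=fp, ft=ft, dv=dv, mtt=mtt)

    def rates(self) -> tuple[float, float, float]:
        """Return ``(fa_s, fp_s, k2_s)`` in 1/s."""
        fa_s = self.fa / FLOW_SCALE
        fp_s = self.fp / FLOW_SCALE
        if self.dv <= 0:
            raise InvalidInputError("DV must be positive to derive k2")
        k2_s = (fa_s + fp_s) / (self.dv / 100.0)
        return fa_s, fp_s, k2_s

    def as_dict(self) -> dict[str, float]:
        return {
            "ART": self.art,
            "Fa": self.fa,
            "Fp": self.fp,
            "Ft": self.ft,
            "DV": self.dv,
            "MTT": self.mtt,
        }


@dataclass(frozen=True)
class VfaSet:
    """Multi-flip-angle SPGR magnitude volumes for T1 mapping."""

    volumes: np.ndarray  # (n_angles, *spatial)
    flip_angles_deg: np.ndarray
    tr_ms: float

    def __post_init__(self) -> None:
        vols = np.asarray(self.volumes, dtype=float)
        angles = np.asarray(self.flip_angles_deg, dtype=float)
        if angles.ndim != 1 or np.unique(angles).size < 2:
            raise InsufficientDataError("need >= 2 distinct flip angles")
        if vols.shape[0] != angles.size:
            raise InvalidInputError("one volume per flip angle required")
        object.__setattr__(self, "volumes", vols)
        object.__setattr__(self, "flip_angles_deg", angles)


@dataclass(frozen=True)
class DynamicSeries:
    """4-D dynamic magnitude series (time first) with acquisition metadata."""

    data: np.ndarray  # (n_frames, *spatial)
    times_s: np.ndarray
    flip_angle_deg: float
    tr_ms: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        t = np.asarray(self.times_s, dtype=float)
        if t.ndim != 1 or t.size != data.shape[0]:
            raise InvalidInputError("one frame time per dynamic frame required")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("frame times must be strictly increasing")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times_s", t)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class T1M0Map:
    """Voxel-wise baseline T1 (ms) and equilibrium signal M0 with validity."""

    t1_ms: np.ndarray
    m0: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class ConversionConfig:
    """Signal-to-concentration conversion settings.

    ``r1_relaxivity`` in 1/s/mM (gadolinium r1 at field strength; default 4.5),
    ``n_baseline`` pre-contrast frames used to anchor M0, and the tissue
    density assumption (g/mL) making flow-per-100g equal flow-per-100mL.
    """

    r1_relaxivity: float = 4.5
    n_baseline: int = 3
    density_g_per_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.r1_relaxivity <= 0:
            raise InvalidInputError("relaxivity must be positive")
        if self.n_baseline < 1:
            raise InvalidInputError("need >= 1 baseline frame")


# ---------------------------------------------------------------------------
# SPGR signal model and T1 mapping
# ---------------------------------------------------------------------------


def spgr_signal(t1_ms, m0, flip_deg: float, tr_ms: float):
    """Steady-state SPGR magnitude: S = M0 sin(a) (1-E1) / (1 - E1 cos(a))."""
    t1_ms = np.asarray(t1_ms, dtype=float)
    alpha = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def fit_t1_vfa(vfa: VfaSet) -> T1M0Map:
    """Voxel-wise T1/M0 from VFA SPGR signals via the linearised fit.

    Writing y = S/sin(a) and x = S/tan(a), the SPGR equation becomes
    y = E1 * x + M0 (1 - E1), a straight line whose slope is E1 = exp(-TR/T1).
    Voxels with a non-physical slope (E1 <= 0 or >= 1) or non-positive
    intercept are flagged invalid.
    """
    angles = np.deg2rad(vfa.flip_angles_deg)
    vols = vfa.volumes
    spatial = vols.shape[1:]
    s = vols.reshape(vols.shape[0], -1)
    if np.any(s < 0):
        raise InvalidInputError("SPGR magnitudes must be non-negative")

    y = s / np.sin(angles)[:, None]
    x = s / np.tan(angles)[:, None]
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, np.nan)
        intercept = ym - slope * xm
        valid = (slope > 0) & (slope < 1) & (intercept > 0)
        t1 = np.where(valid, -vfa.tr_ms / np.log(slope), np.nan)
        m0 = np.where(valid, intercept / (1.0 - slope), np.nan)
    n_invalid = int(np.sum(~valid))
    if n_invalid:
        logger.info("T1 mapping: %d/%d voxels flagged non-physical", n_invalid, s.shape[1])
    return T1M0Map(
        t1_ms=t1.reshape(spatial),
        m0=m0.reshape(spatial),
        valid=valid.reshape(spatial),
    )


def signal_to_concentration(
    dyn: DynamicSeries, t1m0: T1M0Map, cfg: ConversionConfig | None = None
) -> np.ndarray:
    """Convert the dynamic SPGR series to tracer concentration (mM).

    Per voxel the equilibrium signal is re-anchored on the mean pre-contrast
    signal together with the mapped baseline T1 (this absorbs scaling
    differences between the VFA and dynamic acquisitions), the SPGR equation
    is inverted frame-wise for R1(t), and

        C(t) = (R1(t) - R1(0)) / r1 .

    Invalid T1 voxels and frames whose signal cannot arise from a physical E1
    are returned as NaN (missing), never as zero.
    """
    cfg = cfg or ConversionConfig()
    alpha = np.deg2rad(dyn.flip_angle_deg)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    tr_s = dyn.tr_ms / 1000.0

    t1 = t1m0.t1_ms
    valid = t1m0.valid & np.isfinite(t1) & (t1 > 0)
    if cfg.n_baseline > dyn.n_frames:
        raise InvalidInputError("more baseline frames than dynamic frames")

    s = dyn.data
    s0 = s[: cfg.n_baseline].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1b = np.exp(-dyn.tr_ms / t1)
        m0_eff = s0 * (1.0 - e1b * cos_a) / (sin_a * (1.0 - e1b))
        sp = s / (m0_eff * sin_a)[None]
        e1 = (1.0 - sp) / (1.0 - sp * cos_a)
        ok = valid[None] & (e1 > 0) & (e1 < 1) & (m0_eff > 0)[None]
        r1 = np.where(ok, -np.log(np.where(ok, e1, 0.5)) / tr_s, np.nan)
        r1_0 = 1000.0 / t1
        conc = (r1 - r1_0[None]) / cfg.r1_relaxivity
    conc[:, ~valid] = np.nan
    return conc


# ---------------------------------------------------------------------------
# Forward kinetic model
# ---------------------------------------------------------------------------


def _expconv(k: float, t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Exact solution of y' = x(t) - k*y, y(0)=0, for piecewise-linear x.

    Integrating the exponential kernel analytically over each interval keeps
    the forward model free of quadrature error on coarse dynamic grids.
    """
    y = np.zeros_like(x)
    dt = np.diff(t)
    if k * dt.max() < 1e-12:  # k -> 0 limit: pure integration
        y[1:] = np.cumsum(0.5 * dt * (x[:-1] + x[1:]))
        return y
    e = np.exp(-k * dt)
    # linear segment x_i + (dx/dt)*s convolved with the exponential kernel:
    # contribution = x_i*c0 + dx*c1 with the closed forms below
    c0 = (1.0 - e) / k
    c1 = (1.0 - c0 / dt) / k
    for i in range(dt.size):
        y[i + 1] = y[i] * e[i] + x[i] * c0[i] + (x[i + 1] - x[i]) * c1[i]
    return y


def _shift_curve(t: np.ndarray, c: np.ndarray, delay_s: float) -> np.ndarray:
    """Delay a curve by linear interpolation; zero before the grid start."""
    if delay_s == 0.0:
        return c
    return np.interp(t - delay_s, t, c, left=0.0, right=c[-1])


def simulate_tissue_curve(
    params: PerfusionParams,
    inputs: InputFunctions,
    delay_a_s: float = 0.0,
    delay_p_s: float = 0.0,
) -> np.ndarray:
    """Tissue concentration (mM) predicted by the dual-input model."""
    if delay_a_s < 0 or delay_p_s < 0:
        raise InvalidInputError("delays before the grid start are not supported")
    fa_s, fp_s, k2_s = params.rates()
    t = inputs.time_s
    x = fa_s * _shift_curve(t, inputs.ca_mM, delay_a_s) + fp_s * _shift_curve(
        t, inputs.cp_mM, delay_p_s
    )
    return _expconv(k2_s, t, x)


def k2_from_flows(fa: float, fp: float, dv: float) -> float:
    """Efflux rate (1/s) implied by flows (mL/min/100 g) and DV (%)."""
    if dv <= 0:
        raise InvalidInputError("DV must be positive")
    return ((fa + fp) / FLOW_SCALE) / (dv / 100.0)


def derive_secondary_params(fa: float, fp: float, k2_s: float):
    """Derive (Ft, ART, DV, MTT) from flows (mL/min/100 g) and k2 (1/s).

    Identities: Ft = Fa + Fp; ART = 100 Fa / Ft; DV = 100 (fa+fp)/k2 with
    rates in 1/s; MTT = 1/k2 = 60 DV / Ft.  ART and MTT are NaN at Ft = 0.
    """
    if fa < 0 or fp < 0:
        raise InvalidInputError("flows must be non-negative")
    if k2_s <= 0:
        raise InvalidInputError("k2 must be positive")
    ft = fa + fp
    if ft == 0:
        return 0.0, np.nan, 0.0, np.nan
    art = 100.0 * fa / ft
    dv = 100.0 * (ft / FLOW_SCALE) / k2_s
    mtt = 60.0 * dv / ft
    return ft, art, dv, mtt


# ---------------------------------------------------------------------------
# Voxel fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitOptions:
    """Bounds, starting points and behaviour of the voxel-wise fit.

    Flows bounded in [0, 600] mL/min/100 g and k2 in [1e-4, 5] 1/s, covering
    the physiological range with margin.  Three multi-starts at log-spaced
    total flows; a start achieving a near-zero relative residual short-cuts
    the remaining starts.  Arterial/portal bolus-arrival delays are fixed at
    zero unless ``fit_delays`` is set, in which case they are fitted within
    ``delay_bounds_s``.
    """

    flow_bounds: tuple[float, float] = (0.0, 600.0)
    k2_bounds_s: tuple[float, float] = (1e-4, 5.0)
    fit_delays: bool = False
    delay_bounds_s: tuple[float, float] = (0.0, 10.0)
    start_total_flows: tuple[float, ...] = (30.0, 100.0, 300.0)
    start_arterial_fraction: float = 0.35
    start_dv: float = 25.0
    xtol: float = 1e-12

    def __post_init__(self) -> None:
        if self.flow_bounds[0] < 0 or self.flow_bounds[1] <= self.flow_bounds[0]:
            raise InvalidInputError("invalid flow bounds")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single voxel fit."""

    params: PerfusionParams | None
    delays_s: tuple[float, float]
    residual_norm: float
    converged: bool
    skipped: bool = False
    n_starts: int = 0


def fit_dual_input_voxel(
    ct: np.ndarray, inputs: InputFunctions, opts: FitOptions | None = None
) -> FitResult:
    """Fit the dual-input model to one tissue curve by bounded least squares.

    All-zero or all-missing curves are skipped (params ``None``).  Among the
    multi-starts the candidate with the lowest residual wins; exact residual
    ties are broken towards the lowest total flow.  Non-convergence of every
    start returns the best candidate flagged ``converged=False``.
    """
    opts = opts or FitOptions()
    ct = np.asarray(ct, dtype=float)
    good = np.isfinite(ct)
    if not good.any() or np.allclose(ct[good], 0.0):
        return FitResult(None, (0.0, 0.0), np.nan, False, skipped=True)

    t = inputs.time_s
    lo_f, hi_f = (b / FLOW_SCALE for b in opts.flow_bounds)
    lo = [lo_f, lo_f, opts.k2_bounds_s[0]]
    hi = [hi_f, hi_f, opts.k2_bounds_s[1]]
    if opts.fit_delays:
        lo += [opts.delay_bounds_s[0]] * 2
        hi += [opts.delay_bounds_s[1]] * 2

    def residual(p):
        fa_s, fp_s, k2 = p[:3]
        da, dp = (p[3], p[4]) if opts.fit_delays else (0.0, 0.0)
        x = fa_s * _shift_curve(t, inputs.ca_mM, da) + fp_s * _shift_curve(
            t, inputs.cp_mM, dp
        )
        model = _expconv(k2, t, x)
        return model[good] - ct[good]

    scale = float(np.linalg.norm(ct[good]))
    best = None
    n_starts = 0
    for ft0 in opts.start_total_flows:
        ft0_s = ft0 / FLOW_SCALE
        p0 = [
            np.clip(opts.start_arterial_fraction * ft0_s, lo_f + 1e-9, hi_f),
            np.clip((1 - opts.start_arterial_fraction) * ft0_s, lo_f + 1e-9, hi_f),
            np.clip(ft0_s / (opts.start_dv / 100.0), *opts.k2_bounds_s),
        ]
        if opts.fit_delays:
            p0 += [opts.delay_bounds_s[0] + 0.1] * 2
        res = least_squares(
            residual, p0, bounds=(lo, hi), method="trf",
            xtol=opts.xtol, ftol=opts.xtol, gtol=opts.xtol,
        )
        n_starts += 1
        cand = (res.cost, res.x[0] + res.x[1], res)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if np.sqrt(2 * res.cost) < 1e-8 * scale:
            break

    _, _, res = best
    fa_s, fp_s, k2 = res.x[:3]
    delays = tuple(res.x[3:5]) if opts.fit_delays else (0.0, 0.0)
    params = PerfusionParams.from_rates(fa_s, fp_s, k2)
    converged = bool(res.status > 0)
    if not converged:
        logger.warning("voxel fit did not converge (status=%d)", res.status)
    return FitResult(
        params=params,
        delays_s=delays,
        residual_norm=float(np.sqrt(2 * res.cost)),
        converged=converged,
        n_starts=n_starts,
    )


def fit_parameter_maps(
    dyn: DynamicSeries,
    t1m0: T1M0Map,
    inputs: InputFunctions,
    mask: np.ndarray,
    cfg: ConversionConfig | None = None,
    opts: FitOptions | None = None,
):
    """Apply the voxel fit over a mask, returning the six parameter volumes.

    Returns ``(maps, diagnostics)`` where ``maps`` maps each name in
    :data:`PARAM_NAMES` to a volume (NaN outside the mask and at failed
    voxels) and ``diagnostics`` reports voxel counts and the failure fraction.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dyn.data.shape[1:]:
        raise InvalidInputError("mask must match the dynamic grid")
    if not mask.any():
        raise InvalidInputError("empty mask")

    conc = signal_to_concentration(dyn, t1m0, cfg)
    maps = {name: np.full(mask.shape, np.nan) for name in PARAM_NAMES}
    n_failed = 0
    idx = np.argwhere(mask)
    for i, j, k in idx:
        result = fit_dual_input_voxel(conc[:, i, j, k], inputs, opts)
        if result.skipped or result.params is None:
            n_failed += 1
            continue
        for name, value in result.params.as_dict().items():
            maps[name][i, j, k] = value
    diagnostics = {
        "n_voxels": int(idx.shape[0]),
        "n_failed": n_failed,
        "failed_fraction": n_failed / idx.shape[0],
    }
    logger.info(
        "parameter maps: %d voxels fitted, %.2f%% failed",
        diagnostics["n_voxels"], 100 * diagnostics["failed_fraction"],
    )
    return maps, diagnostics
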