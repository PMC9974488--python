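"""Binding models for ratiometric sensor titrations and fluorescence polarization.

The sensor's emission ratio R = F_donor/F_acceptor responds hyperbolically to
analyte concentration,

    R(c) = R_min + (R_max - R_min) / (1 + c50 / c),

where ``c50`` is the concentration of half-maximal ratio change (not a
thermodynamic Kd: the tethered intramolecular ligand competes with the
analyte, so c50 depends on both affinities).  Fluorescence polarization of a
labeled tracer is fitted either with the exact ligand-depletion quadratic
(direct binding, yields Kd) or with the same hyperbola in the competitor
concentration (competition, yields c50).

All concentrations are in micromolar throughout the API.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or is ill-posed."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class TitrationSeries:
    """Concentration-response data for one analyte titration.

    ``concentrations`` are analyte concentrations in µM (zero allowed: the
    zero-analyte point defines R_min through the c → 0 limit); ``ratios`` are
    the dimensionless emission ratios, strictly positive.
    """

    analyte_name: str
    concentrations: np.ndarray
    ratios: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.concentrations.shape != self.ratios.shape:
            raise ValueError("concentrations and ratios must have equal length")
        if not np.all(np.isfinite(self.concentrations)):
            raise ValueError("concentrations must be finite")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.ratios)) or np.any(self.ratios <= 0):
            raise ValueError("ratios must be finite and strictly positive")
        if self.replicate_id is not None:
            self.replicate_id = np.asarray(self.replicate_id)
            if self.replicate_id.shape != self.ratios.shape:
                raise ValueError("replicate_id must match data length")

    @property
    def n_distinct_concentrations(self) -> int:
        return np.unique(self.concentrations).size


@dataclass
class IsothermFit:
    """Fitted hyperbolic isotherm: (R_min, R_max, c50) with diagnostics."""

    r_min: float
    r_max: float
    c50: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_sse: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    @property
    def dynamic_range(self) -> float:
        return dynamic_range(self)


@dataclass
class FPSeries:
    """Fluorescence polarization vs protein (direct) or competitor (competition)."""

    x_values: np.ndarray
    fp_values: np.ndarray
    mode: str  # "direct" | "competition"
    tracer_conc: float | None = None  # [L] of labeled tracer, µM (direct mode)

    def __post_init__(self) -> None:
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.fp_values = np.asarray(self.fp_values, dtype=float)
        if self.x_values.shape != self.fp_values.shape:
            raise ValueError("x_values and fp_values must have equal length")
        if np.any(self.x_values < 0):
            raise ValueError("concentrations must be non-negative")
        if self.mode not in ("direct", "competition"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if np.any(np.abs(self.fp_values) > 1):
            raise ValueError("FP values must lie in [-1, 1]")
        if self.mode == "direct" and (self.tracer_conc is None or self.tracer_conc <= 0):
            raise ValueError("direct mode requires a positive tracer_conc")


@dataclass
class QuadraticBindingFit:
    """Direct-binding fit under ligand depletion: FP0, FPs and Kd (µM)."""

    fp0: float
    fps: float
    kd: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_sse: float = float("nan")
    warnings: list[str] = field(default_factory=list)


@dataclass
class CompetitionFit:
    """Competition fit: FP0 (no competitor, bound tracer), FPs, c50 (µM)."""

    fp0: float
    fps: float
    c50: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_sse: float = float("nan")
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------


def hyperbola(conc, y0: float, y1: float, xhalf: float):
    """Saturation hyperbola y0 + (y1 - y0)/(1 + xhalf/conc), with y(0) = y0.

    The zero-concentration point is evaluated through the c → 0 limit rather
    than dropped, so titrations routinely include it.
    """
    conc = np.asarray(conc, dtype=float)
    out = np.empty_like(conc)
    pos = conc > 0
    out[pos] = y0 + (y1 - y0) / (1.0 + xhalf / conc[pos])
    out[~pos] = y0
    return out if out.ndim else float(out)


def isotherm_forward(conc, fit: IsothermFit):
    """Emission ratio predicted at analyte concentration ``conc`` (µM)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    return hyperbola(conc, fit.r_min, fit.r_max, fit.c50)


def isotherm_invert(ratio: float, fit: IsothermFit) -> float:
    """Analyte concentration (µM) at which the isotherm takes ``ratio``.

    Algebraic inverse c = c50 (R - R_min)/(R_max - R); only defined strictly
    between R_min and R_max.
    """
    lo, hi = sorted((fit.r_min, fit.r_max))
    if not lo < ratio < hi:
        violated = lo if ratio <= lo else hi
        bound = "r_min" if violated == fit.r_min else "r_max"
        raise ValueError(
            f"ratio {ratio} outside the open response range ({lo}, {hi}): "
            f"violates the {bound} bound"
        )
    return fit.c50 * (ratio - fit.r_min) / (fit.r_max - ratio)


def dynamic_range(fit: IsothermFit) -> float:
    """Fold dynamic range ΔR = R_max / R_min."""
    if fit.r_min <= 0:
        raise ValueError("r_min must be positive to form a fold change")
    return fit.r_max / fit.r_min


def selectivity_fold(c50_other: float, c50_analyte: float) -> float:
    """Selectivity as the fold ratio of the off-target c50 over the analyte c50."""
    if c50_other <= 0 or c50_analyte <= 0:
        raise ValueError("c50 values must be positive")
    return c50_other / c50_analyte


def fp_from_intensities(i_parallel, i_perpendicular, g_factor: float = 1.0):
    """Fluorescence polarization (I∥ - G·I⊥)/(I∥ + G·I⊥)."""
    i_par = np.asarray(i_parallel, dtype=float)
    i_perp = np.asarray(i_perpendicular, dtype=float)
    if g_factor <= 0:
        raise ValueError("g_factor must be positive")
    if np.any(i_par < 0) or np.any(i_perp < 0):
        raise ValueError("intensities must be non-negative")
    denom = i_par + i_perp * g_factor
    if np.any(denom == 0):
        raise ValueError("zero total intensity: FP undefined")
    out = (i_par - i_perp * g_factor) / denom
    return out if out.ndim else float(out)


def fp_direct_forward(protein_conc, fp0: float, fps: float, kd: float, tracer_conc: float):
    """Exact ligand-depletion (quadratic) direct-binding FP model.

    The bound tracer fraction solves the quadratic mass balance at total
    tracer [L] and total protein [P]; FP interpolates between free (fp0) and
    bound (fps) polarization by that fraction.
    """
    p = np.asarray(protein_conc, dtype=float)
    ltot = tracer_conc
    s = ltot + p + kd
    frac_bound = (s - np.sqrt(s * s - 4.0 * ltot * p)) / (2.0 * ltot)
    out = fp0 + (fps - fp0) * frac_bound
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _jacobian_standard_errors(res, names: list[str]) -> tuple[dict[str, float], float]:
    """Parameter SEs from the Jacobian-based covariance at the optimum."""
    sse = float(2.0 * res.cost)
    dof = res.fun.size - res.x.size
    ses: dict[str, float] = {}
    if dof > 0:
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * (sse / dof)
            diag = np.clip(np.diag(cov), 0.0, None)
            ses = dict(zip(names, np.sqrt(diag)))
        except np.linalg.LinAlgError:
            ses = {n: float("nan") for n in names}
    return ses, sse


def fit_isotherm(series: TitrationSeries, weights=None) -> IsothermFit:
    """Least-squares fit of the hyperbolic isotherm for (R_min, R_max, c50).

    Unweighted nonlinear least squares on the pooled points (optional
    per-point ``weights``); c50 is log-parameterized internally to enforce
    positivity and reported on the linear scale with a delta-method SE.
    Deterministic, data-driven starting values: R_min/R_max from the
    5th/95th percentiles of the ratios (oriented by the response direction)
    and c50 from the concentration nearest the response midpoint.
    """
    if series.n_distinct_concentrations < 5:
        raise ValueError("at least 5 distinct concentrations are required to fit")
    conc = series.concentrations
    r = series.ratios
    w = np.ones_like(r) if weights is None else np.asarray(weights, dtype=float)

    lo_val = float(np.percentile(r, 5))
    hi_val = float(np.percentile(r, 95))
    # orient: does the ratio rise or fall with concentration?
    order = np.argsort(conc)
    rising = np.mean(r[order][-3:]) >= np.mean(r[order][:3])
    r0, r1 = (lo_val, hi_val) if rising else (hi_val, lo_val)
    mid = 0.5 * (r0 + r1)
    pos = conc > 0
    if not np.any(pos):
        raise ValueError("titration needs positive concentrations")
    c50_0 = float(conc[pos][np.argmin(np.abs(r[pos] - mid))])
    if c50_0 <= 0:
        c50_0 = float(np.median(conc[pos]))

    def resid(theta):
        rmin, rmax, logc = theta
        return w * (hyperbola(conc, rmin, rmax, math.exp(logc)) - r)

    res = least_squares(resid, x0=[r0, r1, math.log(c50_0)], method="lm", xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise FitError(f"isotherm fit did not converge: {res.message}")
    rmin, rmax, logc = res.x
    c50 = math.exp(logc)
    ses, sse = _jacobian_standard_errors(res, ["r_min", "r_max", "log_c50"])
    se = {
        "r_min": ses.get("r_min", float("nan")),
        "r_max": ses.get("r_max", float("nan")),
        "c50": c50 * ses.get("log_c50", float("nan")),
    }

    warns: list[str] = []
    span = np.ptp(r)
    if span == 0 or abs(rmax - rmin) < 1e-3 * max(abs(rmin), abs(rmax), 1.0):
        warns.append("unidentifiable: flat response, c50 not determined")
    cpos = conc[pos]
    if c50 > 10.0 * cpos.max() or c50 < cpos.min() / 10.0:
        warns.append("extrapolated: c50 lies >10x outside the sampled concentration range")
    for msg in warns:
        warnings.warn(msg, stacklevel=2)
    return IsothermFit(float(rmin), float(rmax), float(c50), se, sse, warns)


def fit_fp_direct(series: FPSeries) -> QuadraticBindingFit:
    """Fit the ligand-depletion quadratic FP model for (FP0, FPs, Kd)."""
    if series.mode != "direct":
        raise ValueError("fit_fp_direct requires a series in direct mode")
    x, fp, ltot = series.x_values, series.fp_values, float(series.tracer_conc)

    fp0_0 = float(fp[np.argmin(x)])
    fps_0 = float(fp[np.argmax(x)])
    mid = 0.5 * (fp0_0 + fps_0)
    pos = x > 0
    kd_0 = float(x[pos][np.argmin(np.abs(fp[pos] - mid))]) if np.any(pos) else 1.0
    kd_0 = max(kd_0, 1e-6)

    def resid(theta):
        fp0, fps, logkd = theta
        return fp_direct_forward(x, fp0, fps, math.exp(logkd), ltot) - fp

    res = least_squares(resid, x0=[fp0_0, fps_0, math.log(kd_0)], method="lm",
                        xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise FitError(f"FP direct fit did not converge at {res.x}: {res.message}")
    fp0, fps, logkd = res.x
    kd = math.exp(logkd)
    ses, sse = _jacobian_standard_errors(res, ["fp0", "fps", "log_kd"])
    se = {"fp0": ses.get("fp0", float("nan")),
          "fps": ses.get("fps", float("nan")),
          "kd": kd * ses.get("log_kd", float("nan"))}
    return QuadraticBindingFit(float(fp0), float(fps), float(kd), se, sse)


def fit_fp_competition(series: FPSeries) -> CompetitionFit:
    """Fit the competition hyperbola FP = FP0 + (FPs - FP0)/(1 + c50/[L])."""
    if series.mode != "competition":
        raise ValueError("fit_fp_competition requires a series in competition mode")
    x, fp = series.x_values, series.fp_values

    fp0_0 = float(fp[np.argmin(x)])
    fps_0 = float(fp[np.argmax(x)])
    mid = 0.5 * (fp0_0 + fps_0)
    pos = x > 0
    c50_0 = float(x[pos][np.argmin(np.abs(fp[pos] - mid))]) if np.any(pos) else 1.0
    c50_0 = max(c50_0, 1e-6)

    def resid(theta):
        fp0, fps, logc = theta
        return hyperbola(x, fp0, fps, math.exp(logc)) - fp

    res = least_squares(resid, x0=[fp0_0, fps_0, math.log(c50_0)], method="lm",
                        xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise FitError(f"FP competition fit did not converge at {res.x}: {res.message}")
    fp0, fps, logc = res.x
    c50 = math.exp(logc)
    ses, sse = _jacobian_standard_errors(res, ["fp0", "fps", "log_c50"])
    se = {"fp0": ses.get("fp0", float("nan")),
          "fps": ses.get("fps", float("nan")),
          "c50": c50 * ses.get("log_c50", float("nan"))}
    return CompetitionFit(float(fp0), float(fps), float(c50), se, sse)
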