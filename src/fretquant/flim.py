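"""TCSPC decay fitting and lifetime-based analyte quantification.

Fluorescence decays are histogrammed photon arrival times (time-correlated
single-photon counting).  A multi-exponential model

    I(t) = sum_i A_i exp(-t / tau_i) + B

is fitted by Poisson maximum likelihood (the photon counts are Poisson;
weighted least squares is available as an option).  The amplitude-weighted
mean lifetime tau = sum(alpha_i tau_i) / sum(alpha_i) enters the FRET
efficiency E = 1 - tau_FRET / tau_D against the donor-only lifetime, and a
hyperbolic calibration E(c) = E_min + (E_max - E_min)/(1 + c50/c) links
efficiency to analyte concentration; its algebraic inverse

    c = c50 (E - E_min) / (E_max - E)

converts a measured efficiency into an absolute concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize, nnls

from .binding import FitError, hyperbola


@dataclass
class DecayHistogram:
    """Photon counts per uniform time bin; ``bin_time_ns`` are left edges."""

    bin_time_ns: np.ndarray
    counts: np.ndarray
    irf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_time_ns = np.asarray(self.bin_time_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_time_ns.shape != self.counts.shape:
            raise ValueError("bin_time_ns and counts must have equal length")
        if self.bin_time_ns.size < 4:
            raise ValueError("too few bins for a decay histogram")
        widths = np.diff(self.bin_time_ns)
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("bins must be uniform")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if self.irf is not None:
            self.irf = np.asarray(self.irf, dtype=float)
            if self.irf.shape != self.counts.shape:
                raise ValueError("IRF must share the decay's bins")

    @property
    def bin_width_ns(self) -> float:
        return float(self.bin_time_ns[1] - self.bin_time_ns[0])

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())


@dataclass
class MultiExpFit:
    """Fitted multi-exponential decay, components sorted by descending tau."""

    amplitudes: np.ndarray
    lifetimes_ns: np.ndarray
    background_offset: float
    chi2_reduced: float
    fitted_curve: np.ndarray
    fit_start_bin: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return int(len(self.lifetimes_ns))


@dataclass
class LifetimeCalibration:
    """Donor lifetime plus the efficiency-vs-concentration hyperbola."""

    tau_donor_ns: float
    e_min: float
    e_max: float
    c50_uM: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_sse: float = float("nan")
    temperature_note: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_min < self.e_max <= 1.0):
            raise ValueError("need 0 <= e_min < e_max <= 1")
        if self.c50_uM <= 0:
            raise ValueError("c50 must be positive")

    def efficiency_forward(self, conc_uM):
        """E(c) hyperbola of the calibration (forward model)."""
        return hyperbola(conc_uM, self.e_min, self.e_max, self.c50_uM)


@dataclass
class ConcentrationEstimate:
    coa_uM: float | None
    fret_efficiency: float
    source_roi: str = ""
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# decay model and fitting
# ---------------------------------------------------------------------------


def _decay_model(t: np.ndarray, amplitudes: np.ndarray, taus: np.ndarray,
                 offset: float, irf: np.ndarray | None = None) -> np.ndarray:
    """Expected counts per bin center: sum of exponentials (optionally IRF-convolved).

    Times are absolute (measured from the excitation pulse), so fitted
    amplitudes are referenced to t = 0 regardless of where the tail fit
    starts.
    """
    model = np.zeros_like(t)
    for a, tau in zip(amplitudes, taus):
        model += a * np.exp(-t / tau)
    if irf is not None:
        kernel = irf / irf.sum()
        model = np.convolve(model, kernel)[: t.size]
    return model + offset


def _initial_lifetimes(t: np.ndarray, counts: np.ndarray, n: int) -> np.ndarray:
    """Spread starting lifetimes around a crude log-slope estimate."""
    c = np.clip(counts, 1e-9, None)
    # slope of log-counts over the central decaying part
    k = max(4, t.size // 4)
    seg_t, seg_c = t[:k], np.log(c[:k])
    slope = np.polyfit(seg_t, seg_c, 1)[0]
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    tau0 = float(np.clip(tau0, 1e-3, 10 * (t[-1] - t[0])))
    if n == 1:
        return np.array([tau0])
    return tau0 * np.geomspace(0.4, 2.5, n)


def fit_multiexp(decay: DecayHistogram, n_components: int = 3, use_irf: bool = False,
                 objective: str = "mle", fit_offset: bool = True,
                 min_photons: float = 1e3) -> MultiExpFit:
    """Fit a multi-exponential model to a TCSPC histogram.

    Poisson maximum likelihood by default (``objective="mle"``); Neyman
    weighted least squares with ``objective="wls"``.  Without an IRF the fit
    is a tail fit starting at the peak bin; with ``use_irf`` the model is
    numerically convolved with ``decay.irf``.  Components whose lifetimes
    collapse onto each other (ratio < 1.2) are merged with a warning.
    Reports the reduced Pearson chi-square of the fit.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if objective not in ("mle", "wls"):
        raise ValueError("objective must be 'mle' or 'wls'")
    if decay.total_photons <= 0:
        raise ValueError("decay has no photons")
    if decay.total_photons < min_photons:
        raise ValueError(
            f"too few photons ({decay.total_photons:.0f} < {min_photons:.0f}) for a stable fit")
    irf = decay.irf if use_irf else None
    if use_irf and irf is None:
        raise ValueError("use_irf requested but the histogram carries no IRF")

    if irf is None:
        start = int(np.argmax(decay.counts))
    else:
        start = 0
    # evaluate the model at bin centers, consistent with histogramming
    t = decay.bin_time_ns[start:] + 0.5 * decay.bin_width_ns
    counts = decay.counts[start:]

    taus0 = _initial_lifetimes(t, counts, n_components)
    # amplitudes by non-negative linear least squares given the starting taus
    basis = np.stack([np.exp(-t / tau) for tau in taus0], axis=1)
    amps0, _ = nnls(basis, counts)
    amps0 = np.clip(amps0, counts.max() * 1e-6 + 1e-12, None)
    off0 = max(float(counts[-max(3, counts.size // 20):].min()), 0.0)

    n = n_components
    x0 = np.concatenate([np.log(amps0), np.log(taus0), [off0]])
    bounds_lo = [-np.inf] * (2 * n) + [0.0]
    bounds_hi = [np.inf] * (2 * n) + [np.inf]
    if not fit_offset:
        x0[-1] = 0.0

    def unpack(x):
        # clip keeps the offset physical for the unbounded polish stage
        return np.exp(x[:n]), np.exp(x[n:2 * n]), (max(x[-1], 0.0) if fit_offset else 0.0)

    if objective == "mle":
        def nll(x):
            a, tau, b = unpack(x)
            m = np.clip(_decay_model(t, a, tau, b, irf), 1e-12, None)
            return float(np.sum(m - counts * np.log(m)))

        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=list(zip(bounds_lo, bounds_hi)),
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        # polish from the L-BFGS-B iterate (tightens noiseless recovery)
        res = minimize(nll, res.x, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        if not np.all(np.isfinite(res.x)):
            raise FitError(f"decay fit diverged: {res.message}")
        xhat = res.x
    else:
        w = 1.0 / np.sqrt(np.clip(counts, 1.0, None))

        def resid(x):
            a, tau, b = unpack(x)
            return w * (_decay_model(t, a, tau, b, irf) - counts)

        res = least_squares(resid, x0, bounds=(bounds_lo, bounds_hi),
                            xtol=1e-14, ftol=1e-14)
        if not res.success:
            raise FitError(f"decay fit did not converge: {res.message}")
        xhat = res.x

    amps, taus, off = unpack(xhat)

    warns: list[str] = []
    # merge collapsed components (over-parameterized fit)
    order = np.argsort(taus)[::-1]
    amps, taus = amps[order], taus[order]
    merged_a, merged_t = [amps[0]], [taus[0]]
    for a, tau in zip(amps[1:], taus[1:]):
        if merged_t[-1] / tau < 1.2:
            w_old, w_new = merged_a[-1], a
            merged_t[-1] = (w_old * merged_t[-1] + w_new * tau) / (w_old + w_new)
            merged_a[-1] = w_old + w_new
            warns.append("component collapse: nearly equal lifetimes merged")
        else:
            merged_a.append(a)
            merged_t.append(tau)
    amps = np.asarray(merged_a)
    taus = np.asarray(merged_t)

    fitted = _decay_model(t, amps, taus, off, irf)
    n_par = 2 * len(taus) + (1 if fit_offset else 0)
    use = fitted > 1e-6
    dof = max(int(use.sum()) - n_par, 1)
    chi2 = float(np.sum((counts[use] - fitted[use]) ** 2 / fitted[use]) / dof)
    for msg in set(warns):
        warnings.warn(msg, stacklevel=2)

    full_curve = np.zeros_like(decay.counts)
    full_curve[start:] = fitted
    return MultiExpFit(amps, taus, float(off), chi2, full_curve, start, warns)


def amplitude_weighted_lifetime(fit: MultiExpFit) -> float:
    """Amplitude-weighted mean lifetime sum(a_i tau_i)/sum(a_i), in ns.

    This is the standard normalized form; it is bounded by the component
    lifetimes and invariant to rescaling all amplitudes by a positive
    constant.
    """
    a = np.asarray(fit.amplitudes, dtype=float)
    tau = np.asarray(fit.lifetimes_ns, dtype=float)
    s = a.sum()
    if s <= 0:
        raise ValueError("amplitudes sum to zero: lifetime undefined")
    return float(np.sum(a * tau) / s)


def fret_efficiency(tau_fret: float, tau_donor: float) -> float:
    """FRET efficiency E = 1 - tau_FRET/tau_D (not clipped; may be < 0)."""
    if tau_donor <= 0:
        raise ValueError("donor lifetime must be positive")
    if tau_fret <= 0:
        raise ValueError("FRET-sample lifetime must be positive")
    return 1.0 - tau_fret / tau_donor


def build_lifetime_calibration(titration, donor_only: DecayHistogram,
                               n_components: int = 2, use_irf: bool = False,
                               temperature_note: str = "") -> LifetimeCalibration:
    """Calibrate the efficiency-vs-concentration hyperbola from decays.

    ``titration`` is a sequence of ``(conc_uM, DecayHistogram)`` pairs
    spanning the response midpoint; ``donor_only`` is the decay of the
    unquenched donor (unlabeled sensor) defining tau_D.  Each decay is fitted
    with ``n_components`` exponentials, reduced to its amplitude-weighted
    lifetime and converted to an efficiency; the hyperbola
    E(c) = E_min + (E_max - E_min)/(1 + c50/c) is then fitted by least
    squares with log-parameterized c50.
    """
    pairs = list(titration)
    concs = np.array([c for c, _ in pairs], dtype=float)
    if np.unique(concs).size < 5:
        raise ValueError("need at least 5 concentrations to calibrate")
    donor_fit = fit_multiexp(donor_only, n_components=1, use_irf=use_irf)
    tau_d = amplitude_weighted_lifetime(donor_fit)

    effs = []
    for _, decay in pairs:
        f = fit_multiexp(decay, n_components=n_components, use_irf=use_irf)
        effs.append(fret_efficiency(amplitude_weighted_lifetime(f), tau_d))
    effs = np.asarray(effs)

    e0 = float(effs[np.argmin(concs)])
    e1 = float(effs[np.argmax(concs)])
    mid = 0.5 * (e0 + e1)
    pos = concs > 0
    c50_0 = max(float(concs[pos][np.argmin(np.abs(effs[pos] - mid))]), 1e-6)

    def resid(theta):
        emin, emax, logc = theta
        return hyperbola(concs, emin, emax, math.exp(logc)) - effs

    res = least_squares(resid, x0=[e0, e1, math.log(c50_0)], method="lm",
                        xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise FitError(f"calibration fit did not converge: {res.message}")
    emin, emax, logc = res.x
    c50 = math.exp(logc)
    sse = float(2.0 * res.cost)

    warns: list[str] = []
    cpos = concs[pos]
    if not (cpos.min() < c50 < cpos.max()):
        warns.append("extrapolated: c50 outside the sampled concentration range")
        warnings.warn(warns[-1], stacklevel=2)
    emin = float(np.clip(emin, 0.0, 1.0))
    emax = float(np.clip(emax, emin + 1e-9, 1.0))
    return LifetimeCalibration(tau_d, emin, emax, float(c50),
                               residual_sse=sse, temperature_note=temperature_note,
                               warnings=warns)


def coa_concentration(efficiency: float, calib: LifetimeCalibration,
                      source_roi: str = "") -> ConcentrationEstimate:
    """Invert the calibration: c = c50 (E - E_min)/(E_max - E).

    Efficiencies at or below E_min report 0 with an out-of-range flag;
    efficiencies at or above E_max are flagged saturated with no value (the
    inverse diverges there) rather than extrapolated.
    """
    flags: list[str] = []
    if efficiency <= calib.e_min:
        flags.append("below-range")
        return ConcentrationEstimate(0.0, efficiency, source_roi, flags)
    if efficiency >= calib.e_max:
        flags.append("saturated")
        return ConcentrationEstimate(None, efficiency, source_roi, flags)
    conc = calib.c50_uM * (efficiency - calib.e_min) / (calib.e_max - efficiency)
    if efficiency > calib.e_min + 0.95 * (calib.e_max - calib.e_min):
        flags.append("near-saturation")
    return ConcentrationEstimate(float(conc), efficiency, source_roi, flags)
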