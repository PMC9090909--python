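"""Rate-constant extraction from kinetic traces and Beer-Lambert
response-to-concentration conversion.

The primary estimator linearises the integrated rate law: with alpha2
known from the spectra, eta(t_i) = (C_i - C0) + alpha2*ln(C_i/C0) is
computed point by point from the measured concentrations and regressed
against time; the overall rate constant k_eta is minus the slope.  A
one-parameter nonlinear fit on the explicit Lambert-W forward model is
provided as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError
from .eta import EtaParams, concentration_at_time, eta_of_t
from .simulate import KineticTrace

__all__ = [
    "CalibrationLine",
    "EtaFit",
    "fit_calibration",
    "trace_from_response",
    "fit_eta_trace",
    "fit_eta_nonlinear",
]

#: Points where C_A has fallen below this fraction of C0 are excluded
#: from the linearised fit: there the log term amplifies noise.
LOW_CONC_CUTOFF = 0.01


@dataclass(frozen=True)
class CalibrationLine:
    """A Beer-Lambert (or peak-area) calibration: response = slope*C + intercept."""

    slope: float
    intercept: float
    r2: float
    conc_range: tuple[float, float]
    mode: str = "single-wavelength absorbance"  # | summed absorbance | peak area
    slope_stderr: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError("r2 must lie in [0, 1]")
        lo, hi = self.conc_range
        if not (0 <= lo <= hi):
            raise ValidationError("concentration range must be positive and ordered")

    @property
    def usable(self) -> bool:
        return self.slope != 0.0

    def response(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def concentration(self, response):
        if not self.usable:
            raise FitError("calibration slope is zero; line unusable")
        return (np.asarray(response, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class EtaFit:
    """Result of an eta-order rate-constant fit."""

    k_eta: float
    stderr: float
    r2: float
    intercept: float  # diagnostic; exactly 0 in through-origin mode
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_used: int = 0
    method: str = "linearised"
    degrading: bool = True


def fit_calibration(concs, responses) -> CalibrationLine:
    """Ordinary least-squares calibration line through >= 3 distinct
    concentrations; the declared linearity range is [min, max] of the
    calibration concentrations."""
    c = np.asarray(concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.size < 3:
        raise ValidationError("calibration requires at least 3 points")
    if np.unique(c).size != c.size:
        raise ValidationError("calibration concentrations must be distinct")
    res = stats.linregress(c, y)
    r2 = float(res.rvalue**2)
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2 if np.isfinite(r2) else 0.0,  # constant responses give r = nan
        conc_range=(float(c.min()), float(c.max())),
        slope_stderr=float(res.stderr),
    )


def trace_from_response(
    t,
    responses,
    cal_A: CalibrationLine,
    cal_B: CalibrationLine | None = None,
    C0: float | None = None,
) -> KineticTrace:
    """Convert an instrument response series to a concentration trace.

    Single-species mode (``cal_B`` absent): C_A = (response - intercept)/slope
    of ``cal_A`` — the photoproduct is invisible to the detector (e.g. a
    detection wavelength where it does not absorb, or its HPLC peak is
    resolved away).

    Two-species absorbance mode: the observed response is
    s_A*C_A + s_B*C_B + baseline with baseline = cal_A.intercept; with the
    mass balance C_B = C0 - C_A this inverts to
    C_A = (response - baseline - s_B*C0) / (s_A - s_B), requiring s_A != s_B
    and a known C0.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(responses, dtype=float)
    if cal_B is None or cal_B.slope == 0.0:
        C_A = cal_A.concentration(y)
    else:
        if C0 is None:
            raise ValidationError("two-species conversion requires C0")
        s_a, s_b = cal_A.slope, cal_B.slope
        if s_a == s_b:
            raise ValidationError(
                "degenerate observable: reactant and photoproduct have equal "
                "response slopes; C_A cannot be separated"
            )
        C_A = (y - cal_A.intercept - s_b * C0) / (s_a - s_b)
    return KineticTrace(t, C_A, provenance="measured")


def _eta_points(trace: KineticTrace, alpha2: float, C0: float | None, cutoff: float):
    C0 = trace.C0 if C0 is None else C0
    if np.any(trace.C_A <= 0):
        raise ValidationError("trace concentrations must be positive")
    keep = trace.C_A >= cutoff * C0
    params = EtaParams(alpha1=1.0, alpha2=alpha2, k_eta=0.0, C0=C0) if alpha2 >= 0 else None
    t = trace.t[keep]
    if params is not None:
        eta = eta_of_t(trace.C_A[keep], params)
    else:  # alpha2 < 0: evaluate directly (EtaParams enforces sign pairing)
        eta = (trace.C_A[keep] - C0) + alpha2 * np.log(trace.C_A[keep] / C0)
    return t, eta, C0, int(keep.sum())


def fit_eta_trace(
    trace: KineticTrace,
    alpha2: float,
    through_origin: bool = True,
    C0: float | None = None,
    cutoff: float = LOW_CONC_CUTOFF,
) -> EtaFit:
    """Linearised eta-order fit: regress eta(t_i) on t_i, k_eta = -slope.

    The integrated law has no intercept, so the default regression is
    through the origin; ``through_origin=False`` keeps a free intercept
    as a diagnostic.  Points with C_A below ``cutoff``*C0 are excluded.
    """
    t, eta, C0, n_used = _eta_points(trace, alpha2, C0, cutoff)
    if n_used < 4:
        raise ValidationError("eta-order fit requires at least 4 usable points")
    if through_origin:
        stt = float(np.dot(t, t))
        if stt == 0:
            raise FitError("all usable times are zero")
        slope = float(np.dot(t, eta)) / stt
        intercept = 0.0
        resid = eta - slope * t
        dof = max(n_used - 1, 1)
        stderr = float(np.sqrt(np.dot(resid, resid) / dof / stt))
    else:
        res = stats.linregress(t, eta)
        slope, intercept, stderr = float(res.slope), float(res.intercept), float(res.stderr)
        resid = eta - (slope * t + intercept)
    # r2 of the eta-vs-t line (squared Pearson correlation)
    if np.ptp(eta) == 0 or np.ptp(t) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(t, eta)[0, 1] ** 2)
    k = -slope
    degrading = k > 0 and (stderr == 0 or k > 2 * stderr)
    return EtaFit(k, stderr, r2, intercept, resid, n_used, "linearised", degrading)


def fit_eta_nonlinear(
    trace: KineticTrace,
    alpha2: float,
    C0: float,
    k0: float | None = None,
) -> EtaFit:
    """Single-parameter least squares of the explicit forward model
    C(t; k_eta) against the measured trace.

    The 1-D problem is solved by bounded scalar minimisation over four
    decades around the initial guess (the linearised estimate unless
    ``k0`` is given), so a guess off by an order of magnitude still
    converges.
    """
    if k0 is None:
        k0 = fit_eta_trace(trace, alpha2, C0=C0).k_eta
    if not np.isfinite(k0) or k0 <= 0:
        raise FitError("no positive initial guess for k_eta available")

    def sse(log_k):
        p = EtaParams(alpha1=1.0 if alpha2 >= 0 else -1.0, alpha2=alpha2,
                      k_eta=float(np.exp(log_k)), C0=C0)
        model = concentration_at_time(trace.t, p)
        return float(np.sum((model - trace.C_A) ** 2))

    res = optimize.minimize_scalar(
        sse,
        bounds=(np.log(k0) - np.log(100.0), np.log(k0) + np.log(100.0)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise FitError(f"nonlinear fit did not converge: {res.message}")
    k = float(np.exp(res.x))
    p = EtaParams(alpha1=1.0 if alpha2 >= 0 else -1.0, alpha2=alpha2, k_eta=k, C0=C0)
    model = concentration_at_time(trace.t, p)
    resid = trace.C_A - model
    ss_tot = float(np.sum((trace.C_A - trace.C_A.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    # stderr from the curvature of the SSE in k (Gauss-Newton approximation)
    dk = max(1e-6 * k, 1e-18)
    d_model = (concentration_at_time(trace.t, EtaParams(p.alpha1, alpha2, k + dk, C0)) - model) / dk
    jtj = float(np.dot(d_model, d_model))
    dof = max(trace.t.size - 1, 1)
    stderr = float(np.sqrt(np.sum(resid**2) / dof / jtj)) if jtj > 0 else float("inf")
    return EtaFit(k, stderr, max(r2, 0.0), 0.0, resid, trace.t.size, "nonlinear")
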