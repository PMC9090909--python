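"""Drug actinometry under polychromatic light.

An AB(1Phi) photosystem whose eta-order rate constant k_eta has been
calibrated against a series of known total photon fluxes P0_tot of one
lamp becomes an actinometer *for that lamp*: the calibration line

    k_eta = beta_eta * P0_tot (+ intercept)

inverts an unknown intensity from a single measured k_eta.  The factor
beta_eta = sum(Phi*eps_A*P0) / (P0_tot * sum(eps_A - eps_B)) depends on
the lamp's normalised emission shape, so calibrations do not transfer
between lamps with different profiles: actinometry is lamp-specific,
and this module makes that property enforceable (strict mode) and
measurable (:func:`cross_lamp_discrepancy`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import LampMismatchError, ProtocolError, ValidationError
from .eta import k_eta_from_attributes
from .fitting import EtaFit, fit_eta_trace
from .simulate import KineticTrace
from .spectra import LampProfile, PhotoSpecies, restrict_to_support, total_flux

__all__ = [
    "ActinometerCalibration",
    "calibrate",
    "unknown_intensity",
    "cross_lamp_discrepancy",
    "beta_from_attributes",
    "ProtocolConfig",
    "ProtocolReport",
    "run_protocol",
]

MIN_CALIBRATION_POINTS = 4  # the protocol demands n > 3 intensities


@dataclass(frozen=True)
class ActinometerCalibration:
    """A drug-lamp pair's k_eta-vs-P0_tot line.

    ``beta_eta`` is stored as the literal ratio of k_eta (M s^-1) to
    P0_tot (einstein dm^-3 s^-1, numerically commensurate with M s^-1);
    the published convention quotes it in M^-1 s.  A calibration is
    meaningless without its lamp identity.
    """

    drug_id: str
    lamp_id: str
    beta_eta: float
    intercept: float = 0.0
    r2: float = 1.0
    points: tuple[tuple[float, float], ...] = ()
    n: int = 0
    beta_unit: str = "M^-1 s"

    def __post_init__(self):
        if not self.lamp_id:
            raise ValidationError("a calibration without a lamp identity is unusable")
        if self.beta_eta <= 0:
            raise ValidationError("beta_eta must be positive")

    @classmethod
    def from_line(
        cls, drug_id: str, lamp_id: str, slope: float, intercept: float = 0.0,
        r2: float = 1.0,
    ) -> "ActinometerCalibration":
        """Wrap a published/known calibration line (no raw points)."""
        return cls(drug_id, lamp_id, slope, intercept, r2)


def calibrate(
    points,
    drug_id: str,
    lamp_id: str,
    through_origin: bool = False,
) -> ActinometerCalibration:
    """Least-squares k_eta = beta_eta * P0_tot (+ intercept) from >= 4
    (P0_tot, k_eta) pairs at distinct intensities.

    The default keeps a free intercept, matching how experimental
    calibration lines are usually reported; the strict proportional
    form is available via ``through_origin``.
    """
    pts = [(float(p), float(k)) for p, k in points]
    if len(pts) < MIN_CALIBRATION_POINTS:
        raise ProtocolError(
            f"actinometer calibration requires at least {MIN_CALIBRATION_POINTS} "
            f"distinct intensities (n > 3); got {len(pts)}"
        )
    p = np.array([x[0] for x in pts])
    k = np.array([x[1] for x in pts])
    if np.unique(p).size < 2:
        raise ProtocolError("all calibration intensities are identical: rank-deficient design")
    if through_origin:
        beta = float(np.dot(p, k) / np.dot(p, p))
        intercept = 0.0
        resid = k - beta * p
    else:
        res = stats.linregress(p, k)
        beta, intercept = float(res.slope), float(res.intercept)
        resid = k - (beta * p + intercept)
    ss_tot = float(np.sum((k - k.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return ActinometerCalibration(
        drug_id, lamp_id, beta, intercept, max(min(r2, 1.0), 0.0), tuple(pts), len(pts)
    )


def unknown_intensity(
    k_eta_unk: float,
    cal: ActinometerCalibration,
    lamp_id: str | None = None,
    strict: bool = False,
) -> float:
    """Invert an unknown total photon flux from a measured k_eta:
    P0_tot = (k_eta - intercept) / beta_eta.

    If ``lamp_id`` names a lamp other than the calibration's, strict
    mode refuses (calibrations are lamp-specific); permissive mode
    warns and proceeds so the discrepancy can be quantified.
    """
    if k_eta_unk <= 0:
        raise ValidationError("measured k_eta must be positive")
    if lamp_id is not None and lamp_id != cal.lamp_id:
        msg = (
            f"calibration was measured on lamp {cal.lamp_id!r} but is being "
            f"applied to lamp {lamp_id!r}; actinometers are lamp-specific"
        )
        if strict:
            raise LampMismatchError(msg)
        warnings.warn(msg, stacklevel=2)
    p = (k_eta_unk - cal.intercept) / cal.beta_eta
    if p <= 0:
        warnings.warn(
            "measured k_eta at or below the calibration intercept: inferred "
            "intensity is not positive (below calibration range)",
            stacklevel=2,
        )
    return p


def cross_lamp_discrepancy(
    k_eta: float,
    cal_true: ActinometerCalibration,
    cal_wrong: ActinometerCalibration,
) -> float:
    """Percent error committed by inverting ``k_eta`` on the wrong lamp's
    calibration: 100*|P_true - P_wrong|/P_true."""
    p_true = unknown_intensity(k_eta, cal_true)
    p_wrong = unknown_intensity(k_eta, cal_wrong)
    return 100.0 * abs(p_true - p_wrong) / abs(p_true)


def beta_from_attributes(species: PhotoSpecies, lamp: LampProfile) -> float:
    """Predict beta_eta directly from per-wavelength attributes:
    beta_eta = k_eta / P0_tot = sum(Phi*eps_A*P0)/(P0_tot*sum(eps_A-eps_B)).

    Invariant under uniform scaling of the lamp profile — it depends
    only on the normalised emission shape — which is what makes an
    a-priori (experiment-free) calibration possible.
    """
    win = restrict_to_support(species, lamp)
    return k_eta_from_attributes(win, lamp) / total_flux(lamp)


@dataclass(frozen=True)
class ProtocolConfig:
    """Inputs to one full actinometric run.

    calibration_series : list of (P0_tot, KineticTrace) at known
        intensities of the same lamp (>= 4 required).
    unknown_trace : trace recorded under the unknown intensity.
    alpha2 : the drug's alpha2 for the lamp window (M).
    """

    calibration_series: tuple
    unknown_trace: KineticTrace
    alpha2: float
    drug_id: str
    lamp_id: str
    through_origin_eta: bool = True
    through_origin_beta: bool = False

    def __post_init__(self):
        if not self.lamp_id:
            raise ValidationError("protocol configuration requires a lamp_id")
        if len(self.calibration_series) < MIN_CALIBRATION_POINTS:
            raise ProtocolError(
                f"protocol requires at least {MIN_CALIBRATION_POINTS} calibration "
                f"intensities; got {len(self.calibration_series)}"
            )


@dataclass(frozen=True)
class ProtocolReport:
    """Structured result of :func:`run_protocol` with every intermediate fit."""

    calibration: ActinometerCalibration
    eta_fits: tuple[EtaFit, ...]
    unknown_fit: EtaFit
    p0_tot_unknown: float

    def as_dict(self) -> dict:
        return {
            "drug_id": self.calibration.drug_id,
            "lamp_id": self.calibration.lamp_id,
            "beta_eta": self.calibration.beta_eta,
            "intercept": self.calibration.intercept,
            "r2": self.calibration.r2,
            "n": self.calibration.n,
            "k_eta_per_intensity": [f.k_eta for f in self.eta_fits],
            "k_eta_unknown": self.unknown_fit.k_eta,
            "p0_tot_unknown": self.p0_tot_unknown,
        }


def run_protocol(config: ProtocolConfig) -> ProtocolReport:
    """Execute the full actinometric workflow on kinetic traces.

    Per known intensity: compute eta(t), fit the line, take k_eta
    (protocol steps 3-5); regress k_eta on P0_tot for beta_eta (step 7);
    fit the unknown-intensity trace and invert P0_tot (steps 9-10).
    """
    fits = tuple(
        fit_eta_trace(trace, config.alpha2, through_origin=config.through_origin_eta)
        for _, trace in config.calibration_series
    )
    points = [(p, f.k_eta) for (p, _), f in zip(config.calibration_series, fits)]
    cal = calibrate(
        points, config.drug_id, config.lamp_id, through_origin=config.through_origin_beta
    )
    unk_fit = fit_eta_trace(
        config.unknown_trace, config.alpha2, through_origin=config.through_origin_eta
    )
    p_unk = unknown_intensity(unk_fit.k_eta, cal, lamp_id=config.lamp_id)
    return ProtocolReport(cal, fits, unk_fit, p_unk)
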