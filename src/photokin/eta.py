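"""Closed-form eta-order kinetics for AB(1Phi) photoreactions whose
photoproduct absorbs the irradiation light.

Under polychromatic irradiation the reactant concentration obeys the
implicit integrated rate law

    (C(t) - C0) + alpha2 * ln(C(t)/C0) = -k_eta * t

a mixture of a zeroth-order (linear) and a first-order (logarithmic)
term, hence a kinetic order of its own.  The left-hand side is written
eta(t); k_eta has the dimension of a zeroth-order rate constant
(M s^-1) and is

    k_eta = sum(Phi * eps_A * P0) / sum(eps_A - eps_B)

with all sums over the lamp's emission window.  The two mixing
coefficients are

    alpha1 = 1 / (l_irr * sum(eps_A - eps_B))          [M]
    alpha2 = C0 * sum(eps_B) / sum(eps_A - eps_B)      [M]

The implicit law inverts in closed form through the principal branch
of the Lambert W function:

    C(t) = alpha2 * W0( (1/alpha2) * exp(b/alpha2) ),
    b = C0 + alpha2*ln(C0) - k_eta*t

evaluated here as alpha2 * wrightomega(b/alpha2 - ln(alpha2)), the
Wright omega form of the same root, which stays finite when the
exponent overflows.  For alpha2 <= 0 (photoproduct out-absorbing the
reactant over the window) no such branch applies and the root is
obtained by bracketed bisection with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import wrightomega

from .errors import DegenerateSystemError, ModelError, ValidationError
from .spectra import LampProfile, PhotoSpecies, ReactorGeometry, lamp_flux_on_grid

__all__ = [
    "EtaParams",
    "total_absorbance",
    "photokinetic_factor",
    "alpha1",
    "alpha2",
    "k_eta_from_attributes",
    "first_order_rate_constant",
    "eta_of_t",
    "concentration_at_time",
    "half_life",
    "initial_velocity",
    "validity_check",
    "ValidityReport",
]

LN10 = math.log(10.0)

#: Total absorbance above which the reduced photokinetic factor 1/A is
#: accepted (the neglected 10^-A term is then at most 1%).
HIGH_ABSORBANCE_THRESHOLD = 2.0


@dataclass(frozen=True)
class EtaParams:
    """Complete parameterisation of one eta-order system.

    alpha1, alpha2 in M; k_eta in M s^-1; C0 = C_A(0) in M;
    window = (lambda_a, lambda_b) in nm.
    """

    alpha1: float
    alpha2: float
    k_eta: float
    C0: float
    window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.C0 <= 0:
            raise ValidationError("C0 must be positive")
        if self.k_eta < 0:
            raise ValidationError("k_eta must be non-negative for a degrading reactant")
        # alpha1 and alpha2 share the sign of sum(eps_A - eps_B)
        if self.alpha1 != 0 and self.alpha2 != 0 and (self.alpha1 > 0) != (self.alpha2 > 0):
            raise ValidationError("alpha1 and alpha2 must share one sign")


def _window_sums(species: PhotoSpecies) -> tuple[float, float]:
    """(sum eps_A, sum eps_B) over the species' (already windowed) grid."""
    return species.eps_A.total(), species.eps_B.total()


def _delta_eps(species: PhotoSpecies) -> float:
    sa, sb = _window_sums(species)
    d = sa - sb
    if d == 0:
        raise DegenerateSystemError(
            "sum(eps_A - eps_B) over the window is zero; the eta-order "
            "coefficients are undefined — use first_order_rate_constant"
        )
    return d


def total_absorbance(
    species: PhotoSpecies, geom: ReactorGeometry, C_A: float, C_B: float
) -> float:
    """Window-summed total absorbance l * sum(eps_A*C_A + eps_B*C_B)."""
    if C_A < 0 or C_B < 0:
        raise ValidationError("concentrations must be non-negative")
    sa, sb = _window_sums(species)
    return geom.l_irr_cm * (sa * C_A + sb * C_B)


def photokinetic_factor(A_tot, reduced: bool = False):
    """Photokinetic factor F of the lumped rate law.

    Full form (1 - 10^-A)/A, continuous at A = 0 where it equals ln 10;
    reduced form 1/A, valid only at high absorbance.
    Accepts scalars or arrays.
    """
    A = np.asarray(A_tot, dtype=float)
    if np.any(A < 0):
        raise ValidationError("total absorbance must be non-negative")
    if reduced:
        if np.any(A == 0):
            raise ZeroDivisionError("reduced photokinetic factor undefined at A = 0")
        out = 1.0 / A
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(A > 1e-9, -np.expm1(-LN10 * A) / np.where(A > 0, A, 1.0), LN10)
    return float(out) if np.isscalar(A_tot) else out


def alpha1(species: PhotoSpecies, geom: ReactorGeometry) -> float:
    """alpha1 = 1 / (l_irr * sum(eps_A - eps_B)) over the window [M]."""
    return 1.0 / (geom.l_irr_cm * _delta_eps(species))


def alpha2(species: PhotoSpecies, C0: float) -> float:
    """alpha2 = C0 * sum(eps_B) / sum(eps_A - eps_B) over the window [M]."""
    if C0 <= 0:
        raise ValidationError("C0 must be positive")
    _, sb = _window_sums(species)
    return C0 * sb / _delta_eps(species)


def _sum_phi_eps_p(species: PhotoSpecies, lamp: LampProfile) -> float:
    flux = lamp_flux_on_grid(lamp, species.grid)
    return float(np.sum(species.qy.value * species.eps_A.value * flux.value))


def k_eta_from_attributes(species: PhotoSpecies, lamp: LampProfile) -> float:
    """Overall eta-order rate constant from per-wavelength attributes.

    k_eta = sum(Phi * eps_A * P0) / sum(eps_A - eps_B), window-summed.
    Independent of C0 and of the optical path; proportional to the lamp
    flux and to the quantum yield.
    """
    return _sum_phi_eps_p(species, lamp) / _delta_eps(species)


def first_order_rate_constant(
    species: PhotoSpecies, lamp: LampProfile, C0: float
) -> float:
    """First-order limit rate constant for sum(eps_A) == sum(eps_B):
    k1 = sum(Phi*eps_A*P0) / (C0 * sum(eps_B)) [s^-1]."""
    _, sb = _window_sums(species)
    if sb == 0:
        raise ModelError("first-order limit needs an absorbing photoproduct")
    return _sum_phi_eps_p(species, lamp) / (C0 * sb)


def eta_of_t(C_t, params: EtaParams):
    """eta = (C - C0) + alpha2 * ln(C/C0); zero at C = C0, non-positive
    and decreasing as C decreases (for alpha2 >= 0)."""
    C = np.asarray(C_t, dtype=float)
    if np.any(C <= 0):
        raise ValidationError("concentrations must be positive to evaluate eta")
    out = (C - params.C0) + params.alpha2 * np.log(C / params.C0)
    return float(out) if np.isscalar(C_t) else out


def _invert_bisection(target_eta: float, params: EtaParams) -> float:
    """Root of eta(C) = target_eta on (0, C0] by bracketed bisection."""
    C0, a2 = params.C0, params.alpha2

    def f(c):
        return (c - C0) + a2 * math.log(c / C0) - target_eta

    lo = 1e-18 * C0
    if a2 < 0:
        # eta(C) has a minimum at C = -alpha2; below it the model has
        # no solution on the physical branch.
        lo = min(-a2, C0)
        if f(lo) > 0:
            raise ModelError(
                "no physical concentration satisfies the rate law at this "
                "time for alpha2 < 0 (model outside its demonstrated regime)"
            )
    return brentq(f, lo, C0, xtol=1e-18, rtol=8.9e-16, maxiter=200)


def concentration_at_time(t, params: EtaParams):
    """Explicit concentration-vs-time inversion of the eta-order law.

    For alpha2 > 0 uses the principal Lambert-W branch in its Wright
    omega form; alpha2 = 0 reduces to the linear (zeroth-order-form)
    trace C0 - k_eta*t clipped at zero; alpha2 < 0 falls back to
    bisection and warns, since that regime is outside the model's
    demonstrated domain.  Accepts scalar or array times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be non-negative")
    C0, a2, k = params.C0, params.alpha2, params.k_eta

    if a2 == 0:
        out = np.maximum(C0 - k * t_arr, 0.0)
    elif a2 > 0:
        b = C0 + a2 * math.log(C0) - k * t_arr
        out = a2 * np.real(wrightomega(b / a2 - math.log(a2)))
        out = np.minimum(out, C0)
    else:
        warnings.warn(
            "alpha2 < 0: sum(eps_B) exceeds sum(eps_A) over the window; "
            "inverting by bisection outside the model's demonstrated regime",
            stacklevel=2,
        )
        out = np.vectorize(lambda ti: _invert_bisection(-k * ti, params))(t_arr)
    return float(out) if np.isscalar(t) else out


def half_life(params: EtaParams) -> float:
    """t_1/2 = (0.5*C0 + alpha2*ln 2) / k_eta [s]; depends on C0 and on
    all spectral attributes through alpha2 and k_eta."""
    if params.k_eta <= 0:
        raise ValidationError("half-life requires k_eta > 0")
    return (0.5 * params.C0 + params.alpha2 * math.log(2.0)) / params.k_eta


def initial_velocity(
    params: EtaParams, species: PhotoSpecies, geom: ReactorGeometry
) -> float:
    """Initial rate r0 = -C0 * k_eta * l_irr * sum(eps_A - eps_B) * F(0)
    with F the full-form photokinetic factor at t = 0 (C_B = 0).
    Approximately independent of C0 once A_tot(0) >> 1."""
    A0 = total_absorbance(species, geom, params.C0, 0.0)
    F0 = photokinetic_factor(A0, reduced=False)
    return -params.C0 * params.k_eta * geom.l_irr_cm * _delta_eps(species) * F0


def params_from_system(
    species: PhotoSpecies,
    lamp: LampProfile,
    geom: ReactorGeometry,
    C0: float,
) -> EtaParams:
    """Assemble EtaParams from spectra, lamp and geometry.

    The species is restricted to the lamp support window first, so every
    sum runs over the emission interval only.
    """
    from .spectra import restrict_to_support

    win = restrict_to_support(species, lamp)
    return EtaParams(
        alpha1=alpha1(win, geom),
        alpha2=alpha2(win, C0),
        k_eta=k_eta_from_attributes(win, lamp),
        C0=C0,
        window=lamp.support,
    )


@dataclass
class ValidityReport:
    """Outcome of the model-applicability checks; flags, not errors."""

    reduced_factor_invalid: bool = False
    c0_outside_linearity: bool = False
    nonpositive_delta_eps: bool = False
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.reduced_factor_invalid
            or self.c0_outside_linearity
            or self.nonpositive_delta_eps
        )


def validity_check(
    species: PhotoSpecies,
    geom: ReactorGeometry,
    params: EtaParams,
    trace_end_absorbance: float,
    linearity_range: tuple[float, float] | None = None,
) -> ValidityReport:
    """Check the assumptions behind the reduced-factor closed form.

    Flags: total absorbance at the end of the trace below the
    high-absorbance threshold (the 1/A approximation breaks); C0 outside
    the declared Beer-Lambert linearity range; non-positive
    sum(eps_A - eps_B) over the window.
    """
    rep = ValidityReport()
    if trace_end_absorbance < HIGH_ABSORBANCE_THRESHOLD:
        rep.reduced_factor_invalid = True
        rep.messages.append(
            f"A_tot falls to {trace_end_absorbance:.3g} < "
            f"{HIGH_ABSORBANCE_THRESHOLD}: reduced photokinetic factor invalid"
        )
    if linearity_range is not None:
        lo, hi = linearity_range
        if not (lo <= params.C0 <= hi):
            rep.c0_outside_linearity = True
            rep.messages.append(
                f"C0 = {params.C0:.3g} M outside calibration linearity "
                f"range [{lo:.3g}, {hi:.3g}] M"
            )
    sa, sb = _window_sums(species)
    if sa - sb <= 0:
        rep.nonpositive_delta_eps = True
        rep.messages.append(
            "sum(eps_A - eps_B) over the window is not positive; the "
            "eta-order coefficients change sign or are undefined"
        )
    return rep
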