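"""Reference numerical integration of the unapproximated photokinetic
rate laws.

Two levels of approximation are exposed so that their gap can be
measured:

* :func:`simulate_perwavelength` integrates the full rate law with a
  per-wavelength photokinetic factor,
  dC_A/dt = -sum_l Phi_l P0_l (A_A,l/A_tot,l) (1 - 10^-A_tot,l),
  the model-free oracle against which everything else is an
  approximation;
* :func:`simulate_lumped` integrates the lumped law
  dC_A/dt = -(sum Phi eps_A P0) l_irr F(t) C_A with a single
  window-summed photokinetic factor F, either in its full
  (1-10^-A)/A form or the reduced 1/A form whose analytic solution
  is the eta-order closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import SimulationError, ValidationError
from .eta import LN10, half_life
from .spectra import (
    LampProfile,
    PhotoSpecies,
    ReactorGeometry,
    lamp_flux_on_grid,
    restrict_to_support,
)

__all__ = [
    "KineticTrace",
    "simulate_perwavelength",
    "simulate_lumped",
    "compare_traces",
    "default_time_grid",
]

RTOL = 1e-11


@dataclass(frozen=True)
class KineticTrace:
    """Sampled concentration-vs-time data for one photokinetic run."""

    t: np.ndarray
    C_A: np.ndarray
    C_B: np.ndarray | None = None
    provenance: str = "simulated"  # simulated | synthetic | measured
    noise_rsd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        ca = np.asarray(self.C_A, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "C_A", ca)
        if t.shape != ca.shape or t.ndim != 1:
            raise ValidationError("t and C_A must be 1-D arrays of equal length")
        if np.any(np.diff(t) < 0):
            raise ValidationError("times must be non-decreasing")
        if ca.size and ca[0] <= 0:
            raise ValidationError("C_A(0) must be positive")
        if self.C_B is not None:
            cb = np.asarray(self.C_B, dtype=float)
            object.__setattr__(self, "C_B", cb)
            if cb.shape != ca.shape:
                raise ValidationError("C_B must match C_A in length")

    @property
    def C0(self) -> float:
        return float(self.C_A[0])

    def with_noise(self, noise_rsd: float, seed: int) -> "KineticTrace":
        """Multiplicative Gaussian noise on C_A (relative error model),
        truncated so concentrations stay positive; C_B dropped."""
        if noise_rsd < 0:
            raise ValidationError("noise_rsd must be non-negative")
        rng = np.random.default_rng(seed)
        factor = np.maximum(1.0 + noise_rsd * rng.standard_normal(self.t.size), 1e-6)
        return KineticTrace(
            self.t, self.C_A * factor, None, "synthetic", noise_rsd, seed
        )


def default_time_grid(params, n: int = 200, half_lives: float = 5.0) -> np.ndarray:
    """t = 0 followed by log-spaced points out to ``half_lives`` times the
    eta-order half-life."""
    t_end = half_lives * half_life(params)
    grid = np.geomspace(t_end / (n * 10), t_end, n - 1)
    return np.concatenate([[0.0], grid])


def _solve(rhs, C0: float, t_grid: np.ndarray) -> np.ndarray:
    sol = solve_ivp(
        rhs,
        (float(t_grid[0]), float(t_grid[-1])),
        [C0],
        t_eval=t_grid,
        method="DOP853",
        rtol=RTOL,
        atol=1e-18 * C0,
    )
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else t_grid[0]
        c_last = sol.y[0, -1] if sol.y.size else C0
        raise SimulationError(f"integrator failed: {sol.message}", t_last, c_last)
    return np.clip(sol.y[0], 0.0, C0)


def simulate_perwavelength(
    species: PhotoSpecies,
    lamp: LampProfile,
    geom: ReactorGeometry,
    C0: float,
    t_grid: np.ndarray,
) -> KineticTrace:
    """Integrate the full per-wavelength rate law; returns both species
    by mass balance (C_B = C0 - C_A)."""
    win = restrict_to_support(species, lamp)
    flux = lamp_flux_on_grid(lamp, win.grid).value
    qy, ea, eb = win.qy.value, win.eps_A.value, win.eps_B.value
    l = geom.l_irr_cm

    def rhs(_t, y):
        ca = max(y[0], 0.0)
        cb = max(C0 - ca, 0.0)
        a_a = ea * l * ca
        a_tot = a_a + eb * l * cb
        # (A_A/A_tot)(1-10^-A_tot) -> A_A*ln10 as A_tot -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            absorbed = np.where(
                a_tot > 1e-12,
                a_a / np.where(a_tot > 0, a_tot, 1.0) * -np.expm1(-LN10 * a_tot),
                a_a * LN10,
            )
        return [-float(np.sum(qy * flux * absorbed))]

    C_A = _solve(rhs, C0, np.asarray(t_grid, dtype=float))
    return KineticTrace(t_grid, C_A, C0 - C_A, "simulated")


def simulate_lumped(
    species: PhotoSpecies,
    lamp: LampProfile,
    geom: ReactorGeometry,
    C0: float,
    t_grid: np.ndarray,
    factor_form: str = "full",
) -> KineticTrace:
    """Integrate the lumped rate law with a single window-summed
    photokinetic factor (``factor_form``: 'full' or 'reduced').

    The reduced form is the ODE whose analytic solution is the
    eta-order closed form."""
    if factor_form not in ("full", "reduced"):
        raise ValidationError("factor_form must be 'full' or 'reduced'")
    win = restrict_to_support(species, lamp)
    flux = lamp_flux_on_grid(lamp, win.grid).value
    rate_sum = float(np.sum(win.qy.value * win.eps_A.value * flux))
    sa, sb = win.eps_A.total(), win.eps_B.total()
    l = geom.l_irr_cm
    reduced = factor_form == "reduced"

    def rhs(_t, y):
        ca = max(y[0], 0.0)
        cb = max(C0 - ca, 0.0)
        a_tot = l * (sa * ca + sb * cb)
        if a_tot <= 0:
            return [0.0]
        F = (1.0 / a_tot) if reduced else (-np.expm1(-LN10 * a_tot) / a_tot)
        return [-rate_sum * l * F * ca]

    C_A = _solve(rhs, C0, np.asarray(t_grid, dtype=float))
    return KineticTrace(t_grid, C_A, C0 - C_A, "simulated")


@dataclass(frozen=True)
class TraceDivergence:
    max_rel: float
    mean_rel: float
    exceeded: bool
    threshold: float


def compare_traces(a: KineticTrace, b: KineticTrace, threshold: float = 0.01) -> TraceDivergence:
    """Max and mean relative deviation of C_A between two traces on an
    identical time grid."""
    if a.t.shape != b.t.shape or not np.allclose(a.t, b.t, rtol=0, atol=0):
        raise ValidationError("traces must share an identical time grid")
    denom = np.maximum(np.abs(a.C_A), 1e-300)
    rel = np.abs(a.C_A - b.C_A) / denom
    return TraceDivergence(float(rel.max()), float(rel.mean()), bool(rel.max() > threshold), threshold)
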