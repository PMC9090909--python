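"""Synthetic AB(1Phi) photosystems: Gaussian-band absorption spectra,
a logistic quantum-yield sigmoid, narrow-band lamp profiles, and noisy
kinetic traces — everything needed to exercise the full analysis
pipeline with known ground truth.

The default system emulates a dacarbazine-like drug: a reactant whose
window-summed absorptivity is roughly three times its photoproduct's,
a quantum yield rising sigmoidally from ~0 below 275 nm to ~0.3 in the
UVA, a mixed 254/365 nm lamp delivering ~1e-4 einstein dm^-3 s^-1
total, an initial concentration of a few 1e-5 M, and 2% multiplicative
(relative) trace noise typical of HPLC quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ProtocolError, ValidationError
from .eta import EtaParams, concentration_at_time, params_from_system
from .simulate import KineticTrace, default_time_grid, simulate_perwavelength
from .spectra import (
    LampProfile,
    PhotoSpecies,
    ReactorGeometry,
    Spectrum,
    UNIT_DIMENSIONLESS,
    UNIT_EPSILON,
    UNIT_PHOTON_FLUX,
    total_flux,
)

__all__ = [
    "GaussianBand",
    "SyntheticSystemSpec",
    "SyntheticSystem",
    "make_system",
    "make_trace",
    "make_intensity_series",
    "DEFAULT_GRID",
]

DEFAULT_GRID = np.arange(200.0, 401.0, 1.0)  # 200-400 nm at 1 nm steps


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band or emission line: centre (nm), standard
    deviation width (nm), peak height (unit of the hosting spectrum)."""

    center_nm: float
    width_nm: float
    peak: float

    def __post_init__(self):
        if self.width_nm <= 0:
            raise ValidationError("band width must be positive")
        if self.peak < 0:
            raise ValidationError("band peak must be non-negative")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return self.peak * np.exp(-0.5 * ((grid - self.center_nm) / self.width_nm) ** 2)


def _bands_to_values(bands, grid):
    out = np.zeros_like(grid)
    for b in bands:
        out = out + b.profile(grid)
    return out


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Recipe for one synthetic photosystem (all stochastic outputs are
    seeded; the spectra themselves are deterministic)."""

    bands_A: tuple[GaussianBand, ...] = (
        GaussianBand(330.0, 28.0, 1.05e4),
        GaussianBand(240.0, 20.0, 6.5e3),
    )
    bands_B: tuple[GaussianBand, ...] = (GaussianBand(270.0, 22.0, 6.2e3),)
    qy_min: float = 0.0
    qy_max: float = 0.3
    qy_midpoint_nm: float = 310.0
    qy_width_nm: float = 18.0
    lamp_lines: tuple[GaussianBand, ...] = (
        GaussianBand(254.0, 4.0, 1.0),
        GaussianBand(365.0, 12.0, 2.0),
    )
    lamp_total_flux: float = 1.0e-4  # einstein dm^-3 s^-1
    C0: float = 5.0e-5  # M
    noise_rsd: float = 0.02
    seed: int = 0
    name: str = "synthetic-drug"
    lamp_id: str = "synthetic-lamp"

    def __post_init__(self):
        if not (0 <= self.qy_min <= self.qy_max <= 1):
            raise ValidationError("quantum-yield bounds must satisfy 0 <= min <= max <= 1")
        if self.qy_width_nm <= 0:
            raise ValidationError("quantum-yield sigmoid width must be positive")
        if self.lamp_total_flux <= 0:
            raise ValidationError("lamp total flux must be positive")
        if self.C0 <= 0:
            raise ValidationError("C0 must be positive")
        if self.noise_rsd < 0:
            raise ValidationError("noise_rsd must be non-negative")
        if self.seed is None:
            raise ValidationError("a seed is mandatory for any stochastic output")


@dataclass(frozen=True)
class SyntheticSystem:
    """A generated system together with its ground-truth parameters."""

    species: PhotoSpecies
    lamp: LampProfile
    geometry: ReactorGeometry
    params: EtaParams  # ground truth, window-restricted
    spec: SyntheticSystemSpec


def make_system(
    spec: SyntheticSystemSpec, geometry: ReactorGeometry | None = None
) -> SyntheticSystem:
    """Build spectra and lamp on the 200-400 nm grid and compute the
    ground-truth eta-order parameters from them.

    The ground truth is obtained through the same closed-form
    attribute equations the analysis uses, restricted to the lamp's
    support window, so generator and analysis agree by construction on
    what the true k_eta, alpha1 and alpha2 are.
    """
    geometry = geometry or ReactorGeometry()
    grid = DEFAULT_GRID
    eps_a = Spectrum(grid, _bands_to_values(spec.bands_A, grid), UNIT_EPSILON)
    eps_b = Spectrum(grid, _bands_to_values(spec.bands_B, grid), UNIT_EPSILON)
    qy_val = spec.qy_min + (spec.qy_max - spec.qy_min) / (
        1.0 + np.exp(-(grid - spec.qy_midpoint_nm) / spec.qy_width_nm)
    )
    qy = Spectrum(grid, qy_val, UNIT_DIMENSIONLESS)
    species = PhotoSpecies(eps_a, eps_b, qy, spec.name)

    shape = _bands_to_values(spec.lamp_lines, grid)
    if shape.sum() <= 0:
        raise ValidationError("lamp lines carry no flux")
    flux = Spectrum(grid, shape * (spec.lamp_total_flux / shape.sum()), UNIT_PHOTON_FLUX)
    lamp = LampProfile(flux, spec.lamp_id)

    params = params_from_system(species, lamp, geometry, spec.C0)
    return SyntheticSystem(species, lamp, geometry, params, spec)


def make_trace(
    system: SyntheticSystem,
    t_grid: np.ndarray | None = None,
    noise_rsd: float | None = None,
    seed: int | None = None,
    generator: str = "closed-form",
) -> KineticTrace:
    """A kinetic trace from the chosen generator, with seeded
    multiplicative Gaussian noise on C_A.

    ``generator``: 'closed-form' evaluates the explicit eta-order
    solution; 'perwavelength' integrates the full per-wavelength rate
    law (slower, approximation-free).
    """
    noise = system.spec.noise_rsd if noise_rsd is None else noise_rsd
    if noise < 0:
        raise ValidationError("noise_rsd must be non-negative")
    seed = system.spec.seed if seed is None else seed
    if t_grid is None:
        t_grid = default_time_grid(system.params)
    if generator == "closed-form":
        c = concentration_at_time(t_grid, system.params)
        trace = KineticTrace(t_grid, c, system.params.C0 - c, "synthetic")
    elif generator == "perwavelength":
        trace = simulate_perwavelength(
            system.species, system.lamp, system.geometry, system.params.C0, t_grid
        )
    else:
        raise ValidationError("generator must be 'closed-form' or 'perwavelength'")
    if noise == 0:
        return replace(trace, provenance="synthetic", seed=seed)
    return trace.with_noise(noise, seed)


def make_intensity_series(
    system: SyntheticSystem,
    scale_factors,
    t_grid: np.ndarray | None = None,
    noise_rsd: float | None = None,
    seed: int | None = None,
    generator: str = "closed-form",
) -> list[tuple[float, KineticTrace]]:
    """Traces at uniformly attenuated copies of the lamp (the synthetic
    analogue of stacking grid-mesh filters), one per scale factor.

    Ground-truth beta_eta is invariant across the series because k_eta
    and P0_tot scale together.  At least 4 factors are required, as for
    a real calibration.
    """
    factors = [float(f) for f in scale_factors]
    if len(factors) < 4:
        raise ProtocolError("an intensity series needs at least 4 attenuation factors")
    if any(f <= 0 for f in factors):
        raise ValidationError("attenuation factors must be positive")
    seed = system.spec.seed if seed is None else seed
    out = []
    for i, f in enumerate(factors):
        lamp_f = system.lamp.scaled(f)
        params_f = replace(system.params, k_eta=system.params.k_eta * f)
        sys_f = SyntheticSystem(system.species, lamp_f, system.geometry, params_f, system.spec)
        trace = make_trace(
            sys_f, t_grid, noise_rsd, seed + 1000 * (i + 1), generator
        )
        out.append((total_flux(lamp_f), trace))
    return out
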