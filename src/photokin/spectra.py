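"""Wavelength-grid data model and radiometric unit conversions.

Every per-wavelength quantity in the package (molar absorption
coefficients, quantum yields, lamp output) lives on a common
nanometre grid held by :class:`Spectrum`.  All summations that enter
the kinetic model run over the lamp's emission window only, which
:func:`restrict_to_support` enforces.

Units are fixed throughout the package: wavelength in nm, molar
absorption coefficients in M^-1 cm^-1, spectral irradiance in
mW cm^-2 nm^-1, volumetric photon flux in einstein dm^-3 s^-1,
concentrations in M, time in s.  No unit inference is attempted; the
unit string on a :class:`Spectrum` is carried as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.constants as const

from .errors import RangeError, ValidationError

__all__ = [
    "Spectrum",
    "LampProfile",
    "PhotoSpecies",
    "ReactorGeometry",
    "align",
    "photon_flux_from_irradiance",
    "total_flux",
    "restrict_to_support",
    "UNIT_EPSILON",
    "UNIT_DIMENSIONLESS",
    "UNIT_IRRADIANCE",
    "UNIT_PHOTON_FLUX",
]

UNIT_EPSILON = "M^-1 cm^-1"
UNIT_DIMENSIONLESS = "dimensionless"
UNIT_IRRADIANCE = "mW cm^-2 nm^-1"
UNIT_PHOTON_FLUX = "einstein dm^-3 s^-1"

#: Lamp support threshold: fraction of the peak flux below which a
#: wavelength is considered outside the lamp's emission window.
SUPPORT_THRESHOLD = 1e-3


@dataclass(frozen=True)
class Spectrum:
    """A per-wavelength quantity sampled on a strictly increasing nm grid."""

    wavelength: np.ndarray
    value: np.ndarray
    unit: str = UNIT_DIMENSIONLESS

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        val = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "value", val)
        if wl.ndim != 1 or val.shape != wl.shape:
            raise ValidationError("wavelength and value must be 1-D arrays of equal length")
        if wl.size == 0:
            raise ValidationError("spectrum must contain at least one sample")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValidationError("spectrum values must be finite")

    def __len__(self) -> int:
        return self.wavelength.size

    @property
    def step(self) -> float:
        """Grid step in nm (nan for a single-point spectrum)."""
        if len(self) < 2:
            return float("nan")
        return float(np.diff(self.wavelength).mean())

    def interp(self, grid: np.ndarray) -> "Spectrum":
        """Linearly interpolate onto ``grid``; extrapolation is refused."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.wavelength[0], self.wavelength[-1]
        if grid.min() < lo or grid.max() > hi:
            raise RangeError(
                f"requested grid [{grid.min()}, {grid.max()}] nm outside "
                f"spectrum range [{lo}, {hi}] nm"
            )
        return Spectrum(grid, np.interp(grid, self.wavelength, self.value), self.unit)

    def window(self, lam_lo: float, lam_hi: float) -> "Spectrum":
        """Truncate to the grid points lying inside [lam_lo, lam_hi]."""
        mask = (self.wavelength >= lam_lo) & (self.wavelength <= lam_hi)
        if not mask.any():
            raise RangeError(f"no grid points inside [{lam_lo}, {lam_hi}] nm")
        return Spectrum(self.wavelength[mask], self.value[mask], self.unit)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelength, self.value * factor, self.unit)

    def total(self) -> float:
        """Plain sum of the sampled values (the discrete sum over the grid)."""
        return float(self.value.sum())

    def same_grid(self, other: "Spectrum") -> bool:
        return len(self) == len(other) and np.array_equal(self.wavelength, other.wavelength)


def _validate_nonneg(spec: Spectrum, name: str) -> None:
    if np.any(spec.value < 0):
        raise ValidationError(f"{name} values must be non-negative")


@dataclass(frozen=True)
class LampProfile:
    """A lamp's volumetric photon-flux spectrum with its emission window.

    The support [lambda_a, lambda_b] is the contiguous span between the
    first and last wavelengths where the flux reaches
    ``SUPPORT_THRESHOLD`` times the peak flux.
    """

    spectrum: Spectrum
    lamp_id: str
    support: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        _validate_nonneg(self.spectrum, "lamp flux")
        if self.spectrum.value.max() <= 0:
            raise ValidationError("lamp has zero flux everywhere; support undefined")
        if self.support is None:
            thr = SUPPORT_THRESHOLD * self.spectrum.value.max()
            idx = np.nonzero(self.spectrum.value >= thr)[0]
            sup = (float(self.spectrum.wavelength[idx[0]]),
                   float(self.spectrum.wavelength[idx[-1]]))
            object.__setattr__(self, "support", sup)

    @property
    def flux_in_support(self) -> Spectrum:
        return self.spectrum.window(*self.support)

    def scaled(self, factor: float) -> "LampProfile":
        """Uniformly attenuated/amplified copy (same support, same id)."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return LampProfile(self.spectrum.scaled(factor), self.lamp_id, self.support)


@dataclass(frozen=True)
class PhotoSpecies:
    """Reactant/photoproduct absorption spectra and the quantum yield.

    eps_A, eps_B (M^-1 cm^-1) and qy (dimensionless, in [0, 1]) must
    share one wavelength grid; use :func:`align` first if they do not.
    """

    eps_A: Spectrum
    eps_B: Spectrum
    qy: Spectrum
    name: str = "species"

    def __post_init__(self):
        if not (self.eps_A.same_grid(self.eps_B) and self.eps_A.same_grid(self.qy)):
            raise ValidationError("eps_A, eps_B and qy must share one wavelength grid")
        _validate_nonneg(self.eps_A, "eps_A")
        _validate_nonneg(self.eps_B, "eps_B")
        _validate_nonneg(self.qy, "quantum yield")
        if np.any(self.qy.value > 1):
            raise ValidationError("quantum yield must not exceed 1")

    @property
    def grid(self) -> np.ndarray:
        return self.eps_A.wavelength

    def window(self, lam_lo: float, lam_hi: float) -> "PhotoSpecies":
        return PhotoSpecies(
            self.eps_A.window(lam_lo, lam_hi),
            self.eps_B.window(lam_lo, lam_hi),
            self.qy.window(lam_lo, lam_hi),
            self.name,
        )


@dataclass(frozen=True)
class ReactorGeometry:
    """Top-illuminated cuvette geometry.

    l_irr_cm : optical path of the collimated beam inside the sample.
    area_cm2 : irradiated (top) surface area.
    volume_dm3 : irradiated sample volume (default 2 mL).
    """

    l_irr_cm: float = 1.0
    area_cm2: float = 1.0
    volume_dm3: float = 2e-3

    def __post_init__(self):
        if self.l_irr_cm <= 0 or self.area_cm2 <= 0 or self.volume_dm3 <= 0:
            raise ValidationError("geometry dimensions must all be positive")


def align(spectra: list[Spectrum], grid: np.ndarray) -> list[Spectrum]:
    """Resample every spectrum onto ``grid`` by linear interpolation.

    Extrapolation is refused: each input must cover the requested grid.
    """
    return [s.interp(grid) for s in spectra]


def photon_flux_from_irradiance(
    E: Spectrum, geom: ReactorGeometry, step_nm: float = 1.0
) -> Spectrum:
    """Convert spectral irradiance to volumetric photon flux.

    P0(lambda) = E * 1e-3 [W] * area * step / (N_A * h * c / lambda) / volume,
    i.e. the radiant power collected by the irradiated area in one
    wavelength bin, divided by the energy of a mole of photons at that
    wavelength and by the irradiated volume.  The result is in
    einstein dm^-3 s^-1 and is linear in E.
    """
    if E.unit != UNIT_IRRADIANCE:
        raise ValidationError(f"expected irradiance in {UNIT_IRRADIANCE!r}, got {E.unit!r}")
    _validate_nonneg(E, "irradiance")
    if len(E) > 1 and not np.isclose(E.step, step_nm):
        raise ValidationError(
            f"grid spacing {E.step} nm does not match declared step {step_nm} nm"
        )
    lam_m = E.wavelength * 1e-9
    power_w = E.value * 1e-3 * geom.area_cm2 * step_nm
    einstein_per_s = power_w * lam_m / (const.N_A * const.h * const.c)
    return Spectrum(E.wavelength, einstein_per_s / geom.volume_dm3, UNIT_PHOTON_FLUX)


def total_flux(lamp: LampProfile) -> float:
    """Total photon flux P0_tot: the sum of per-wavelength flux over the
    lamp's support window (einstein dm^-3 s^-1)."""
    tot = lamp.flux_in_support.total()
    if tot <= 0:
        raise ValidationError("lamp support carries no flux")
    return tot


def restrict_to_support(species: PhotoSpecies, lamp: LampProfile) -> PhotoSpecies:
    """Truncate the species spectra to the lamp's emission window.

    All downstream sums (sum of eps_A, eps_B, Phi*eps*P) must run over
    this window only.  Idempotent.
    """
    lam_lo, lam_hi = lamp.support
    grid = species.grid
    if grid[-1] < lam_lo or grid[0] > lam_hi:
        raise RangeError(
            f"species grid [{grid[0]}, {grid[-1]}] nm does not overlap "
            f"lamp support [{lam_lo}, {lam_hi}] nm"
        )
    return species.window(lam_lo, lam_hi)


def lamp_flux_on_grid(lamp: LampProfile, grid: np.ndarray) -> Spectrum:
    """Per-wavelength flux evaluated on ``grid`` (zero outside the lamp's
    own grid), restricted to the support window."""
    wl = lamp.spectrum.wavelength
    val = np.interp(grid, wl, lamp.spectrum.value, left=0.0, right=0.0)
    lam_lo, lam_hi = lamp.support
    val = np.where((grid >= lam_lo) & (grid <= lam_hi), val, 0.0)
    return Spectrum(grid, val, UNIT_PHOTON_FLUX)
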