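"""Published reference values for the nifedipine (NIF) and dacarbazine
(DBZ) drug-actinometers, usable as fixtures.

These are reported experimental regressions and window-summed
absorptivities for the two drugs in ethanol under four laboratory UV
lamps (short-wave 254 nm, mid-wave 302 nm, long-wave 365 nm, and a
mixed 254/365 nm source).  They let the cross-lamp arithmetic be
reproduced without the underlying spectra, which were never published
in machine-readable form.

Note: the reported table assigns the slope-1365.3 line to the
long-wave lamp while the accompanying discussion treats 1365.3 as the
mixed-lamp value; both labels are recorded here and the line is keyed
by its slope, leaving the conflict unresolved.
"""

from __future__ import annotations

from .actinometry import ActinometerCalibration
from .fitting import CalibrationLine

__all__ = [
    "NIF_LAMP_LINES",
    "nif_calibration",
    "BETA_ETA_LAMP4",
    "TOTAL_EPSILON",
    "DBZ_SINGLE_WAVELENGTH_CALIBRATION",
]

#: NIF k_eta-vs-P0_tot lines per lamp: slope beta_eta (M^-1 s),
#: intercept (M s^-1), r^2, and the label(s) attached to the line.
NIF_LAMP_LINES = {
    548.26: {"intercept": -0.4e-3, "r2": 0.99, "labels": ("Lamp #1",)},
    1109.8: {"intercept": 1.2e-3, "r2": 0.99, "labels": ("Lamp #2",)},
    1365.3: {"intercept": 1.3e-3, "r2": 0.99, "labels": ("Lamp #3", "Lamp #4")},
    779.26: {"intercept": 1.5e-3, "r2": 0.99, "labels": ("Lamp #4",)},
}

#: beta_eta under the mixed-wavelength lamp as quoted in the
#: drug-comparison discussion (M^-1 s).
BETA_ETA_LAMP4 = {"NIF": 1365.0, "DBZ": 211.0}

#: Window-summed molar absorptivities (M^-1 cm^-1) of each drug (A)
#: and its photoproduct (B).
TOTAL_EPSILON = {
    "DBZ": {"A": 1_150_028.96, "B": 344_785.15},
    "NIF": {"A": 1_920_219.56, "B": 1_936_173.24},
}

#: DBZ single-wavelength spectrophotometric calibration:
#: A = 4996 (+/- 2.31% RSD) * C + 0.0007, linear over 1.50-10.74e-5 M.
DBZ_SINGLE_WAVELENGTH_CALIBRATION = CalibrationLine(
    slope=4996.0,
    intercept=0.0007,
    r2=0.999,
    conc_range=(1.50e-5, 10.74e-5),
    mode="single-wavelength absorbance",
    slope_stderr=4996.0 * 0.0231,
)


def nif_calibration(slope: float) -> ActinometerCalibration:
    """The reported NIF calibration line with the given slope, wrapped
    as an :class:`ActinometerCalibration` keyed by its first label."""
    line = NIF_LAMP_LINES[slope]
    return ActinometerCalibration.from_line(
        "NIF", line["labels"][0], slope, line["intercept"], line["r2"]
    )
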