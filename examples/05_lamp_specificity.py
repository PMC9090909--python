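"""Why actinometers are lamp-specific.

beta_eta depends on the lamp's normalised emission shape through the
ratio sum(Phi*eps_A*P0)/P0_tot: two lamps with different shapes over a
species with a wavelength-dependent (sigmoid) quantum yield calibrate
differently, and applying one lamp's calibration to the other commits
a systematic intensity error.  The published worked example on the
nifedipine lines is reproduced at the end.
"""

from photokin import (
    ActinometerCalibration,
    GaussianBand,
    SyntheticSystemSpec,
    beta_from_attributes,
    cross_lamp_discrepancy,
    make_system,
    unknown_intensity,
)
from photokin.datasets import nif_calibration


def system(weights, lamp_id):
    lines = (GaussianBand(300.0, 8.0, weights[0]), GaussianBand(365.0, 8.0, weights[1]))
    return make_system(SyntheticSystemSpec(lamp_lines=lines, lamp_id=lamp_id))


a = system((2.0, 1.0), "uvb-heavy")
b = system((1.0, 2.0), "uva-heavy")
beta_a = beta_from_attributes(a.species, a.lamp)
beta_b = beta_from_attributes(b.species, b.lamp)
print(f"beta_eta, uvb-heavy lamp : {beta_a:.4f}")
print(f"beta_eta, uva-heavy lamp : {beta_b:.4f}")
print(f"shape-driven difference  : {abs(beta_b - beta_a) / beta_b * 100:.1f} %")

k = beta_b * 1e-4  # rate measured under the uva-heavy lamp at 1e-4 flux
err = cross_lamp_discrepancy(
    k,
    ActinometerCalibration("drug", "uva-heavy", beta_b),
    ActinometerCalibration("drug", "uvb-heavy", beta_a),
)
print(f"cross-lamp inversion err : {err:.1f} %")

# The published nifedipine worked example: one measured rate constant
# (0.332 M s^-1) inverted on two different lamps' calibration lines.
p_mixed = unknown_intensity(0.332, nif_calibration(1365.3))
p_lamp2 = unknown_intensity(0.332, nif_calibration(1109.8))
d = cross_lamp_discrepancy(0.332, nif_calibration(1109.8), nif_calibration(1365.3))
print(f"\nnifedipine, slope-1365.3 line : {p_mixed:.3e} M s^-1")
print(f"nifedipine, lamp #2 line      : {p_lamp2:.3e} M s^-1")
print(f"discrepancy                   : {d:.1f} %  (ca. 19%)")
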