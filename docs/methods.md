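# Methods

## Model and assumptions

`photokin` treats the unimolecular phototransformation A —hν→ B in
which the photoproduct B absorbs the irradiation light (the
AB(1Φ)<sub>ε_B≠0</sub> mechanism), driven by a polychromatic source.
The physical picture is a stirred, top-illuminated cuvette: collimated
light enters through the free surface, no scattering, no thermal (dark)
reaction, no back-photoreaction, Beer–Lambert behaviour throughout.
Wavelength-resolved inputs — reactant and photoproduct molar
absorptivities ε_A(λ), ε_B(λ) in M⁻¹ cm⁻¹ and the quantum yield Φ(λ) —
are sampled on a 1 nm grid; the lamp enters as a volumetric photon
flux P₀(λ) in einstein dm⁻³ s⁻¹.

Two rate-law levels are implemented:

1. **Per-wavelength** (module `simulate`, the reference):
   dC_A/dt = −Σ_λ Φ P₀ (A_A/A_tot)(1 − 10^(−A_tot)) with per-λ
   absorbances. This is the physically complete discrete rate law and
   has no closed form.
2. **Lumped**: dC_A/dt = −(ΣΦε_A P₀) l_irr F(t) C_A, where the single
   photokinetic factor F is built from the *window-summed* absorbance
   A_tot^Δλ(t), either in full form (1 − 10^(−A))/A or reduced form
   1/A. The reduced-factor ODE integrates in closed form to the η-order
   law η(t) = (C−C₀) + α₂ ln(C/C₀) = −k_η t.

The lumped law is the model the analysis and actinometry layers are
built on. Its relation to the per-wavelength law is *not* innocuous:
because A_tot^Δλ sums absorbances over every grid point in the window,
a broad-band lamp makes the lumped rate much smaller than the
per-wavelength rate (the denominator grows with the number of absorbing
grid points). The two coincide for effectively monochromatic emission,
and the package's agreement tests use that regime; for broad lamps the
simulator exposes both so the lumping gap can be measured for any
system of interest. Within the lumped description itself the
full/reduced factor gap is bounded by the neglected 10^(−A) term and is
below 1% whenever A_tot ≥ 2, the threshold used by `validity_check`.

All summations run over the lamp's emission window only. The window is
the contiguous span where the lamp flux is at least 0.1% of its peak —
the emission interval has no natural hard edges, and this choice also
keeps Σ(ε_A − ε_B) positive for systems whose photoproduct out-absorbs
the reactant outside the emission region. k_η, α₁, α₂ and β_η are
therefore window-dependent quantities by construction, which is
precisely what makes actinometric calibrations lamp-specific.

## Parameters

| quantity | unit | meaning / default |
|---|---|---|
| l_irr | cm | optical path of the collimated beam; 1 |
| area | cm² | irradiated surface; 1 |
| volume | dm³ | irradiated sample volume; 2×10⁻³ (a 2 mL cuvette) |
| C₀ | M | initial reactant concentration; synthetic default 5×10⁻⁵, within a typical calibration linearity range |
| P₀,tot | einstein dm⁻³ s⁻¹ | lamp total photon flux over the window; synthetic default 1×10⁻⁴ |
| noise RSD | – | multiplicative trace noise; 0.02 (HPLC-grade relative error) |

Internal units are fixed (M, s, cm, dm³, einstein); nothing infers
units from data. Spectral irradiance in mW cm⁻² nm⁻¹ converts to
photon flux as E·10⁻³·area·step·λ/(N_A h c·volume) with CODATA
constants (`scipy.constants`).

## Numerical choices

- **Closed-form inversion.** C(t) = α₂ W₀((1/α₂)e^(b/α₂)) is evaluated
  as α₂·wrightomega(b/α₂ − ln α₂): the Wright omega function is the
  same principal-branch root computed in log space, so the exponent
  never overflows and no bisection fallback is needed for α₂ > 0.
  Verified against independent root bracketing of the implicit law to
  1e-10 relative over randomised parameters. For α₂ = 0 the law
  degenerates to the linear trace C₀ − k_η t (clipped at zero); for
  α₂ < 0 (Σε_B > Σε_A over the window) the branch structure changes,
  the root is found by bracketed bisection and a warning is attached —
  that regime has no demonstrated experimental counterpart. Below
  C/C₀ ≈ e⁻⁷⁰⁰ the exact solution underflows double precision and the
  implementation returns 0.
- **Degenerate window** (Σε_A = Σε_B exactly): α₁, α₂, k_η are
  undefined (removable singularity); a dedicated error directs callers
  to `first_order_rate_constant` = ΣΦε_AP₀/(C₀Σε_B).
- **Reference integrator.** `solve_ivp` with DOP853 at rtol 1e-11,
  atol 1e-18·C₀. The rate laws are smooth and non-stiff; an 8th-order
  explicit method reproduces the analytic solution of the
  reduced-factor ODE to ~1e-10 relative at no extra cost, comfortably
  inside the 1e-8 equivalence budget the tests enforce. Comparisons
  against ODE output are restricted to C ≥ 10⁻⁶·C₀ — six decades of
  decay — below which the solver output sits at its absolute-tolerance
  floor.
- **Wavelength summation** inside ODE right-hand sides is a plain dot
  product at the native 1 nm step; no quadrature weights.
- **Time grids** default to 200 points log-spaced through five
  η-order half-lives, t₁/₂ = (0.5 C₀ + α₂ ln 2)/k_η.
- **η-order fitting** regresses η(t_i), computed from the measured
  concentrations without smoothing (smoothing would bias k_η), against
  t through the origin — the integrated law has no intercept. A
  free-intercept mode is kept as a diagnostic, since experimental
  calibration lines are usually reported with small intercepts. Points
  with C_A below 1% of C₀ are excluded (the log term amplifies noise
  there; threshold configurable). The nonlinear cross-check minimises
  the SSE of the explicit forward model over log k_η on a bounded
  interval spanning four decades, so a guess off by 10× still
  converges.
- **Actinometer calibration** (k_η vs P₀,tot) defaults to a free
  intercept, matching how such lines are reported; the strict
  proportional form is a flag. At least four distinct intensities are
  required.

## The synthetic generator

`synthetic` builds complete systems from minimal shapes: 1–3 Gaussian
bands per absorption spectrum, a logistic sigmoid quantum yield rising
toward long wavelengths, Gaussian lamp lines, and multiplicative
Gaussian concentration noise (truncated to keep C_A > 0). The default
system emulates the dacarbazine regime: window-summed photoproduct
absorptivity about a third of the reactant's, Φ rising from ~0 below
275 nm to 0.3 in the UVA, a mixed 254/365 nm lamp at 1×10⁻⁴ einstein
dm⁻³ s⁻¹ total, C₀ = 5×10⁻⁵ M, 2% noise. Ground-truth parameters are
computed from the generated spectra through the same window-restricted
attribute equations the analysis uses, so generator and analysis agree
by construction on what "truth" is; the double-entry test recomputes
k_η by independent summation.

What the generator does *not* emulate: real band shapes and spectral
baselines, wavelength-dependent detector error, drift between
replicate runs, inner-filter geometry effects, photoproduct
instability, or temperature coupling. Passing the recovery tests
therefore demonstrates the correctness and noise-robustness of the
estimation chain under the model's own assumptions — not the accuracy
of the model for any particular real drug/lamp pair.

Monte-Carlo problem sizes were chosen to keep the whole suite fast
while leaving the medians stable: 200 seeds for the protocol recovery
and k_η-recovery studies, 5-point calibration series, 15–80-point
traces.

## Design choices on genuinely open points

- β_η is stored as the literal ratio k_η/P₀,tot. With both quantities
  in M s⁻¹-commensurate units the ratio is dimensionless, yet the
  published convention quotes β_η in M⁻¹ s; the unit string is carried
  as metadata without resolving the inconsistency.
- The reported nifedipine calibration lines are keyed by slope in
  `datasets`, because the source table and the accompanying text
  attach the 1365.3 slope to different lamps; both labels are stored.
- Calibration registry semantics: strict mode refuses cross-lamp use
  outright; permissive mode warns and proceeds, so the magnitude of
  the error remains measurable (`cross_lamp_discrepancy`).
- CSV/JSON/YAML only; the domain has no entrenched binary format for
  these objects.

## Known limitations

- The α₂ < 0 branch is mathematically serviced but physically
  undemonstrated; results there carry a warning and should not be
  trusted quantitatively.
- Quantum yields are consumed as input spectra; the package does not
  estimate Φ(λ) from polychromatic data.
- No photon-transport modelling beyond the collimated top-illumination
  assumption; strongly scattering or optically thin samples violate
  the model.
- The lumped rate law's gap to the per-wavelength law for broad-band
  lamps is exposed but not corrected; k_η calibrated against a real
  lamp absorbs that gap empirically, which is one more reason the
  calibration is lamp-specific.
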