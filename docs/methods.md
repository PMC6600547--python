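# Methods

This note documents the models implemented in specbind, the defaults and
unit conventions, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was open.

## Units and constants

Energies are kcal mol⁻¹ throughout, with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹;
concentrations are molar internally (CSV readers convert from a declared
unit, default µM); temperatures are Kelvin. Serum-albumin defaults, all
overridable: tryptophan lifetime τ0 = 5.71×10⁻⁹ s, diffusion-controlled
quenching limit 2×10¹⁰ M⁻¹ s⁻¹, mean residue weight M0 = 113.6 g mol⁻¹
(66,437 Da over 585 residues), FRET constants κ² = 2/3, n = 1.33,
Φ = 0.118.

## Fluorescence quenching

The Stern–Volmer fit is unweighted ordinary least squares of F0/F on [Q];
no weighting scheme is imposed because replicate variances are rarely
available at this stage, and the intercept (ideally 1) is reported as a
lack-of-fit diagnostic rather than being constrained. The inner-filter
correction F_corr = F_obs·10^((A_ex+A_em)/2) is the standard multiplicative
form; absorbance columns are optional and the correction is skipped when
they are absent, since raw absorbances are often unrecorded.

The double-log binding fit uses base-10 logarithms; the [Q] = 0 point is
excluded because its logarithm is undefined, and any quenched point with
F ≥ F0 is rejected rather than silently dropped. For data generated by the
pure 1:1 static model, (F0−F)/F = K_SV[Q] exactly, so this fit returns
n = 1 and K_b = K_SV — a round-trip identity the tests rely on.

Mechanism classification is deliberately conservative: "static" requires
K_SV strictly decreasing with temperature *and* every k_q above the
diffusion limit; "dynamic" requires the opposite on both counts; everything
else is "indeterminate". Note that a generator which ties K_b to K_SV and
uses an endothermic van't Hoff truth produces *rising* K_SV with k_q above
the limit — correctly labelled indeterminate, which is also why the
integration test asserts that label for the synthetic bundle.

Van't Hoff analysis treats ΔS as temperature-independent over the fitted
range (here 298–315 K); ΔG(T) = ΔH − TΔS is tabulated per input
temperature and the identity is re-checked row-wise in the report.

## FRET

The overlap integral is evaluated by the trapezoidal rule on the union of
the two wavelength grids after linear interpolation of each spectrum, with
zero extension outside each measured range. λ is converted to cm inside the
numerator so that J carries M⁻¹ cm³ and the prefactor 8.79×10⁻²⁵ of the
R0⁶ relation yields R0 in cm (returned in nm); this convention reproduces
the published pairing J = 3.08×10⁻¹⁴ M⁻¹ cm³ → R0 = 2.96 nm (the package
computes 2.966 nm; the 0.2% gap is rounding of the three-digit J).
Against a 0.01 nm brute-force quadrature of Gaussian band pairs the
trapezoid evaluation agrees to well within 0.1%.

Transfer efficiency is computed from equimolar donor/acceptor intensities
(standard single-point FRET practice). Distances are meaningful only for
0 < E < 1; the validity flags check the 0.5·R0 < r < 1.5·R0 ratio window
and the 2–8 nm FRET range.

## Circular dichroism and denaturation

Helix content uses the Chen relation, helix% = 100(−[θ]₂₂₂−2340)/30300,
clamped to [0, 100] with a warning outside the calibrated range — the
relation is an empirical calibration, not a physical bound.

Denaturation curves are fit to the six-parameter two-state linear
extrapolation model with ΔG(g) = ΔG_D − m·g (positive m destabilises;
C_m = ΔG_D/m) and linear baselines for both states. Initialisation is
data-driven: baselines from OLS on the first/last three points, the
midpoint from where the smoothed, roughly-normalised curve crosses 0.5,
and m0 = 2 kcal mol⁻¹ M⁻¹ (a typical GdmCl m-value for a protein of this
size). Two plateau checks guard identifiability: before fitting, at least
two points must sit below 0.2 and above 0.8 of the initial normalised
curve; after fitting, the *fitted* transition must likewise be bracketed —
this catches curves whose tail masquerades as a plateau. The exponent in
the logistic term is clipped at ±500 to avoid overflow during
optimisation. The midpoint's standard error is propagated from the
(ΔG_D, m) covariance by the delta method. A three-state extension is
deliberately out of scope.

## ITC

The one-site model is the closed-form root of the 1:1 mass-action
quadratic (single set of n identical sites); it is verified in the tests
against an independent Brent root-finder for the bound-ligand
concentration to 10⁻¹⁰ relative across c = n·K_a·[M] from 0.01 to 1000.
Injection bookkeeping follows the perfusion-cell convention: after
cumulative injected volume v, Mt = M0(1−v/2V0)/(1+v/2V0) and
Xt = Xs(v/V0)(1−v/2V0), and each injection's heat includes the
displaced-volume term ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V0)(Qᵢ+Qᵢ₋₁)/2 (toggleable
off).

The fit runs on heats normalised to their largest magnitude and on
log10 K_a: absolute per-injection heats are ~10⁻⁹ kcal and K_a spans
decades, and the raw parameterisation stalls the optimizer's relative
tolerances. Standard errors for K_a are mapped back by the delta method.
When c < 1 — the regime of weak binders like the albumin system emulated
by the generator defaults, c ≈ 0.05 — n and K_a are nearly degenerate
along n·ΔH ≈ const; the fit does not hide this: the `low_c` flag is set
and the covariance-based errors inflate accordingly, so noisy point
estimates can wander far while remaining within their (honest, large)
confidence intervals. Noiseless thermograms are still recovered exactly
because the degeneracy is exact only to first order.

Both Gibbs-energy routes are exposed: ΔG = −RT ln K_a from the fitted
constant, and ΔG = ΔH − TΔS when enthalpy and entropy are supplied
directly; for the published calorimetric table these two routes disagree
(−4.53 vs −5.75 kcal mol⁻¹ at 298 K), and the package reports the
computation it is asked for rather than reconciling them.

## Synthetic data

Generators emulate the study conditions: quencher 0–56 µM in eight points
with F0 = 1000 au (arbitrary scale — only ratios matter), temperatures
298–315 K, GdmCl 0–5 M around a midpoint near 2.4 M with unit-normalised
flat baselines by default, and a VP-ITC-style schedule (1.4 mL cell, 25 µM
macromolecule, 1.25 mM syringe ligand, 25 × 10 µL injections). Noise is
additive i.i.d. Gaussian scaled to a natural per-modality signal (F0, the
baseline separation, the largest injection heat); real instruments add
heteroscedastic and correlated components (detector shot noise, baseline
drift, injection artefacts) that are not modelled, so recovery tests here
demonstrate correctness of the estimators, not instrument-grade error
bars. All generators are bit-reproducible for a fixed seed and echo their
full ground truth.

Default problem sizes (8-point titrations, 15-point denaturation grids,
25-injection thermograms, 200 replicates for stochastic-recovery
summaries) match typical bench practice for these experiments and keep
every analysis interactive.

## Known limitations

- No combined static+dynamic (sphere-of-action) quenching model and no
  global multi-temperature fitting.
- No CD spectral deconvolution (CONTIN/SELCON class); helix content comes
  from the single-wavelength Chen relation only.
- No κ² estimation from structure; single-point FRET efficiency only.
- No raw ITC power-trace integration, multi-site or competitive models.
- Peak location reports the raw-grid maximum; no sub-nm interpolation.
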