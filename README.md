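# specbind

Quantitative analysis of small-molecule binding to serum albumin from
spectroscopic and calorimetric measurements. The package covers the five
standard stages of a solution-phase binding study in one consistent,
unit-checked pipeline:

1. **Fluorescence quenching** — Stern–Volmer analysis of tryptophan
   quenching titrations, `F0/F = 1 + K_SV [Q]`, the bimolecular quenching
   rate constant `k_q = K_SV / τ0`, and the static/dynamic mechanism call
   from the temperature trend of `K_SV` and the diffusion limit.
2. **Binding thermodynamics** — the double-log (modified Stern–Volmer) fit
   `log[(F0−F)/F] = log K_b + n log [Q]` for the association constant and
   stoichiometry, followed by van't Hoff analysis
   `ln K_b = −ΔH°/(RT) + ΔS°/R` and `ΔG° = ΔH° − TΔS°`.
3. **FRET** — spectral overlap integral
   `J = ∫F(λ) ε(λ) λ⁴ dλ / ∫F(λ) dλ`, Förster radius
   `R0⁶ = 8.79×10⁻²⁵ κ² n⁻⁴ Φ J`, transfer efficiency `E = 1 − F/F0`, and
   the donor–acceptor distance `r = R0 ((1−E)/E)^{1/6}`.
4. **Circular dichroism** — mean residue ellipticity
   `[θ] = θ·M0/(10·c·l)`, α-helix content by the Chen relation, and
   two-state chemical denaturation by the linear extrapolation method,
   `ΔG(g) = ΔG_D − m·[g]`, with midpoint `C_m = ΔG_D/m`.
5. **ITC** — the one-site (Wiseman) isotherm with displaced-volume
   injection bookkeeping, fit for `(n, K_a, ΔH°)` with derived
   `ΔG° = −RT ln K_a` and `TΔS° = ΔH° − ΔG°`.

Seeded synthetic-data generators produce every input modality with known
ground truth, so each fitting stage carries generator→fit recovery tests.
Energies are kcal mol⁻¹ (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹), concentrations
molar, temperatures Kelvin.

## Worked example

Fit a noiseless static-quenching titration and run a van't Hoff analysis:

```python
import specbind as sb

tits, truth = sb.synthetic.simulate_quenching_series(dh=16.34, ds=0.0696)
points = []
for T, tit in tits.items():
    fit = sb.stern_volmer_fit(tit)          # K_SV, intercept, kq, SEs
    points.append((T, sb.modified_sv_fit(tit).kb))
vh = sb.vant_hoff_fit(points)
print(f"dH = {vh.dh:.2f} kcal/mol, TdS(298) = {298*vh.ds:.2f}, dG(298) = {vh.dg(298):.2f}")
```

prints

```
dH = 16.34 kcal/mol, TdS(298) = 20.74, dG(298) = -4.40
```

i.e. the generator's enthalpy is recovered exactly from the titration
chain, and at 298 K the entropic term (+20.7 kcal mol⁻¹) dominates the
unfavourable enthalpy to give a spontaneous ΔG of −4.4 kcal mol⁻¹.

The same stages are scriptable from the shell:

```sh
specbind simulate denaturation --outdir data/
specbind denat fit data/denaturation.csv -t 298
specbind run --config analysis.yaml     # full multi-stage pipeline + report
```

`specbind run` consumes a YAML config naming per-stage input CSVs and
constants, and writes `report.json` / `report.md` with all fitted
parameters, standard errors, and automatic internal-consistency checks
(ΔG = ΔH − TΔS, C_m = ΔG_D/m, the FRET efficiency identity).

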