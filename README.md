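# fluorex

Quantitative ¹⁹F NMR chemical-exchange analysis for proteins that
interconvert between conformational states on millisecond-to-second
timescales — the regime of domain motions and fold-switching.

A single ¹⁹F reporter on such a protein shows resonances whose intensities
respond to two kinds of experiment:

- **CPMG relaxation dispersion** quantifies millisecond exchange: the
  effective transverse rate R₂,eff(ν_CPMG) = −ln(I/I₀)/T_CPMG decreases as
  faster pulsing quenches exchange broadening. Single-field series are
  fitted with the Luz–Meiboom fast-exchange model; multi-field,
  multi-condition series are fitted globally with the Carver–Richards
  two-state model, sharing |Δδ| across fields/conditions and (k_i, p)
  across fields, to recover the exchange rate k_i, populations and the
  chemical-shift difference |Δδ| between the exchanging states.
- **Saturation transfer** quantifies slow exchange: saturating one
  resonance drains its exchange partner as
  I(τ) = I₀[k·e^{−τ(k+R₁)} + R₁]/(k+R₁), giving the directed rate k out of
  the observed state (with R₁ fixed from an inversion-recovery fit). The
  two directed rates yield k_s = k_mn + k_nm, populations p_n = k_mn/k_s,
  and ΔG = −RT·ln(p_n/p_m).

The package also deconvolves overlapping resonances into Lorentzians (peak
integrals are an independent population estimate for slow exchange),
assembles the slow × fast equilibria into a four-state conformational model
with free-energy levels, and ships a numerical **Bloch–McConnell
propagator** that serves as the model-free oracle for every closed form,
plus a fully seeded **synthetic-data generator** so the entire pipeline is
testable without experimental data.

## Worked example

Generate a synthetic two-condition, two-field study at the package's
reference ground truth (slow fold-switch rates 1.08/1.23 s⁻¹ apo and
4.2/8.3 s⁻¹ ligand-saturated; millisecond exchange at 4300–8000 s⁻¹) with
1% intensity noise, then run the full analysis:

```bash
fluorex simulate --seed 7 --out fixture/
fluorex pipeline --input-dir fixture/ --out results/ --seed 7
```

The log reports each stage; `results/report.tsv` contains the fitted
parameters. From an actual run at seed 7:

```
apo     k_mn=1.076  k_nm=1.218  ks=2.29  p_active=0.469  dG=0.073
ligand  k_mn=4.229  k_nm=7.688  ks=11.92 p_active=0.355  dG=0.354
active resonance:   |Δδ|=1.211 ppm, k_i=4278 s⁻¹ (apo), 7597 s⁻¹ (ligand)
inactive resonance: |Δδ|=3.125 ppm, k_i=5776 s⁻¹ (apo), p_minor=0.010
```

Read: the slow fold-switch fits recover the generating rates within a few
percent (truth 1.08/1.23 and 4.2/8.3 s⁻¹); ligand binding accelerates the
fold-switch roughly five-fold and shifts the equilibrium toward the
inactive manifold (p_active 0.47 → 0.36); dG is the free-energy difference
G_active − G_inactive in kcal/mol. The active-resonance dispersion is well
determined (|Δδ| truth 1.2 ppm, k_i truth 4300/7300 s⁻¹), while the
inactive-resonance parameters scatter more because its minor state is
populated at only ~1% — exactly the identifiability behavior expected for
so skewed an equilibrium.

The same operations are available as a library:

```python
from fluorex import (default_ground_truth, generate_cpmg_series,
                     fit_carver_richards_global)

truth = default_ground_truth(noise_sigma=0.01, seed=7)
datasets = [generate_cpmg_series(truth, "active", "apo", f) for f in (564.0, 659.0)]
fit = fit_carver_richards_global(datasets)
print(fit.delta_delta, fit.per_condition["apo"].k_i)
```

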