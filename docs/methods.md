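# Methods

## The physical problem

A single ¹⁹F reporter attached to a protein that interconverts between
conformational states gives a 1-D spectrum whose positions, widths and
intensities encode the exchange network. For the glycosyltransferase system
this package is built around, two resonances (near −82.7 and −84.1 ppm)
report on the catalytically active and inactive folds. Two processes
operate on well-separated timescales:

- a **slow fold-switch** (seconds) between the inactive and active
  manifolds, visible as saturation transfer between the two resonances;
- a **fast compact/extended equilibrium** (milliseconds) within each
  manifold, visible as CPMG relaxation dispersion of each resonance.

Combining the two two-state equilibria under timescale separation yields a
four-state model (inactive-compact, inactive-extended, active-extended,
active-compact) with joint populations equal to products of manifold and
conditional populations, and free-energy levels from Boltzmann inversion,
ΔG = −RT ln(p/p_ref) with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298.15 K
by default (both configurable).

## Models

**Constant-time CPMG observable.** R₂,eff(ν) = −ln(I(ν)/I₀)/T_CPMG with
T_CPMG = 3.84 ms. Only refocusing frequencies ν = n/(2·T_CPMG) for integer
pulse counts n are realizable; the default acquisition grid takes 14 of the
first 46 multiples (130.2–5989.6 s⁻¹), log-uniformly subsampled with both
endpoints forced.

**Luz–Meiboom (fast exchange).**
R₂,eff = (c/k_app)[1 − (4ν/k_app)·tanh(k_app/4ν)] + R₂,₀ with
c = p_A·p_B·Δω². Populations and shift difference are not separable;
single-field data are fitted with this model and only (k_app, c, R₂,₀)
reported.

**Carver–Richards (all timescales).** With
ψ = (p_B−p_A)²k² − Δω² + 4p_Ap_Bk², ξ = 2Δω(p_B−p_A)k,
η± = (1/(√8·ν))·√(±ψ + √(ψ²+ξ²)), D± = ½[±1 + (ψ+2Δω²)/√(ψ²+ξ²)]:

R₂,eff = R₂,₀ + ½(k − 2ν·arccosh(D₊cosh η₊ − D₋cos η₋)).

The expression is symmetric under p_A ↔ p_B; only the minor-population
branch p_B ∈ [0, 0.5] is fitted. The arccosh argument is clamped to 1 when
it undershoots by < 10⁻⁹ (floating-point guard); larger violations raise.
For η₊ > 350 the asymptotic form arccosh(z) ≈ ln D₊ + η₊ avoids cosh
overflow.

**Saturation transfer (Forsén–Hoffman).** With the partner resonance held
saturated, the observed intensity decays as
I(τ) = I₀[k·e^{−τ(k+R₁)} + R₁]/(k+R₁), where k is the rate *out of* the
observed state and R₁ its longitudinal rate. Observing each resonance in
turn yields both directed rates; k_s = k_mn + k_nm, p_n = k_mn/k_s, and
ΔG = −RT ln(p_n/p_m) follow, with first-order error propagation from the
rate standard errors.

## The Bloch–McConnell oracle

Every closed form is validated against direct numerical propagation of the
two-site evolution equations (`bloch_mcconnell`), with ideal instantaneous
180° pulses (complex conjugation of M⁺) and ideal saturation (the saturated
site's longitudinal magnetization pinned at zero) — the same idealizations
the closed forms assume.

For CPMG the default observable is the decay rate of the dominant
eigenvalue of the two-pulse unit-cell propagator E·conj(E)·conj(E)·E. This
is exactly the quantity the Carver–Richards expression describes (agreement
is at machine precision for equal intrinsic R₂), independent of how the
initial magnetization projects onto the decaying modes. A second
observable, `"magnitude"`, propagates equilibrium magnetization through the
full train and applies the intensity-ratio definition to the observed-site
amplitude; it additionally carries the spectral amplitude factor and can
differ from the closed form by several percent at low ν when the minor
population is large. The eigenmode observable is the package default
because it is the physically meaningful asymptotic rate and the one the
fitted model parameterizes; the magnitude observable is retained for
studying amplitude-factor effects.

Saturation-transfer traces are integrated with LSODA at rtol 10⁻⁹ and agree
with the closed form to better than 10⁻⁶ relative. Lineshapes come from the
resolvent Re[1·(iωI − L)⁻¹·p], which reduces to Lorentzians of FWHM R₂/π Hz
without exchange and coalesces at the population-weighted shift in the fast
limit.

## Synthetic data

The generator's defaults are the study conditions: 14 realizable ν values
at two fields (564 and 659 MHz), 8 log-spaced saturation times in
25–1000 ms, ≥10 inversion delays in 25–800 ms, additive Gaussian intensity
noise of σ = 0.01·I₀, and the reference parameter set
(slow rates 1.08/1.23 s⁻¹ apo and 4.2/8.3 s⁻¹ ligand-saturated; fast
exchange 4300→7300 s⁻¹ with p = 0.81/0.19→0.70/0.30 and |Δδ| = 1.2 ppm on
the active resonance, 8000→5100 s⁻¹ with p = 0.009→0.026 and |Δδ| = 2.9 ppm
on the inactive one). Values not fixed by the reference study were chosen
once as field-typical: R₁ = 1.5 s⁻¹ for a ¹⁹F methyl-like reporter on a
~45 kDa protein, intrinsic R₂ of 30 s⁻¹ at 564 MHz rising to 40 s⁻¹ at
659 MHz (chemical-shift-anisotropy broadening grows with field; it is
emulated by per-field R₂ inputs, not derived from CSA theory).

All generators are pure functions of (truth, seed). Titration spectra use
the exact two-component binding quadratic (K_D = 0.23 µM default) and
interpolate shifts and slow-exchange parameters linearly with bound
fraction, so spectra stop changing once ligand exceeds protein
stoichiometry.

What the generator does **not** emulate: time-domain acquisition artifacts
(phase, apodization, baseline roll), scalar coupling, non-ideal pulses and
finite-B₁ saturation, temperature drift, and per-point noise heterogeneity
from differing transient counts. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated noise model, not
robustness to every artifact of real spectrometers.

## Fitting choices

- Bounded trust-region least squares throughout (lmfit); bounds
  p ∈ [0, 0.5] (minor branch), rates ∈ [0, 10⁷ s⁻¹], |Δδ| ∈ [0, 20 ppm].
- Uniform weights by default (per-point σ of the original acquisitions is
  unknown); per-point σ can be supplied.
- Global dispersion fit sharing: |Δδ| shared across all datasets of a
  resonance; (k_i, p) shared across fields within a condition, free across
  conditions; R₂,₀ free per dataset (the most conservative choice; sharing
  R₂,₀ across conditions is a one-line change).
- Multi-start over k_i ∈ {10², 10³, 3·10³, 10⁴} × p_minor ∈ {0.01, 0.05,
  0.1, 0.3} (16 starts) to escape the well-known k/p degeneracy valleys;
  best final objective wins, ties broken toward smaller k_i.
- Inversion-recovery amplitude is free (I = A − B·e^{−R₁τ}) so imperfect
  inversion does not bias R₁; B = 2A is the generator's default but not
  assumed by the fit.
- Saturation-transfer fits hold R₁ fixed, taken per resonance per condition
  from the inversion-recovery fit; the provenance is recorded on the
  series.
- Uncertainties: covariance at the optimum by default; a seeded
  residual-bootstrap is available and reported side by side when requested.
  Neither is claimed to replicate any particular published ± convention.
  Calibration tests show the covariance errors from 8-point
  saturation-transfer fits are modestly under-dispersed (z-scores spread
  ~1.6), as expected when σ is estimated from few residuals of a nonlinear
  model — consistency checks against propagated uncertainties therefore use
  replicate calibration rather than single-draw 1σ bands.

## Degenerate inputs and flags

Flat dispersions pin c (or |Δδ|) at zero and flag the exchange parameters
unidentifiable; flat saturation decays flag the rate as indistinguishable
from zero; constant inversion-recovery series flag `no_decay`. Parameters
that finish at a bound are flagged. Non-convergence is always flagged,
never silent. Single-field global fits run but record a degeneracy warning.

## Problem sizes

The validation suite runs dispersions of 14 points × 2 fields × 2
conditions, 8-point saturation decays, and 20-seed replicate studies; the
full pipeline (fixture generation through report) completes in a few
seconds, and the entire test suite in under a minute on one core. These
sizes match the reference acquisitions, so nothing is scaled down.

## Known limitations

- Two-site closed forms only; no three-site models, no off-resonance R1ρ.
- No model selection (2- vs 3-state) — the state count is an input.
- The assignment of the dispersion fit's minor population to the compact or
  extended conformation is interpretive (made from solvent-exposure shift
  arguments), not determined by the fit; `assemble_four_state_model`
  exposes it as an override.
- Free-energy *barriers* are not estimated — rates are reported as rates,
  with no transmission-prefactor assumption.
- Display rounding in reports is round-half-even; full precision is kept in
  machine-readable columns.
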