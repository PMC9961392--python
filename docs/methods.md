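# Methods

This note documents the models implemented in `hgdiff`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Chemical system and reference data

The package ships four reference tables as CSV under `hgdiff/data/`:
ternary mutual-diffusion coefficients of NaSal + Na₄EtRA and NaSal + β-CD
at 0.010 mol dm⁻³ total solute (five compositions each, X₁ = 0…1, 298.15 K),
limiting diffusivities of the free salicylate ion (0.918), β-CD (0.436) and
their 1:1 complex (0.421, all ×10⁻⁹ m² s⁻¹), and limiting ionic
conductivities of Na⁺ (50.1), Sal⁻ (34.5) and EtRA⁴⁻ (229.3, all
×10⁻⁴ S m² mol⁻¹).

Each diffusion table has an `as_printed` and a `corrected` variant. The
corrections — recorded machine-readably in `data/corrections.json` — fix
three internal inconsistencies in the printed tables: a mid-series row whose
concentrations (0.0005/0.0005) contradict the stated 0.010 total, an X₁
column inconsistent with its own C₁, C₂ (X₁ = C₁/(C₁+C₂) is definitional,
so X₁ is recomputed from concentrations), and an X₁ = 0 endpoint whose host
concentration (0.008) contradicts both the series total and the
accompanying description of that endpoint (0.010). Two further
discrepancies are flagged but deliberately not "fixed": the β-CD binary
limit is quoted as 0.460 in prose but tabulated as 0.436 (the tabulated
value is used everywhere), and the EtRA⁴⁻ limiting diffusivity is quoted as
0.384 while the conductivity route gives 0.382 (both are carried; agreement
is not forced).

Units at every interface: concentrations in mol dm⁻³, diffusivities in
10⁻⁹ m² s⁻¹; SI internally where a formula requires it. Constants are
CODATA; temperature defaults to 298.15 K.

## Nernst (zero-current) coupled diffusion

For the charged system the limiting-law prediction treats each ion as an
independent diffuser subject to the diffusion potential that enforces zero
net current: J_i = −D_i⁰[∇c_i − (z_i c_i/S) Σ_k z_k D_k⁰ ∇c_k] with
S = Σ z_j² c_j D_j⁰. Solute coefficients follow by the stoichiometric chain
rule, each solute's flux identified with its distinguishing anion (Sal⁻ or
EtRA⁴⁻) — the standard common-ion bookkeeping for mixed electrolytes with a
shared cation. The model:

* reduces exactly to the binary Nernst–Hartley closed form
  (z₊+|z₋|)D₊D₋/(z₊D₊+|z₋|D₋) when one solute is absent, and to the tracer
  limit D⁰ of the dilute species;
* conserves charge flux identically (Σ z_i J_i = 0 for any gradient), which
  is property-tested on random electroneutral systems;
* depends only on concentration ratios (no ionic-strength dependence) —
  it is a limiting law, with no electrophoretic or relaxation corrections.

β-CD is neutral, so the zero-current construction does not apply to the
cyclodextrin system; where a prediction is needed there, β-CD is treated as
an uncharged tracer with constant diffusivity. This is a documented
limitation, not a model claim.

## Taylor dispersion

The two-mode peak model is evaluated as
V(t) = V₀ + V₁·t + V_max√(t_R/t)[W₁e^(−12D₁(t−t_R)²/(r²t)) + (1−W₁)e^(−12D₂(t−t_R)²/(r²t))].
Two transcription choices were made for dimensional consistency: the
baseline-slope term multiplies t, and both exponents carry the full
divisor r²t. Weights are normalized (W₁ + W₂ = 1) but not confined to
[0, 1]: strong cross-diffusion legitimately produces weights outside that
interval.

Instrument defaults are a 30.480 m tube of internal radius 0.3220 mm at
0.17 mL min⁻¹ with 5 s sampling. The geometric retention time L/u of this
configuration is ≈3.5×10³ s; retention time is nonetheless always a *free*
fit parameter, the geometric value serving only to initialize the
optimizer, because published retention times for such setups need not match
the nominal geometry. Detector sensitivities R₁, R₂ default to 1:1 and are
configurable; injections are modelled as delta perturbations (63 μL into a
~10 mL tube volume justifies this).

**Fitting.** `fit_peak` uses multi-start Levenberg–Marquardt with
moment-based initialization (linear baseline from the trace edges, apex →
t_R, peak variance → apparent D via σ² = r²t_R/24D) and a noise-floor
stopping rule estimated from the edge samples. Two degeneracies are
flagged rather than silently reported: coincident modes (D₁ ≈ D₂) and a
mode carrying no amplitude — in both cases W₁ is returned as NaN with
`w1_identifiable=False`.

**Inversion.** `invert_dik` recovers the four D_ik from ≥2 fitted peaks
with linearly independent injections by inverting the eigenmode map
(eigenvalues shared across fits, one weight per injection) with
`scipy.optimize.least_squares`. Eigenvalues are pooled across fits weighted
by each mode's visibility |W| in each peak — an axis injection often
renders one mode nearly invisible in its own peak, and an invisible mode
constrains its eigenvalue poorly. Fits whose visible-mode eigenvalues
disagree beyond 5 % raise a data-inconsistency error.

**Joint refinement.** The two-stage route (fit each peak, then invert)
discards inter-peak coupling and plateaus at a few percent error on cross
terms. `refine_dik` therefore refits all raw traces simultaneously with the
four D_ik shared and per-peak baseline/amplitude/retention-time nuisance
parameters, started from the two-stage solution. At peak SNR 10³ this
recovers random valid matrices to within 1 % of the largest coefficient in
≥95 of 100 seeded replicates (the packaged replicate study,
`synthetic.taylor_roundtrip_study`). Error is quoted relative to the
largest |D_ik| because small cross terms (~0.03–0.05×10⁻⁹ m² s⁻¹) carry
tens of percent relative uncertainty even in careful measurements; the
matrix-scale metric matches the ±0.025×10⁻⁹ m² s⁻¹ precision typical of
cross coefficients.

## 1:1 binding model

Speciation is the smaller root of K_a x² − (K_a(C₁+C₂)+1)x + K_aC₁C₂ = 0,
evaluated in the cancellation-free form 2c/(−b+√(b²−4ac)); mass balance and
mass action hold to 10⁻¹² relative over 10⁴ random draws (property-tested).
The sensitivities ∂x/∂C_i come from implicit differentiation —
∂x/∂C₁ = K_a(C₂−x)/(1 + K_a(C₁−x) + K_a(C₂−x)) — and are verified against
central finite differences to 10⁻⁶.

The complex diffusivity defaults to the volume-additivity combination
(D_G⁻³ + D_H⁻³)^(−1/3) = 0.421×10⁻⁹ m² s⁻¹ on the tabulated free-species
values, with an override parameter: the alternative literature figure
0.400 is not self-consistent with the combination rule, and internal
consistency was preferred.

**K_a estimation** minimizes the weighted sum of squared *relative*
residuals over a configurable subset of the four coefficients, D12 only by
default: D12 is the binding-sensitive observable, whereas D11 in the
drug-rich limit is dominated by electrolyte coupling that this
complexation-only model cannot represent (the measured 1.055 vs the model
ceiling D_G = 0.918 at X₁ = 1); including D11 would bias K_a downward.
Uncertainty comes from the curvature of the residual profile at the
minimum — with five composition rows a bootstrap would be theatre. On the
measured β-CD table the default fit gives K_a ≈ 101 ± 86 dm³ mol⁻¹,
compatible with the literature value 80 but with structured residuals
(|D12| underpredicted at X₁ ≥ 0.5 at K_a = 80); the per-row residual report
is always emitted, and no agreement claim is enforced.

## Stoichiometry

The Job response is modelled as proportional to the equilibrium complex
concentration at fixed total concentration (molar-absorptivity differences
fold into the proportionality constant; an optional linear free-species
background exists but defaults to off, since baseline handling in published
continuous-variation data is rarely stated). The maximum is located by
quadratic interpolation through the three points bracketing the discrete
maximum; a 1:1 complex peaks at x = 0.5, a 1:2 guest:host complex at 1/3
(other small integer stoichiometries are solved by bracketed
root-finding). A maximum on the boundary is reported as
no-complexation, not as a ratio.

The NMR titration model is the standard 1:1 fast-exchange population
average Δδ = Δδ_max·[GH]/C_guest, fitted globally: one shared K_a, one
Δδ_max per proton. Shift displacements are stored *signed* (δ_free −
δ_complex) — shielding on inclusion gives negative values for some protons,
and the sign is diagnostic, so it is never rectified. Default titration
conditions mirror the study: 2.9 mM guest, host added to molar ratio ≈2.75.

## Synthetic data

Generators are pure functions of (parameters, seed) via
`numpy.random.Generator`; no global RNG is touched, and every dataset is
paired with a serialized `TruthRecord`. Noise models: additive i.i.d.
Gaussian for detector traces and Job/titration responses; multiplicative
Gaussian for diffusion tables, matching the roughly constant relative
uncertainty of measured coefficients. Defaults are the study conditions
(0.010 mol dm⁻³ total solute, five-point composition grids, 5 s sampling,
peak SNR 10³ ≙ σ = V_max/1000, 1 % relative table noise, K_a = 80).

What the generators do *not* emulate: baseline drift, spikes or correlated
detector noise, finite injection volume, tube coiling and secondary-flow
corrections, activity-coefficient effects, and any stoichiometry beyond the
Job-curve generator's small integers. Passing round-trip tests therefore
demonstrates correctness of the estimators under the stated noise models,
not robustness to every instrumental artefact of real traces.

## Problem sizes

The replicate studies are sized for desk-scale runs: 100 seeded replicates
for the Taylor chain (two 577-point traces each), 20 replicates × three
K_a values for the binding recovery study, 10⁴ random draws for the
equilibrium invariants, 201-point Job grids. These sizes give stable
pass/fail statistics while keeping the full suite in the low minutes.

## Known limitations

* The Nernst predictor is a limiting law; quantitative agreement with
  measured coefficients at 0.010 mol dm⁻³ is not expected (nor observed —
  it is a qualitative fingerprint).
* The complexation diffusion model assumes composition-independent species
  diffusivities and no electrostatic coupling; its D11 prediction fails in
  the drug-rich limit by construction.
* `invert_dik` assumes the peaks share eigenvalues (same composition);
  slow composition drift across injections is not modelled.
* K_a from five compositions has a wide, asymmetric uncertainty; the
  curvature-based standard error is indicative only.
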