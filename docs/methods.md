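# Methods

This note records the models behind `granudry`, the parameter choices that
matter, what the synthetic-data generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Drying model

A fluidised bed of wet granules (dry solids mass m_s, adsorbing-excipient
mass m_adsorb) is dried by a gas stream φ_g. Water leaves the granules
through a network of mass-transfer resistances; in the plug-flow limit the
gas picks up

C_g,out − C_g,in = f_MTR (1 − S_in) C_S\*,  f_MTR = 1 − exp(−m_s/(Ω_tot f_s ρ_s φ_g)),

where C_S\* = a_w P\*(T_bed)/(R T_bed) is the saturation concentration over
the granule surface, S_in = C_g,in/C_S\* the inlet saturation, f_s the solids
volume fraction and ρ_s the skeletal density. The total resistance is
parametrised as a constant external gas-film term plus an internal term that
grows exponentially as the dry-basis moisture F_w = m_w/m_adsorb falls:

Ω_tot(F_w) = Ω_ext + Ω_max exp(−(F_w − F_w,end)/F_w,crit).

Thermodynamics close the model: P\*(T) is an Antoine correlation anchored to
2339.1 Pa at 20 °C; the water activity a_w(F_w) inverts the formulation's
aggregate GAB isotherm (a quadratic in k_w·a_w, solved in closed form), and
is pinned at 1 whenever F_w exceeds the isotherm capacity at saturation —
the free-water regime that produces the constant-rate drying period. The
constant-rate/falling-rate transition emerges near F_w ≈ 0.35 at the default
operating point.

Assumptions: quasi-steady gas residence (bed state frozen on the gas transit
time); ideal-gas conversions at inlet conditions; no bed hydrodynamics,
particle-size or attrition effects; no temperature dependence of the GAB
parameters; liquid and solid phases in local equilibrium (one common C_S\*).

## Forward simulation (synthetic batches)

`simulate_drying` steps the water inventory explicitly with dt ≤ 1 s (the
dynamics are minutes-scale, so Euler is ample) and solves the quasi-steady
evaporative heat balance φ_g c_air (T_in − T_bed) = Ṅ_w ΔH_vap for T_bed at
each step. The undamped fixed-point map T ← T_in − β C_S\*(T) has gain ≈ 1.4
around 15 °C (dC_S\*/dT ≈ 0.04 mol m⁻³ K⁻¹), so a relaxation factor of 0.5
is applied; tolerance 1e-6 °C, at most 100 iterations, error on
non-convergence names the step. The run ends at the requested duration or
when the rate falls below 1e-9 mol/s.

Default operating point (the package's reference conditions): initial
moisture 34 wt%, m_s = 0.331 kg, m_adsorb = 0.118 kg, f_s = 0.40,
ρ_s = 1500 kg/m³, 600 L/min at 25 °C, inlet water concentration
C_g,in = 0.36 mol/m³ (≈28% RH at 25 °C), ΔH_vap = 44 kJ/mol,
c_air = 1200 J m⁻³ K⁻¹, Ω_ext = 0.028 s, Ω_max = 0.58 s, F_w,crit = 0.10.
These jointly reproduce the expected batch envelope: ~0.17 mol/min plateau
rate, ~10 °C bed-temperature depression, ~55 min to 5 wt%, equilibrium near
1.5 wt% set by the inlet humidity through the isotherm.

## Synthetic NIR signal

`generate_spectra` emits one intensity scan per second on the 401-point
1750–2150 nm grid: I = dark + (bright − dark)·10^(−A·g) + ε, with a Gaussian
water band at 1940 nm (width 35 nm), a flat-plus-slope baseline, per-scan
lognormal gain g (sd 0.2 — the scatter of variable probe–solid contact),
additive detector noise (sd 100 counts on a 500/20000 dark/bright range),
air-gap dropout scans (probability 0.03, ~1–3% signal) and Poisson fouling
episodes (~1 per 30 min, 0.03 AU, decaying at 1/300 s⁻¹). Every artefact can
be switched off via `OpticsConfig`.

The apparent band amplitude follows a *concave* response,
log(1 + f_w/f_ref)/log(1 + 1/f_ref) with f_ref = 0.005 chosen below the
working moisture range: diffuse reflectance from wet granules saturates
(path-length and band-saturation effects), which is precisely why a
log-moisture calibration is linear on the real instrument. Setting
`response_ref_moisture = 0` recovers a strictly linear response for unit
tests. What the generator does *not* emulate: slow ambient drift of inlet
temperature/humidity, batch-to-batch granulate variation, structured
(wavelength-correlated) detector noise, and probe-window history effects —
so passing recovery tests demonstrate correctness of the analysis chain
under the stated noise model, not robustness to every plant disturbance.

## Preprocessing

Fixed order: 10-scan block average of intensities (trailing partial block
dropped) → absorbance −log₁₀((I−dark)/(bright−dark)), transmittance clipped
at 1e-6 with a logged count → causal 75-spectrum moving mean (expanding
window during warm-up, warm-up length recorded in metadata) → SNV only for
the monitoring branch → mean-centring owned by the model-fitting stage,
which stores the training mean. The 75-spectrum filter centres ~370 s in the
past; consumers that pair spectra with concurrent state must account for
this lag (see MSPC below).

## PLS moisture calibration

NIPALS PLS1 on mean-centred spectra and mean-centred log₁₀ moisture;
component loop tolerance 1e-10 (≤500 iterations; for a single response it
converges in one pass). The regression vector is b = W(PᵀW)⁻¹q with
b₀ = ȳ − x̄·b on the uncentred scale. Base-10 is used consistently for the
transform and the 10^ŷ back-transform. Each LOD sample is paired with the
nearest preprocessed spectrum within 30 s. The latent-variable count comes
from contiguous-block cross-validation (time order preserved — adjacent
smoothed spectra are strongly correlated, so random folds would leak) with a
one-standard-error rule; because fold RMSEs are strongly correlated across
candidate counts, the SE is that of the paired fold-wise difference against
the best candidate — the naive per-candidate SE systematically collapses the
choice to one component and underfits the artefact directions. Default: 5
folds, up to 5 components. Full spectral range by default.

## MSPC endpoint detection

PCA by SVD of SNV-normalised, mean-centred endpoint spectra; the component
count is cross-validated by row folds with a wavelength split (scores of a
held-out row estimated from half the channels, reconstruction error scored
on the other half) because plain row-held-out PRESS is monotone
non-increasing in the component count. Residual eigenvalues below 1e-12 of
the leading one are truncated before forming the Jackson–Mudholkar moments.

Two constructions matter in practice. First, training spectra must come from
several normal-operation batches (default 7): within one batch the smoothed
rows are serially correlated, leaving only a handful of independent noise
directions that PCA would absorb, collapsing the limit and pushing every
fresh batch permanently off-plane. Second, each smoothed spectrum is
labelled by the moisture of the material it actually measured — the causal
window's centroid, (window−1)/2 spectra in the past — when selecting
"endpoint" (< 2 wt%) training rows; with same-timestamp labels the training
cloud includes wetter material and the chart fires while the batch is still
at ~3 wt%. With both in place the endpoint lands just below the 2 wt%
criterion and truncated batches are never flagged. The reported endpoint is
the *first* of the 10 consecutive sub-limit observations (a deliberate
choice between first and last; reports use 1-based indices).

## Mass-transfer analysis

Traces are resampled to the 10 s post-preprocessing cadence. The drying rate
at each point is the negative slope of a 72-point (720 s) linear regression
of N_w(t); edge points (truncated windows) and points where the slope
changes by more than half its value between the two window halves are
flagged low-confidence and excluded from fitting — the latter guards the
windowed derivative against trajectory knees sharper than the window (for
fast-transitioning batches, e.g. without internal resistance, a shorter
window should be chosen to resolve the falling-rate phase). f_MTR is clipped
to (1e-6, 1−1e-6) before the logarithm and clipped points are excluded. The
resistance curve is fitted by nonlinear least squares on log₁₀ Ω (the data
span two decades; a linear-space fit would ignore the external plateau),
with positivity enforced by log-parametrisation, three F_w,crit starts and
delta-method standard errors; F_w,end is fixed to the final observed F_w
rather than co-estimated.

The inlet humidity is rarely measured, so `estimate_inlet_concentration`
implements the plant heuristic: choose C_g,in so the outlet is saturated at
the time of maximum smoothed rate (first 5 min excluded). This estimator is
well-posed only when the outlet truly is near-saturated there; by
construction it forces the estimated f_MTR to 1 at that time, so on a batch
whose plateau efficiency is below ~0.95 it destroys the identifiability of
Ω_ext (on real plants, ambient drift and noise mask this). `analyze_run`
therefore accepts `inlet="known"` to use a recorded or configured inlet
concentration — the right choice for synthetic-twin recovery experiments and
instrumented dryers — with `"estimate"` retained as the field procedure.

The aggregate isotherm sums the mass-weighted GAB uptake of *all* components
(mannitol's small uptake included in the numerator) and divides by the
adsorbing mass (118 g: Avicel, Hypromellose, Ac-Di-Sol); a single GAB curve
is then refitted on a_w ∈ {0.02, …, 0.94} (unweighted, multi-start over
C ∈ {1, 10, 100}, k ∈ {0.5, 0.8, 0.95}).

## Problem sizes and verification

The test-suite and acceptance experiments use one 120 min batch at 1 s
simulation resolution (≈7200 steps, 7200 synthetic scans of 401 channels,
18 LOD samples), 7 training plus 5 monitored batches for the endpoint study,
10⁵–10⁶ Monte-Carlo draws for the control-limit calibration, and 50 random
problems for the NIPALS/SVD cross-check — sizes at which every check runs on
one CPU in seconds while leaving the statistics sharp enough for the stated
tolerances. Parameter recovery under 2% moisture noise lands within ±5% of
Ω_ext and ±10% of F_w,crit across seeds, comfortably inside the ±15%/±25%
acceptance bands.

## Known limitations

* The resistance parametrisation is empirical; it summarises, not derives,
  the internal transport physics (no shrinking-core or diffusion model).
* Volumetric flow is taken at inlet conditions with no temperature
  correction through the bed.
* The saturated-outlet inlet-humidity estimator biases Ω_ext low whenever
  the plateau efficiency is below ~0.95 (see above); prefer a measured
  inlet humidity where available.
* The generator's batch-to-batch variation is limited to noise/artefact
  realisations; trajectory-level variation (granulate, ambient) is not
  modelled, so multi-batch robustness claims are outside its scope.
* GAB parameters are treated as temperature-independent over 10–25 °C.
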