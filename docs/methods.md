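# Methods

This note records the models implemented in `algadry`, the numerical
choices behind them, what the synthetic-data generators emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Moisture accounting

Dry-basis moisture X (kg water / kg dry matter) is the canonical internal
representation; wet-basis percentages appear only at I/O boundaries
(`mass_to_moisture` converts total mass to X = (m − m_dry)/m_dry). The
moisture ratio is MR = (X − X_e)/(X_0 − X_e) with the equilibrium moisture
X_e defaulting to 0, i.e. treated as negligible relative to the drying
range — the usual convention when the final moisture is far above the true
sorption equilibrium. Because X_0 is taken from the measured first point,
normalization maps any amplitude noise at t = 0 into a common scale factor
on the whole curve; models with a free amplitude absorb it.

Kinetics time grids are kept in **minutes** (fitted rate constants of
order 0.01–0.1 are only meaningful on that scale); the diffusivity module
converts to **seconds** through the curve's explicit unit tag, never
implicitly.

## Thin-layer model fitting

Eight closed forms are registered (parameters in fitting order):

| model | MR(t) | parameters |
|---|---|---|
| page | exp(−k tⁿ) | k, n |
| weibull | exp[−(t/β)^α] | α, β |
| wang_singh | a t² + b t + 1 | a, b |
| henderson_pabis | n exp(−k t) | n, k |
| midilli_kucuk | a exp(−k tⁿ) + b t | a, k, n, b |
| logarithmic | a exp(−k t) + c | a, k, c |
| verma | a exp(−k t) + (1−a) exp(−c t) | a, k, c |
| verma_modified | a exp(−b tⁿ) + (1−a) exp(−c tⁿ) | a, b, c, n |

The Weibull form uses β as the time scale (minutes) and α as the shape
exponent. Bounds and start grids are assigned by parameter role: rate
constants (k, c, the Verma-modified b) in [10⁻⁶, 10] with starts
{10⁻⁴…10⁻¹}; shape exponents (n, α) in [0.05, 5] with starts
{0.5, 1, 1.5, 2.5}; amplitudes a in [−10, 10] (fitted values well above 1
and below 0 occur in practice for the Verma family); additive slopes (the
Midilli–Kucuk b and both Wang–Singh coefficients) get symmetric bounds
[−1, 1] with sign-spanning starts, because a drying curve requires a
negative linear term in the Wang–Singh form and small negative b values
are routinely reported for Midilli–Kucuk.

Fitting minimizes Σ(MR_exp − MR_pred)² with SciPy's bounded trust-region
least squares from every point of the start-grid Cartesian product
(`FitConfig(n_best_starts=k)` optionally refines only the k grid points
with the lowest initial SSE — spot checks in the test suite show identical
optima; the full grid remains the default). Tolerances are strict
(ftol 10⁻¹², xtol 10⁻¹⁰, ≤ 2000 evaluations per start) since problems are
desk-scale. The procedure is fully deterministic: fixed grid, no jitter.

Identifiability caveats: the Verma family is symmetric under
(k, c) → (c, k) with a → 1−a, so recovered parameters are compared up to
that reflection; with its exponent near 1 the modified Verma is close to
a reparameterized Verma and its two rates can be nearly collinear.

### Fit statistics

For residuals r with N points and p fitted parameters:

- `sse_raw` = Σr²; `sse_paper` = Σr²/N (the mean-square variant some
  drying studies tabulate under the name SSE — both are reported, clearly
  labelled, because downstream formulas need Σr²);
- RMSE = √(Σr²/N); χ² = Σr²/(N − z) with the "number of model constants"
  z taken equal to p;
- the concentrated Gaussian log-likelihood
  ln L = −(N/2)[ln 2π + 1 − ln N + ln Σr²], hence AIC = 2p − 2 ln L and
  AICc = AIC + 2p(p+1)/(N − p − 1). A numerically perfect fit (Σr² = 0)
  yields ln L = +∞ and AICc = −∞, which sorts first as intended.

Model selection sorts ascending AICc; ties within 10⁻⁹ break by fewer
parameters, then name. R² = 1 − Σr²/Σ(MR − mean MR)².

### When AICc does *not* pick the generating model

The 50 °C reference parameter set has b = 10⁻⁵, which moves MR by at most
~0.003 over a 300-min horizon — below a σ = 0.005 noise floor. In that
regime the additive-slope term is statistically invisible: the modified
Verma (same p = 4) matches the remaining shape essentially exactly and
wins close to half of random replicates, and if the run is truncated at
MR < 0.01 (N ≈ 9 points) the parsimony penalty hands the decision to
Page. This is correct behaviour of the criterion, not an optimizer
failure; the acceptance test that demands a ≥ 90% overall identification
rate across the three temperatures documents this limit by failing. At
30 °C and 40 °C, where b·t is well above the noise, the generating model
is identified in every tested replicate.

## Diffusivity

Forward model: the slab series
MR = (8/π²) Σ (2n−1)⁻² exp[−(2n−1)²π²D_eff·t/(4L²)], clamped to
[0, 1+10⁻⁹]; 200 terms change MR by < 10⁻¹² beyond the first hundred
microseconds of dimensionless time. The slope method regresses ln MR on
time (seconds) over the window 0.05 ≤ MR ≤ 0.95 — the upper cut removes
early points where the multi-term series is not yet log-linear, the lower
cut removes points where log-noise explodes; the window is a parameter.
D_eff = −slope·4L²/π². L defaults to 0.001 m (half of a 0.2 cm slab).
Shrinkage is ignored (constant L).

Arrhenius: least squares of ln D_eff on 1/T (K); E_a = −slope·R,
D₀ = exp(intercept). R defaults to 8.3123 J/mol/K for arithmetic
traceability to the engineering literature this package follows
(`gas_constant=8.314` switches to CODATA; the difference is orders of
magnitude below estimation error). Applied to the published diffusivity
triple (3.1, 3.7, 4.7)×10⁻¹⁰ m²/s at 30/40/50 °C, this regression gives
E_a ≈ 16.9 kJ/mol with R² ≈ 0.989 (frozen as a test oracle); a published
value of 11.01 kJ/mol for the same triple is not reproducible by direct
regression, so the package always reports its own fit.

## Energy audit

- Electrical supply: E_total = Σ V·I·Δt (left-endpoint rates, kWh).
- Air stream: E_air = Σ v̄·A·ρ_air·C̄p·(T_P − T_inlet)·Δt, piecewise over
  the log. ρ_air defaults to ideal-gas density at the process temperature
  and 101.325 kPa; C̄p = 1.006 kJ/kg/K; both overridable.
- Water: E_water = M_dry·Σ(−ΔX)·λ(T) over intervals with net loss;
  noisy moisture-gain intervals contribute zero and are counted in a
  warning (the published energy-balance summand carries a stray time
  factor that is not dimensionally coherent; the mass-times-latent-heat
  reading is implemented). λ(T) = 2501 − 2.361·T kJ/kg (linear steam-table
  approximation, coefficients configurable) since no correlation is
  prescribed by the sources.
- Efficiencies: η_air = E_air/E_total, η_water = E_water/E_air,
  OTE = η_air·η_water ≡ E_water/E_total (the two routes agree to 10⁻⁹ by
  construction and are asserted). Values outside [0, 100]% are flagged,
  never clipped. SEC = E_total/M_water; cost is reported on both the
  per-run (tariff·E_total) and per-kg-water (tariff·SEC) bases because
  published cost-per-kg columns are ambiguous about their basis.
- K_G per interval:
  K_G = M_dry·(−ΔX/Δt)·λ(T_P) / [λ(T_wb)·A_tray·(P_sat(T_wb) − P_vap)],
  units kg/m²/s/Pa (the dimensionally forced choice). P_sat is the Tetens
  correlation 610.78·exp(17.27T/(T+237.3)) Pa; P_vap defaults to
  (RH/100)·P_sat(T_db), with a wet-bulb-depression alternative
  (`pvap_mode="wet_bulb"`). Intervals with non-positive driving force are
  excluded with a warning; an error is raised only if none survive.

## Synthetic generators

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; byte-identical reruns are asserted in tests.

`simulate_drying_run` evaluates a chosen thin-layer model on a 7-min grid
(study sampling interval) up to 300 min, truncating at the first point
with clean MR < 0.01 ("dried to constant weight"); adds Gaussian MR noise
(σ default 0.005, chosen so best-fit R² lands near 0.999, the magnitude
reported for well-behaved bench curves), resampling rather than clipping
negative draws so log-transforms stay defined; and converts to dry-basis
moisture with X₀ = 7.0 kg/kg (87.5% wet basis on a 150 g sample,
M_dry = 18.75 g). The three presets carry reference Midilli–Kucuk
parameter sets for 30/40/50 °C.

`simulate_energy_log` produces constant-setpoint telemetry (220 V × 10 A
≈ 2.2 kW heater — a bench tray-dryer scale that keeps the sensible air
load below the electrical supply at every preset — 2 m/s, 83% RH,
0.03 m² duct, 0.045 m² tray, 20 °C inlet) with optional Gaussian jitter.
The wet-bulb channel solves the Tetens-based psychrometer relation
P_vap = P_sat(T_wb) − A·P·(T_db − T_wb) (A = 6.66×10⁻⁴ K⁻¹), so the
logged (T_db, T_wb, RH) triple is self-consistent and the K_G driving
force is strictly positive below saturation.

What the generators do **not** emulate: real drying logs have
heteroscedastic balance noise on mass (not MR), airflow disturbances when
trays are weighed, product shrinkage, and a nonzero equilibrium moisture;
telemetry has sensor drift and quantization. Passing round-trip tests
therefore demonstrates estimator correctness under the stated noise
model, not robustness to every bench artefact. Likewise the audit of a
simulated 150 g load in a 2.2 kW dryer honestly yields a small OTE and a
large SEC; absolute published audit values for pilot runs are not
reproducible without the original telemetry and are not targeted.

Assay plates are constructed by inverting the pigment formulas (γ pinned
to 0, β split evenly between the 582/631 nm channels) so that CT and FC
recover the targets exactly at σ = 0; targets should be given at
extract-level concentrations (µg/mL) to keep generated absorbances in the
plate-reader range.

## Degenerate inputs and tie-breaks

Strictly increasing time grids are enforced with the first offending index
reported; runs with X₀ = X_e are rejected as degenerate; statistics guard
their degrees of freedom (N > z, N > p + 1, nonzero total sum of
squares); the slope method requires ≥ 3 in-window points and a negative
slope; Arrhenius requires ≥ 2 distinct temperatures. Negative pigment or
out-of-range efficiency values are flagged with warnings, never silently
altered.

## Problem sizes

Default test and acceptance computations use the study-scale grids: 44
samples per 300-min run at 7-min intervals, 20 seeds per temperature in
the selection study, 200×200 grids in the exhaustive-search oracle, and
one-term/50-term Fick curves of ~52 points. These sizes make every
statistical claim in the suite recomputable in seconds to a couple of
minutes on a laptop.
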