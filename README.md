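# algadry

Thin-layer drying kinetics, effective moisture diffusivity, dryer energy
auditing and spectrophotometric functional assays for convective drying of
brown seaweed (and other thin-slab food matrices).

The package is aimed at food-process engineers and algal-biomass
researchers who need a tested, reproducible version of the standard
bench-drying analysis chain:

1. **Kinetics** — normalize a drying log to the moisture ratio
   MR(t) = (W_t − W_e)/(W_0 − W_e), fit eight semi-empirical thin-layer
   models (Page, Weibull, Wang–Singh, Henderson–Pabis, Midilli–Kucuk,
   logarithmic, Verma, modified Verma) by deterministic multi-start bounded
   least squares, and rank them by the bias-corrected Akaike criterion
   AICc = 2p − 2 ln L + 2p(p+1)/(N−p−1).
2. **Diffusivity** — slope-method estimation of the effective moisture
   diffusivity from the slab solution of Fick's second law,
   ln MR ≈ ln(8/π²) − π²·D_eff·t/(4L²), and Arrhenius fitting of
   D_eff = D₀·exp(−E_a/RT) across air temperatures.
3. **Energy audit** — E_total = ΣV·I·Δt split into air-heating and
   water-removal stages, stage efficiencies, overall thermal efficiency
   (OTE), specific energy consumption (SEC, kWh per kg of evaporated
   water), energy cost, and a per-interval overall mass-transfer
   coefficient K_G driven by the Tetens vapor-pressure deficit at the
   wet bulb.
4. **Assays** — total carotenoids CT = 4α and fucoxanthin
   FC = 7.69α − 5.55β − 0.377γ from five-wavelength absorbances, DPPH
   percent inhibition, and linear calibration curves for TPC/TFC.
5. **Synthetic data** — seed-deterministic generators for drying runs,
   Fick curves, dryer telemetry and assay plates with known ground truth,
   so every estimator is testable without bench data.

## Worked example

Simulate a 30 °C drying run (150 g sample at 87.5% wet-basis moisture,
7-min sampling, σ = 0.005 MR noise), fit and rank all models, and audit
the energy use:

```python
from dataclasses import replace
from algadry import (DRYING_PRESETS, simulate_drying_run, simulate_energy_log,
                     fit_all_models, select_model, moisture_ratio,
                     build_energy_audit, FitConfig)

cfg = replace(DRYING_PRESETS["30C"], seed=42)
run, truth = simulate_drying_run(cfg)
ranked = select_model(fit_all_models(moisture_ratio(run),
                                     config=FitConfig(n_best_starts=12)))
for f in ranked[:3]:
    print(f"{f.model:15s} R2={f.stats.r2:.4f} AICc={f.stats.aicc:8.2f}")

audit = build_energy_audit(run, simulate_energy_log(cfg, run))
print(f"OTE={audit.ote_pct:.2f}%  SEC={audit.sec_kWh_per_kg:.2f} kWh/kg")
```

prints

```
midilli_kucuk   R2=0.9998 AICc= -354.22
verma_modified  R2=0.9995 AICc= -326.46
verma           R2=0.9956 AICc= -229.77
OTE=0.82%  SEC=87.30 kWh/kg
```

The generating Midilli–Kucuk model is identified (lowest AICc, ΔAICc ≈ 28
to the runner-up) and its rate constant comes back as k = 0.0094 against a
true 0.009. The audit numbers describe the simulated bench dryer: a 2.2 kW
heater drying a 150 g sample removes ~0.13 kg of water, so the overall
thermal efficiency is necessarily small and the SEC large; see
`docs/methods.md` for what the generator does and does not emulate.

A command-line interface mirrors the library
(`algadry simulate|fit|diffuse|arrhenius|energy|assays|all`):

```sh
algadry simulate --preset 30C --seed 42 --out run.csv --telemetry tel.csv
algadry fit --input run.csv --models all --out fits.json
algadry energy --run run.csv --telemetry tel.csv --out audit.json
```

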