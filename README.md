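# onebox

One-box mass-balance modeling of indoor nanoparticle exposure.

Occupational hygienists assessing workplaces with strong unintentional
nanoparticle sources (thermal spraying, laser printing, powder handling)
rarely get to measure inside the source enclosure — concentrations there
saturate portable counters. What they do have is a 1-minute particle-number
log from the worker area. This package turns such a log into emission-rate
estimates, forward-modeled exposure concentrations, and a quantitative
verdict on how well the well-mixed-room assumption held.

## Model

The worker area is a single well-mixed compartment of volume *V* ventilated
at *Q* (ACH = *Q/V*). Number concentration *N* (cm⁻³) obeys

    dN/dt = λ·N_BG(t) + S_N(t)/V − λ·N(t),    λ = ACH/60 min⁻¹,

with background entering through the incoming air and ventilation as the
only loss. The source strength S_N (particles·min⁻¹) is estimated two ways:

* **Deconvolution** (convolution-theorem method): the discrete inverse
  S_tot(t) = V·(N(t) − N(t−Δt)·e^(−γΔt))/Δt, minus the background
  generation rate S_BG = Q·N_BG estimated the same way from a source-off
  window;
* **Cyclic steady state**: S_N = Ĉ·V/t_ESD from the mean activity
  concentration Ĉ and the duration t_ESD of one spraying repetition.

The forward model then uses the exact per-step exponential update (unbiased
even at λΔt ≈ 0.5), and the evaluation layer scores modeled against
measured series per shift: mean ratio, RMSLE, the BG + 3σ_BG significance
rule, and the 0.5–2 performance benchmark. A seeded generator synthesizes
complete workshop days (cyclic bursts, lognormal instrument noise, counter
saturation) with known ground truth, so every stage is testable without any
measurement campaign.

## Worked example

Score a published shift of a thermal-spraying campaign, then run the full
pipeline on a synthetic short-cycle day (ACH 25 h⁻¹, 249 m³, seven 5–10-min
bursts at a true rate of 10¹³ min⁻¹, 15% instrument noise):

```python
from onebox import mean_ratio, run_pipeline
from onebox.datasets import THERMAL_SPRAY_SHIFTS

rec = THERMAL_SPRAY_SHIFTS[3]  # day 3, morning shift
print(f"day {rec.day} {rec.shift}: modeled/measured (NanoScan) "
      f"convolution = {mean_ratio(rec.modeled['convolution'], rec.measured['nanoscan']):.2f}, "
      f"cyclic = {mean_ratio(rec.modeled['cyclic'], rec.measured['nanoscan']):.2f}")

config = {
    "scenario": {"volume_m3": 248.6, "ach": 25.0},
    "synth": {"seed": 1},
    "shifts": [{"id": "morning", "window": [0, 165]},
               {"id": "afternoon", "window": [225, 420]}],
}
result = run_pipeline(config)
print(result.table.round(3).to_string(index=False))
```

which prints

```
day 3 morning: modeled/measured (NanoScan) convolution = 0.24, cyclic = 0.18
    shift      method  emission_rate_per_min  modeled_mean_cm3  measured_mean_cm3  ratio  rmsle  significant
  morning convolution           8.617307e+12         72094.205          83345.956  0.865  0.207         True
  morning      cyclic           2.659223e+12         35552.775          83345.956  0.427  0.826         True
afternoon convolution           8.617307e+12         74574.977          85611.580  0.871  0.190         True
afternoon      cyclic           2.659223e+12         36318.346          85611.580  0.424  0.827         True
```

Reading this: on the published shift the one-box model underestimated
measured means roughly four- to five-fold (ratios 0.24 and 0.18) — real
rooms are not perfectly mixed. On the synthetic day, where the model's
assumptions hold by construction, deconvolution recovers the source to
within its one-step discretization bias (8.6×10¹² vs the true 10¹³ min⁻¹;
ratio 0.87, RMSLE ≈ 0.2), while the cyclic formula — which ignores removal
during a burst — lands a factor ~3 low at this high air-exchange rate. Both
shifts register as statistically significant exposure increases over the
lunch-break background.

The same pipeline is available from the shell:

```sh
onebox run --config day.yaml --method both --ach-scenario closed --seed 1 --out-dir out/
```

with stage subcommands `synth`, `estimate`, `model` and `evaluate` that
compose to identical outputs.

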