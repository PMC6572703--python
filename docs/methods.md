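# Methods

## Model

The worker area of an industrial workshop is treated as a single well-mixed
compartment of volume *V* ventilated at flow *Q*. Particle number
concentration *N(t)* (cm⁻³) follows the mass balance

    dN/dt = λ·N_BG(t) + S(t)/V − λ·N(t),

with λ = ACH/60 (min⁻¹) the total first-order loss rate, *N_BG* the particle
concentration of the incoming air, and *S(t)* the source strength in
particles·min⁻¹. The model assumes (i) instantaneous full mixing, (ii)
particle input only from the source and from infiltrating background air,
and (iii) ventilation as the only loss process. Assumption (iii) is
justified at the air-exchange rates of interest (25–35 h⁻¹): gravitational
and diffusional deposition rates for 10 nm–35 µm particles are typically
below 4 h⁻¹ and are therefore neglected. Background enters as inflow
(λ·N_BG), not as an additive offset, because the replacement air itself
carries particles.

### Numerical scheme

For piecewise-constant *S* and *N_BG* over one step Δt the balance has the
exact solution

    N(t+Δt) = N* + (N(t) − N*)·e^(−λΔt),   N* = N_BG + S/(λV),

which the forward model applies step by step. At the 1-minute resolution of
portable particle counters λΔt ≈ 0.42–0.58, where an explicit Euler step is
visibly biased; the exact update is unbiased for any λΔt. An independent
fine-step Euler integrator (Δt/1000) is kept in the test suite as an oracle
and agrees to <0.1%.

Units are fixed internally — concentrations cm⁻³, volumes cm³, rates min⁻¹ —
with all conversions from the reporting units (m³, m³·h⁻¹, h⁻¹) centralized
in three functions so they are testable in isolation.

## Emission-rate estimators

**Deconvolution.** On a regular grid the discrete inverse of the exact
update is

    S_tot(t) = V·(N(t) − N(t−Δt)·e^(−γΔt))/Δt,

with γ the total loss rate. The first grid step has no predecessor and is
reported missing (NaN), never zero. Raw deconvolved rates may be negative
under instrument noise; they are preserved, because clipping at zero before
averaging biases the mean upward. A clipped "physical" view is available
separately. The background generation rate S_BG is estimated by applying
the same deconvolution to a source-off window (the lunch break) and
averaging; subtracting this empirical S_BG rather than the analytic Q·N_BG
makes the discretization factor common to both terms cancel, so that a
constant source is recovered with relative bias exactly

    (1 − e^(−λΔt))/(λΔt) − 1

(−18% at λΔt = 0.42, −2% at λΔt = 0.042). The bias is a property of the
one-step backward difference and vanishes as Δt → 0. Because the booth
protection factor ε_C cannot be separated from data measured outside the
booth, all reported rates are the lumped ε_C·S_N.

*Grid alignment.* A deconvolved rate describes the step *ending* at its
timestamp. Segment labels derived from a source schedule (which describe
the step *starting* at their timestamp) are shifted one step before
averaging; labels obtained by thresholding the measured series already live
on the reading grid and are used as-is.

**Cyclic steady state.** S_N = Ĉ·V/t_ESD with Ĉ the mean concentration over
activity-labeled minutes and t_ESD the spraying duration. Two choices were
genuinely open:

* *Ĉ*: taken without background subtraction, exactly as the formula is
  written; the formula's own assumption is that pre-activity concentrations
  are much lower than activity concentrations. An option subtracts the
  background mean for settings where that assumption is weak.
* *t_ESD*: defaults to the **mean duration of a single spraying
  repetition** (contiguous activity block), with a total-duration mode
  available. The single-cycle reading is used as default because the
  formula's derivation balances the particles of one cycle against the
  concentration it builds, and because worked values for short-cycle days
  (Ĉ ≈ 2.5×10⁵ cm⁻³, V ≈ 2.5×10⁸ cm³, rate ≈ 8×10¹² min⁻¹) imply
  t_ESD ≈ 8 min — one 5–10-min repetition, not the ~1 h total.

The estimator deliberately ignores removal during the burst. With
λ·t_ESD between ~3 (short cycles at ACH 25) and ~15 (long cycles at ACH 35)
it therefore *underestimates* strong sources by roughly λ·t_ESD relative to
the deconvolution result, and *overestimates* weak sources whose activity
mean is background-dominated. Factor-of-several disagreement between the
two estimators is consequently expected, not a defect; the property tests
bound it at one order of magnitude across the workshop regimes, matching
what is observed in such campaigns. Recovery to better than a factor ~2–3
should not be expected from the cyclic formula at high ACH.

## Segmentation and significance

Minutes with concentration above a threshold (default 10⁵ cm⁻³) are labeled
activity; an explicitly configured source-off window (default 12:45–13:45)
is labeled background. A spraying period is a significant exposure increase
when its mean exceeds BG + 3σ_BG, with σ_BG the sample (n−1) standard
deviation — background windows are short, so the small-sample correction
matters.

On synthetic days the pipeline defaults to the generator's ground-truth
labels, which play the role of the source-side (in-booth) counter used to
read spray ON/OFF in practice; thresholding the worker-area series is the
fallback for measured input, and lags the source by the room's response
time (visible as a lower modeled/measured ratio in self-consistency runs).

## Evaluation

Per shift and per estimator: modeled mean, measured mean, their ratio, and
the root mean squared logarithmic error

    RMSLE = sqrt(mean[(ln N_mod − ln N_meas)²]),

computed over activity-labeled minutes. Natural logarithm without a "+1"
offset: concentrations are ≫1 cm⁻³, so the offset would be noise; the log
base is configurable since the convention is not standardized. Both ratio
and RMSLE are flagged against the 0.5–2 model-performance benchmark.
Distribution summaries report the 10/25/50/75/90th percentiles with linear
interpolation between order statistics (the usual box-plot convention).

## Synthetic data generator

Emulates one monitored workday, 10:00–17:00 on a 1-minute grid with a
source-off lunch window 12:45–13:45:

| parameter | default | rationale |
|---|---|---|
| ACH | 25 h⁻¹ | short-cycle workshop regime (long-cycle: 35 h⁻¹) |
| volume | 248.6 m³ | modeled booth area consistent with Q = 6216 m³ h⁻¹ at ACH 25 |
| background mean | 1.9×10⁴ cm⁻³ | within the observed 1.2–4.5×10⁴ day range |
| background CV | 0.05 | mild minute-to-minute jitter |
| bursts | 7 × 5–10 min | short-cycle activity pattern (7–9/half day); long-cycle: 2–4 × 20–30 min |
| true rate | 10¹³ min⁻¹ | upper end of the estimated workshop band 10¹¹–10¹³ |
| noise CV | 0.15 | multiplicative lognormal, mean one |
| saturation | 4×10⁶ cm⁻³ | counter ceiling; readings clip there |

Multiplicative lognormal noise is used instead of additive Gaussian because
number concentrations are strictly positive and span decades. Bursts are
packed left to right with uniform random durations and gaps; a burst that
would overlap lunch is pushed past it, and infeasible packings raise an
error instead of silently dropping repetitions. An optional AR(1) drift on
the background multiplier emulates day-scale background variation (off by
default). All randomness flows from one integer seed through keyed
substreams, so identical seeds are bitwise reproducible and changing the
noise level does not reshuffle the burst layout.

What the generator does **not** emulate: spatial concentration gradients
(imperfect mixing), instrument-specific size-range differences between
counters, door-configuration changes within a day, and correlated
(drifting) instrument error. Passing the recovery tests therefore shows the
estimators are correct under the model's own assumptions, not that a real
workshop is well mixed.

## Numerical and degenerate-case choices

* Constant decay windows fit γ = 0 with r² defined as 1 (the constant model
  is exact); rising windows are flagged, not rejected.
* λ ≤ 0 with a nonzero source is a configuration error (unbounded growth);
  λ = 0 with zero source is allowed and holds the state constant.
* Deconvolution of the first grid step is NaN and excluded from averages.
* Simulation initial condition defaults to the background value; the
  pipeline uses the first measured value of the window.
* Grid equality checks use 1e-9 relative tolerance; forward/inverse
  identities are asserted to 1e-9 beyond their analytic bounds.

## Problem sizes

Default runs simulate single 420-minute days (420 steps at Δt = 1 min,
4 200 at Δt = 0.1 min); the regime grid spans 2 ACH × 3 source strengths.
These sizes keep the full suite and the summary script to seconds while
exercising every code path at the study's own scales.

## Known limitations

* The booth protection factor ε_C is never separated; all rates are ε_C·S_N.
* Threshold segmentation on the room signal lags the true source by the
  room response time; source-side labels are preferred where available.
* Two-compartment (near-field/far-field) modeling, size distributions, mass
  metrics, deposition losses and probabilistic ACH sensitivity analysis are
  out of scope; alternative fixed ACH regimes (doors closed/open) can be
  run side by side instead.
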