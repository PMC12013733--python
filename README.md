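# vo2fit

Modeling of post-exercise oxygen-uptake (V̇O₂) off-kinetics from
breath-by-breath data, for exercise physiologists who estimate recovery
dynamics and anaerobic-alactic energy contributions (the PCr-La-O₂ method)
after high-intensity efforts such as a 30-s Wingate sprint.

## The model

After exercise cessation, V̇O₂ decays from its end-exercise peak back toward
the resting baseline. `vo2fit` fits two bounded nonlinear models to the
recovery series:

```
mono:  V̇O₂(t) = V̇O₂_baseline + A  · e^{−(t−td)/τ}
bi:    V̇O₂(t) = V̇O₂_baseline + A1 · e^{−(t−td)/τ1} + A2 · e^{−(t−td)/τ2}
```

with a single shared time delay `td`, a fast phase (A1, τ1: phosphocreatine
resynthesis and O₂-store refilling) and a slow phase (A2, τ2: lactate
clearance, thermoregulation, catecholamines). The curves are clamped at
their `td` value for `t < td`.

The defining feature is the **user-fixed measured baseline**: because a
15-min recovery seldom returns to rest, a freely fitted asymptote is poorly
identified and tends to inflate, dragging amplitude and τ with it and
corrupting the alactic energy estimate A·τ (mono) or A1·τ1 (bi) × caloric
equivalent (default 20.92 kJ/L O₂). Fixing the baseline at its measured
pre-exercise value anchors the fit to the physiological recovery target.

Around the fits the package provides: Savitzky–Golay smoothing and
cubic-spline resampling, R² (full window and fast-phase), least-squares
AIC/AICc, trapezoidal and closed-form recovery O₂ integrals, kJ/kcal energy
conversion, baseline-sensitivity sweeps, a ground-truth breath-by-breath
simulator, and cohort statistics (paired t, pooled-SD Cohen's d, one-way
repeated-measures ANOVA with partial η²).

The fitting core follows the scikit-learn estimator API
(`MonoExponentialRegressor`, `BiExponentialRegressor`: `fit(X, y)` with X a
single column of recovery times, `predict`, `score`, `get_params`), so it
composes with sklearn tooling; `vo2fit.fit_model` is the series-level
wrapper.

## Worked example

Simulate a 15-min recovery (true baseline 390 mL/min, fast phase
2500 mL/min / τ₁ 65 s, slow phase 840 mL/min / τ₂ 743 s, breath noise
SD 120 mL/min), then fit both models with the measured baseline fixed:

```bash
vo2fit simulate --out demo.csv --seed 7
vo2fit fit --input demo.csv --baseline 390 --model both --out report.json
```

From `report.json` (rounded):

| model | params | R² | AICc | alactic (kJ) | 15-min integral (L) |
|---|---|---|---|---|---|
| mono | A=2500.1, td=0.0, τ=215.4 | 0.825 | 5154.5 | 187.8 | 14.69 |
| bi | A1=2599.5, τ1=67.1, A2=796.6, τ2=793.0, td=0.0 | 0.961 | 4457.6 | 60.8 | 15.90 |

The bi-exponential model recovers the simulated fast phase (τ1 67 s vs the
true 65 s) and a plausible ~61 kJ alactic contribution; the mono model,
forced to explain both phases with one exponential, lands between them
(τ 215 s) and overestimates the alactic energy three-fold — exactly the
distortion the two-component model and the fixed baseline are there to
avoid. Its 15-min integral also underestimates the observed recovery volume.

Other subcommands: `vo2fit cohort --manifest cohort.yaml` (per-participant
fits plus mono-vs-bi comparisons), `vo2fit sweep --baselines 300:750:50`
(sensitivity of every metric to the assumed baseline).

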