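# Methods

## Model and assumptions

Post-exercise V̇O₂ recovery is modeled as a sum of one or two exponential
phases decaying toward the resting baseline:

- mono: `VO2(t) = baseline + A·exp(−(t−td)/τ)`
- bi: `VO2(t) = baseline + A1·exp(−(t−td)/τ1) + A2·exp(−(t−td)/τ2)`,
  with `τ1 < τ2` (fast/slow ordering) and a **single shared delay** `td`.
  A per-phase delay is deliberately not representable anywhere in the
  package: it adds complexity without physiological interpretability for
  off-kinetics.

For `t < td` the exponent would be positive; both curves are clamped to
their value at `td`, i.e. a plateau at `baseline + ΣA`. This keeps early
breaths usable and the curve continuous; an `exclude_pre_td` option refits
with pre-delay samples dropped for users who prefer the delete-the-delay
convention. All amplitudes and baselines are mL/min (absolute mode) or
mL/kg/min (relative mode; body mass converts to absolute before any volume
or energy computation). Integrals are litres of O₂ ((mL/min)·s / 60 000).

## Fitting

Bounded least squares (`scipy.optimize.least_squares`, trust-region
reflective), plain quadratic loss, deterministic start, tolerances
`ftol=1e-10`, `xtol=1e-8`, at most 2000 function evaluations. Identical
inputs give bit-identical results.

Baseline handling: the primary mode fixes the baseline at the measured
resting value, removing it from the free set (k=3 mono, k=5 bi). Free
mode (k=4/6) is retained to quantify the auto-calibration distortion: on
synthetic replicates the free baseline has an RMSE of roughly 180 mL/min
around truth, and fixing the true baseline never worsens τ1 recovery.

Default bounds (absolute mode): amplitudes 0 – max(8000, 1.5·peak) mL/min,
delay 0–30 s, mono τ 10–600 s, fast τ1 5–120 s, slow τ2 120–2000 s,
free baseline 100–1000 mL/min. Relative mode caps amplitudes at
100 mL/kg/min and the free baseline at 1–15 mL/kg/min. The disjoint
τ1/τ2 intervals enforce phase ordering structurally, keeping the problem
box-constrained. All bounds are user-overridable.

Starts: mono amplitude `peak − baseline`, td 3 s, τ 150 s; bi splits the
amplitude 75/25 with τ1 60 s, τ2 600 s. The bi fit additionally always
tries a start seeded from an internal mono fit placed on the A2=0 (or A1=0)
boundary of the bi parameter space; since the optimizer only descends, this
guarantees rss(bi) ≤ rss(mono) on every series. An optional deterministic
3×3 geometric τ-grid multi-start exists for difficult series (off by
default; best rss wins, first-in-grid-order breaks ties).

Identifiability note: with breath data whose first sample falls after the
true delay, `td` and the amplitudes are only jointly identified (the
likelihood is flat along `A·e^{td/τ}` = const). A uniform grid that starts
at t=0 pins them individually; exact-recovery tests use such a grid.

## Preprocessing

- Savitzky–Golay filter, default 5-point window, polynomial order 2
  (on a symmetric 5-point window orders 2 and 3 give identical
  coefficients). Interior points use the standard convolution in
  sample-index space; the two points at each edge are re-fit on the
  available shrunk window so no pre-recovery values are fabricated.
  Filtered values are not clipped at zero.
- Cubic-spline resampling, natural boundary conditions (recorded in the
  series meta), default 1-s grid over [0, 900] s, truncated to the observed
  range — never extrapolated. 1 s makes n comparable across participants.
- Order when both are on: smooth first, then resample — the filter
  tolerates near-uniform breath spacing better than the spline tolerates
  smoothing-after-interpolation, and the spline then interpolates denoised
  knots.

## Statistics

- R² = 1 − SSres/SStot with SStot about the mean of the evaluated subset;
  the fast-phase R² re-evaluates the full-window fit on samples with
  t ≤ 300 s (no refit), since the fast phase is what the alactic estimate
  uses.
- Least-squares AIC = n·ln(RSS/n) + 2k, AICc = AIC + 2k(k+1)/(n−k−1).
  k counts free parameters only (a measured baseline is not estimated; the
  error variance is not counted — pure least-squares convention). n is the
  post-preprocessing sample count, so AICc levels are comparable only
  within one pipeline configuration; mono-vs-bi *differences* on the same
  series are always meaningful.
- Alactic energy: fast-phase volume A·τ (mono) or A1·τ1 (bi) — the
  closed-form integral of the fast component from td to infinity, not
  truncated at 15 min — times a caloric equivalent, default 20.92 kJ/L O₂
  (configurable; published PCr-La-O₂ equivalents span ≈20.9–21.5, about a
  ±3% effect on the kJ figure). kcal uses the thermochemical 4.184 kJ/kcal.
- Cohort comparisons: paired t (scipy), Cohen's d from the pooled SD of the
  two conditions `|m_a−m_b| / sqrt((sd_a²+sd_b²)/2)` — this convention, not
  the SD-of-differences variant, reproduces published mono-vs-bi effect
  sizes from their summary statistics. One-way repeated-measures ANOVA uses
  the condition × subject decomposition, plain F (no sphericity
  correction), partial η² = SS_cond/(SS_cond+SS_err); post-hoc pairwise
  tests are uncorrected paired t, labeled as such.

## Synthetic data generator

`vo2fit.simulate` emulates a 15-min breath-by-breath recovery record:
lognormal inter-breath intervals (arithmetic mean 2.0 s, SD 0.5 s —
~0.5 Hz, positive and right-skewed like real breathing), a bi-exponential
mean curve, and additive homoscedastic Gaussian noise (default SD
120 mL/min) floored at zero (negligible bias at recovery V̇O₂ levels, noted
because it matters near zero). Cohort truths are drawn uniformly on
mean ± 2 SD windows around values typical of trained adults after a 30-s
sprint (baseline 384±56 mL/min; fast phase 2506±467 mL/min, τ1 65±13 s;
slow phase 841±270 mL/min, τ2 743±187 s; delay 2.7±1.9 s), truncated to
the default bounds.

What it does **not** emulate: breath-duration-dependent (heteroscedastic)
noise, the cardiodynamic phase, analyzer drift, movement artifacts, or
thermoregulatory slow-phase nonexponentiality. Passing recovery tests
therefore demonstrate estimator correctness under the stated noise model,
not robustness to every feature of real gas-exchange data; mono-model
misfit magnitudes (its τ, AICc level, alactic overestimate) in particular
depend on the true shape of real recovery curves and should be read
qualitatively.

## Problem sizes and numerical choices

Simulation-based checks use 900-s series (~450 breaths), 100–200 seeded
replicates for recovery studies, and a 22-participant synthetic cohort —
sizes at which the Monte-Carlo summaries are stable to well under their
test tolerances. Unit detection flags a series as relative when its peak is
below 150 (boundary → absolute); duplicate timestamps keep the first
occurrence (deterministic, order-preserving); loading re-zeroes time to the
first retained breath by default, with a flag to keep original clock
offsets since it is ambiguous whether a recovery window starts at test
cessation or at the first post-exercise breath. Text exports write 17
significant digits and loading parses round-trip, so canonical CSV
round-trips are bit-exact (spreadsheet XML keeps ~16 digits, 1-ulp wobble).

## Known limitations

- No on-transient (exercise-onset) models, no tri-exponential extension,
  no weighted or robust losses, no Bayesian uncertainty.
- AICc magnitudes depend on n (hence on smoothing/interpolation settings);
  only within-configuration comparisons are supported.
- The baseline-sweep trend results are demonstrated on a representative
  simulated participant; trend directions, not magnitudes, are the claim.
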