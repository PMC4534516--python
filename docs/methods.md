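# Methods

## The model

Performance on a progressive-ratio (PR) schedule is described by four
parameters per subject and condition. Writing `N_i` for the response
requirement of ratio `i` and `T_TOT,i` for the total inter-reinforcement
time of that ratio (post-reinforcement pause plus run time, measured from
the end of the previous reinforcer delivery to the last response of the
ratio):

```
T_P,i   = T0 + k · T_TOT,i-1              (linear waiting)
R_RUN,i = 1 / (δ · (1 + T_TOT,i-1 / a))   (MPR running rate)
R_OVL,i = N_i / T_TOT,i                   (overall rate)
```

* `T0` (s) — minimum post-reinforcement pause; sensitive to
  reinforcer-specific post-prandial behaviour (e.g. grooming after viscous
  reinforcers).
* `k` (–) — slope of the linear waiting function: how strongly the pause
  tracks the previous inter-reinforcement interval.
* `a` (s) — specific activation: seconds of behaviour activated by one
  reinforcer; the model's index of incentive value.
* `δ` (s) — minimum time to execute one response; `1/δ` is the motor
  ceiling on response rate, independent of motivation.

Because run time is `N_i / R_RUN,i`, the totals obey the affine recursion
`T_TOT,i = (T0 + k·T_TOT,i-1) + N_i·δ·(1 + T_TOT,i-1/a)`. At constant `N`
this contracts to the fixed point `(T0 + Nδ)/(1 − k − Nδ/a)` whenever
`k + Nδ/a < 1`; on the exponential PR progression
`N_n = round(5·e^(0.2n) − 5)` (1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, ...)
the totals escalate without bound, and what terminates responding in the
deterministic model is solely the 40-minute session clock. The `N_i` versus
`N_i − 1` inter-response-interval distinction is deliberately ignored: run
time is defined as the exact inverse of the measurement rule
`R_RUN = N / run-time`, so simulation and measurement are mutually
consistent.

The model involves one composition choice the rate equations do not fix:
run time in the recursion is taken as `N_i/R_RUN,i` conditioned on the
*previous* total. The forward recursion starts from `T_TOT,0 = 0` (lever
insertion opens the session; no reinforcer precedes ratio 1). The choice is
inconsequential for inference because the first ratio is excluded from
fitting anyway.

## Measurement and exclusion rules

From an event log, the post-reinforcement pause of ratio `i` runs from
`REINF_END` of ratio `i−1` (lever insertion for `i = 1`) to the first
response; run time from first to last response; the reinforcer-delivery
time (default 5 s) advances the session clock but belongs to no ratio's
total. The first ratio (one response, hence no run time) and any ratio left
incomplete at lever withdrawal are recorded but excluded from fitting.
Rates are averaged per ratio index across a rat's last ten sessions before
fitting (default); pooling all session-ratios as separate points is a
selectable alternative, since which of the two the original analyses used
is not documented.

The breakpoint is the last ratio completed before the first response-free
interval of ≥ 300 s (the scan covers lever-in → first response, all
inter-response intervals, and last response → lever-out; an interval of
exactly 300 s counts, reinforcer-consumption time is not subtracted), or
the highest completed ratio if no such interval occurs. A session in which
no ratio was completed — or, degenerately, in which the first qualifying
gap precedes the first completion — has no defined breakpoint and raises an
error rather than returning a sentinel.

## Synthetic data

No event-level rat data are available for this design, so cohorts are
simulated with the structure the estimator assumes plus the minimum extra
stochastic structure needed to make group analyses meaningful:

* **Within-session noise** — each ratio's pause and run time are the model
  predictions, conditioned on the *realised* previous total, multiplied by
  independent mean-1 lognormal factors (default CV 0.2 each). Lognormal
  keeps durations positive, is CV-parameterised, and reproduces the
  deterministic model exactly at CV 0. Responses are spread evenly across
  the run; for `N = 1` the single response falls at the end of the
  pause+run interval so the realised total still matches the model.
* **Between-rat heterogeneity** — each rat's base parameters are drawn
  independently lognormally around the group means with CV 0.3. The
  default generating means are the reference group values for food-deprived
  rats (sucrose: T0 = 3.33 s, k = 0.51, a = 23.4 s, δ = 0.21 s; corn oil:
  5.63, 0.63, 70.2, 0.44; food pellet: 4.81, 0.50, 28.1, 0.23). The 0.3 CV
  is of the order implied by the reported group SEMs; parameter
  correlations are unknowable from group summaries and are set to zero.
* **Condition effects** — multiplicative on parameters (preserving
  positivity). The default free-feeding effect is a × 0.4, T0 × 0.7,
  k × 1.3, matching the reported directions: lower incentive value, shorter
  minimum pause and steeper waiting slope without food restriction. Dose
  designs are expressed the same way (one multiplier set per dose).
* **Seeding** — a master seed spawns per-rat streams which spawn
  per-session streams, so cohorts are bit-reproducible and partially
  regenerable.

What the generator does **not** emulate: bout/pause fine structure within
runs, warm-up and satiation drift across a session, day-to-day parameter
drift, correlated parameter heterogeneity, and occasional non-performing
animals. Passing tests therefore certify the pipeline's arithmetic,
identifiability and calibration under the model's own assumptions — not
robustness to the ways real rats deviate from them.

## Fitting

`(T0, k, a, δ)` are estimated per rat×condition by minimising the
unweighted combined SSE of the running- and overall-rate series (the two
series are on comparable scales, responses/s, and no weighting convention
is documented for the original fits). Predictions are conditioned on the
observed previous total (`conditioned` mode, default — the direct reading
of the rate equations) or generated by the model's own recursion seeded
with the observed first-ratio total (`recursive` mode, provided because a
fully recursive original fit cannot be ruled out). Optimisation uses
bounded trust-region least squares (`scipy.optimize.least_squares`, trf)
restarted from one data-driven start (δ from the fastest observed running
rate, a from the median conditioning interval, T0 from the shortest pause)
plus seeded Latin-hypercube draws (default 16 starts) across the bounds
T0 ∈ [0, 60] s, k ∈ [0, 2], a ∈ [0.1, 3600] s, δ ∈ [0.01, 10] s — generous
physical ranges around reported estimates. Ties are broken toward the
lowest a; solutions within 1% of the best SSE define a multistart
dispersion diagnostic, and parameters landing on a bound are flagged
(a flat running-rate series, for instance, pins a at its upper bound).

R² = 1 − SSE/SST with SST summed over both series about each series' own
mean (default). A pooled grand-mean SST is selectable; the per-series
convention is the stricter of the two and the one a joint fit of two
different curves most naturally reports.

## Group analysis

Sums of squares for the 2×2 mixed (split-plot) ANOVA and the one-way
repeated-measures ANOVA are computed by explicit partitioning; the
decomposition is exact for unequal group sizes provided each retained
subject is complete (incomplete subjects are dropped listwise, as when one
animal stops responding under free feeding). Effect sizes are partial
η² = SS_effect/(SS_effect + SS_error). Significance is two-tailed p < 0.05
throughout; no sphericity correction is applied (none is applied in the
reference analyses; with two within levels it is moot). The linear dose
contrast uses equally spaced centred coefficients over the ordered levels
(log-dose coding selectable; with doses 0.3/1/3 log-spaced the two
coincide up to scale except for the vehicle position), and its F is the
squared one-sample t of the per-subject contrast scores (df 1, n−1). The
within-subject Dunnett test forms paired differences against the control
and refers each |t| to the maximum of k equicorrelated (ρ = ½)
t variates, evaluated by deterministic Gauss–Hermite × Gauss–Legendre
quadrature; with k = 1 it reduces to the ordinary paired t. Interaction
post hocs are Student's t — paired across conditions within a group,
unpaired across groups within a condition — run only when the interaction
is significant.

## Problem sizes and numerical choices

Monte-Carlo checks use cohort sizes chosen to balance statistical
resolution against run time: parameter recovery uses 12 rats × 10 sessions
(the reference design) with homogeneous rats; detection power uses 20
replicate cohorts of 12 rats/group × 4 sessions/condition (the
within-subject a × 0.4 effect is so large relative to fit noise that power
is insensitive to the session count); type-I calibration uses 200 null
cohorts of 8 rats/group × 3 sessions. Fixed-point checks run the recursion
2000 steps at a 1e-9 relative tolerance. Session truncation treats a ratio
whose last response falls exactly at lever withdrawal as completed. The
optimiser runs with ftol = xtol = gtol = 1e-14 so zero-noise fixtures
recover parameters to ~1e-6 relative or better.

## Known limitations

* The deterministic model has no intrinsic stopping rule; finite
  breakpoints arise only from the session limit (plus, under noise, chance
  long pauses). Very long sessions would complete every scheduled ratio.
* Conditioned-mode estimates inherit a small upward rate bias from
  averaging reciprocal times across sessions (about 2–4% at CV 0.2); it
  vanishes as noise → 0 and is well inside the recovery tolerances tested.
* The split-plot partition uses group-size-weighted condition means; for
  severely unbalanced groups a Type-III analysis could differ (the intended
  use case loses at most one animal per group).
* Fitted-parameter distributions are right-skewed under lognormal
  heterogeneity; the ANOVAs are run on the raw scale to match standard
  practice in this literature, and the null calibration test confirms the
  type-I rate survives this at the sizes used.
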