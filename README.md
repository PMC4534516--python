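# progratio

Simulation, measurement and model-based analysis of performance on
**progressive-ratio (PR) schedules** of reinforcement.

Under a PR schedule the number of lever presses required per reinforcer,
*N*, grows from one reinforcer to the next — here along the exponential
progression `N_n = round(5·e^(0.2n) − 5)` = 1, 2, 4, 6, 9, 12, 15, 20, 25,
32, 40, … — until responding peters out within a 40-minute session. The
classical summary of such a session, the *breakpoint*, collapses the whole
performance into a single noisy number. This package implements instead a
four-parameter dynamic model of the entire session, of interest to
behavioural pharmacologists who want to separate *motivational* drug or
deprivation effects from *motor* ones:

```
T_P,i   = T0 + k · T_TOT,i-1              post-reinforcement pause (linear waiting)
R_RUN,i = 1 / (δ · (1 + T_TOT,i-1 / a))   running response rate (MPR)
R_OVL,i = N_i / T_TOT,i                   overall response rate
```

where `T_TOT,i` is ratio *i*'s total inter-reinforcement time. `a`
("specific activation", s) indexes the reinforcer's incentive value; `δ`
(s/response) the motor limit on responding; `T0` and `k` the linear-waiting
pause dynamics. Because no event-level rat data are publicly available for
this design, the package also ships a synthetic-data generator that
realises the model as timestamped event logs with lognormal timing noise,
between-rat heterogeneity and multiplicative condition effects — so the
whole analysis chain is testable end to end against known ground truth.

The pipeline: **simulate** event logs → **extract** per-ratio pauses,
run times, rates and breakpoints (with the standard exclusion rules) →
**fit** (T0, k, a, δ) per rat by joint nonlinear least squares on the
running- and overall-rate curves → **analyze** with the field's standard
statistics (2×2 mixed ANOVA with partial η², repeated-measures ANOVA with
a linear dose contrast, within-subject Dunnett tests).

## Worked example

```python
import progratio as pr

sched = pr.ratio_progression(20)                 # exponential PR progression
params = pr.REFERENCE_PARAMS["sucrose"]          # T0=3.33, k=0.51, a=23.4, δ=0.21

sess = pr.generate_session(params, sched, seed=42)   # one noisy 40-min session
rec = pr.extract_ratios(sess, sched)
print(rec[rec.completed].tail(3).round(2))
bp = pr.breakpoint(sess, sched)
print("breakpoint:", bp.breakpoint, "criterion met:", bp.criterion_met)

rec["session_id"] = "s01"
res = pr.fit(pr.prepare_fit_table(rec, last_n_sessions=1), seed=0)
p = res.params
print(f"fitted: T0={p.t0:.2f} s  k={p.k:.2f}  a={p.a:.1f} s  "
      f"delta={p.delta:.3f} s  R2={res.r2:.3f}")
```

prints

```
 ratio_index    n  prp_s  run_s  ttot_s  r_run  r_overall  completed  excluded
          15   95  58.39 113.32  171.71   0.84       0.55       True     False
          16  118 136.23 186.94  323.16   0.63       0.37       True     False
          17  145 148.97 376.39  525.37   0.39       0.28       True     False
breakpoint: 145 criterion met: True
fitted: T0=2.66 s  k=0.60  a=25.9 s  delta=0.204 s  R2=0.880
```

The rat completed 17 ratios: pauses escalate (`prp_s`) and running rate
decays (`r_run`) exactly as the model prescribes, the breakpoint criterion
(≥ 5 min without a response) fired after ratio N = 145, and a single noisy
session already recovers the generating parameters to within ~10–20%
(fitting a rat's last ten sessions, the default, does much better — see
`docs/methods.md`). `pr.sucrose_mass(0.6, 50)` → `10.27` mg is the sucrose
delivered per 50 µl reinforcer of the 0.6 M solution.

The same pipeline is scriptable from the shell:

```bash
progratio simulate --config demo.yaml --seed 7 --out-dir run/
progratio extract  --config demo.yaml --out-dir run/
progratio fit      --config demo.yaml --seed 7 --out-dir run/
progratio analyze  --config demo.yaml --out-dir run/   # anova.csv, summary.csv, posthoc.csv
```

where `demo.yaml` overrides any of the defaults (group parameter means,
condition multipliers, cohort sizes, noise CVs, fit mode/bounds; see
`progratio.cli.DEFAULT_CONFIG`).

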