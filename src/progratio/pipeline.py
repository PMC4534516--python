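"""End-to-end experiment drivers: simulate → extract → fit → analyse.

These functions bind the pipeline stages together for the two study
designs (deprivation 2×2 and dose series) and for the Monte-Carlo
experiments that characterise the estimator: parameter recovery under
noise, detection power for a condition effect on the specific activation
a, and type-I calibration on null cohorts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .extract import extract_sessions, session_breakpoints
from .fitting import fit_per_rat
from .groupstats import mixed_anova_2x2
from .model import ParamSet
from .schedule import RatioSchedule, ratio_progression
from .synth import (
    FREE_FEEDING_EFFECTS,
    REFERENCE_PARAMS,
    CohortDesign,
    NoiseModel,
    generate_cohort,
)


def deprivation_design(
    seed: int = 0,
    n_rats: int = 12,
    n_sessions: int = 10,
    groups: Mapping[str, ParamSet] | None = None,
    free_feeding_effects: Mapping[str, float] | None = None,
    between_cv: float = 0.3,
    noise_cv: float = 0.2,
    n_terms: int = 20,
) -> CohortDesign:
    """A two-reinforcer, deprived/free-feeding cohort in the style of the
    reference experiment.  Pass ``free_feeding_effects={}`` for a null
    cohort (no condition effect)."""
    if groups is None:
        groups = {"sucrose": REFERENCE_PARAMS["sucrose"], "corn_oil": REFERENCE_PARAMS["corn_oil"]}
    if free_feeding_effects is None:
        free_feeding_effects = FREE_FEEDING_EFFECTS
    return CohortDesign(
        groups=dict(groups),
        conditions={"deprived": {}, "free_feeding": dict(free_feeding_effects)},
        n_rats=n_rats,
        n_sessions=n_sessions,
        between_cv=between_cv,
        noise=NoiseModel(pause_cv=noise_cv, run_cv=noise_cv),
        schedule=ratio_progression(n_terms),
        seed=seed,
    )


def run_cohort(
    design: CohortDesign,
    last_n_sessions: int | None = None,
    mode: str = "conditioned",
    multistart: int = 6,
    fit_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and carry it through extraction and fitting.

    Returns (params, breakpoints): per-rat×condition parameter estimates
    and per-session breakpoints.
    """
    sessions, _truth = generate_cohort(design)
    records = extract_sessions(sessions, design.schedule)
    bps = session_breakpoints(sessions, design.schedule)
    if last_n_sessions is None:
        last_n_sessions = design.n_sessions
    params = fit_per_rat(
        records,
        last_n_sessions=last_n_sessions,
        mode=mode,
        multistart=multistart,
        seed=fit_seed,
    )
    return params, bps


def deprivation_effect_p(params: pd.DataFrame, measure: str = "a") -> float:
    """p-value of the deprivation (within-subject) main effect on a fitted
    parameter in the 2×2 mixed ANOVA."""
    sub = params[["rat_id", "group", "condition", measure]].rename(columns={measure: "value"})
    table = mixed_anova_2x2(sub)
    return float(table.loc[table["effect"] == "condition", "p"].iloc[0])


def recovery_experiment(
    seed: int = 0,
    n_rats: int = 12,
    n_sessions: int = 10,
    noise_cv: float = 0.2,
    params: ParamSet | None = None,
    multistart: int = 8,
) -> dict[str, float]:
    """Recover group-mean parameters from a noisy homogeneous cohort.

    All rats share the same generating ParamSet (no between-rat spread);
    only session-level timing noise applies.  Returns the relative error of
    each recovered group-mean parameter and their median.
    """
    if params is None:
        params = REFERENCE_PARAMS["sucrose"]
    design = CohortDesign(
        groups={"sucrose": params},
        conditions={"deprived": {}},
        n_rats=n_rats,
        n_sessions=n_sessions,
        between_cv=0.0,
        noise=NoiseModel(pause_cv=noise_cv, run_cv=noise_cv),
        schedule=ratio_progression(20),
        seed=seed,
    )
    fitted, _ = run_cohort(design, multistart=multistart, fit_seed=seed + 1)
    truth = {"t0": params.t0, "k": params.k, "a": params.a, "delta": params.delta}
    errors = {
        name: abs(fitted[name].mean() - true) / true for name, true in truth.items()
    }
    errors["median"] = float(np.median(list(errors.values())))
    return errors


def effect_detection_rate(
    n_reps: int = 20,
    seed: int = 0,
    n_rats: int = 12,
    n_sessions: int = 4,
    alpha: float = 0.05,
    multistart: int = 4,
) -> float:
    """Fraction of replicate cohorts (free-feeding a×0.4) in which the
    deprivation main effect on fitted a is significant."""
    hits = 0
    for r in range(n_reps):
        design = deprivation_design(seed=seed + 1000 * r + 1, n_rats=n_rats, n_sessions=n_sessions)
        params, _ = run_cohort(design, multistart=multistart, fit_seed=seed + r)
        if deprivation_effect_p(params, "a") < alpha:
            hits += 1
    return hits / n_reps


def type1_rate(
    n_reps: int = 200,
    seed: int = 0,
    n_rats: int = 8,
    n_sessions: int = 3,
    alpha: float = 0.05,
    multistart: int = 3,
) -> float:
    """Fraction of null cohorts (no condition effects) in which the
    deprivation main effect on fitted a is (spuriously) significant."""
    hits = 0
    for r in range(n_reps):
        design = deprivation_design(
            seed=seed + 1000 * r + 7,
            n_rats=n_rats,
            n_sessions=n_sessions,
            free_feeding_effects={},
        )
        params, _ = run_cohort(design, multistart=multistart, fit_seed=seed + r)
        if deprivation_effect_p(params, "a") < alpha:
            hits += 1
    return hits / n_reps
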