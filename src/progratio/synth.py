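"""Synthetic event-level sessions and cohorts.

No raw rat-by-rat PR data are publicly available for this kind of
experiment, so the analysis pipeline is exercised on synthetic sessions
whose statistical structure matches what the measurement rules assume:
escalating post-reinforcement pauses and decelerating run rates driven by
the deterministic model, multiplicative (lognormal, mean-1) timing noise
within sessions, lognormal between-rat parameter heterogeneity, and
multiplicative condition effects on the parameters (e.g. free feeding
scaling down the specific activation a).

The generator is the inverse of the extraction step: with all noise
coefficients at zero, extracting a generated session reproduces the
deterministic trajectory to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .events import (
    LEVER_IN,
    LEVER_OUT,
    REINF_END,
    REINF_START,
    RESPONSE,
    SessionEvents,
)
from .model import (
    DEFAULT_REINFORCER_DURATION_S,
    DEFAULT_SESSION_LEN_S,
    ParamSet,
    pause_predict,
    run_rate_predict,
)
from .schedule import RatioSchedule, ratio_progression

#: Representative group-mean parameters for food-deprived female Wistar
#: rats responding for three reinforcer types (50 µl 0.6 M sucrose, 25 µl
#: corn oil, 45 mg food pellets) under the exponential PR schedule.  Used
#: as generating values for synthetic cohorts.
REFERENCE_PARAMS: dict[str, ParamSet] = {
    "sucrose": ParamSet(t0=3.33, k=0.51, a=23.4, delta=0.21),
    "corn_oil": ParamSet(t0=5.63, k=0.63, a=70.2, delta=0.44),
    "pellet": ParamSet(t0=4.81, k=0.50, a=28.1, delta=0.23),
}

#: Default multiplicative condition effects for a deprivation experiment:
#: free feeding reduces incentive value (a) sharply, shortens the minimum
#: pause and steepens the waiting slope relative to food deprivation.
FREE_FEEDING_EFFECTS: dict[str, float] = {"a": 0.4, "t0": 0.7, "k": 1.3}


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = _lognormal_sigma(cv)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class NoiseModel:
    """Within-session timing noise: independent multiplicative factors on
    each ratio's pause and run time.  ``cv=0`` reproduces the deterministic
    model exactly."""

    pause_cv: float = 0.2
    run_cv: float = 0.2
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.pause_cv < 0 or self.run_cv < 0:
            raise ArgumentError("noise CVs must be >= 0")
        if self.family != "lognormal":
            raise ArgumentError(f"unsupported noise family {self.family!r}")


def generate_session(
    params: ParamSet,
    schedule: RatioSchedule,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    session_len: float = DEFAULT_SESSION_LEN_S,
    reinforcer_duration: float = DEFAULT_REINFORCER_DURATION_S,
    rat_id: str = "rat",
    session_id: str = "s01",
    group: str = "",
    condition: str = "",
) -> SessionEvents:
    """Realise one session as a timestamped event log.

    Per ratio, the pause and run time are the model predictions —
    conditioned on the *realised* previous total inter-reinforcement time —
    times independent mean-1 lognormal factors.  Responses are evenly
    spaced across the run (for N=1 the single response falls at the end of
    the pause+run interval, so the realised T_TOT matches the model).
    Generation stops at lever withdrawal; responses of the in-progress
    ratio that precede it are kept, leaving that ratio incomplete.
    """
    rng = np.random.default_rng(seed)
    labels: list[str] = [LEVER_IN]
    times: list[float] = [0.0]
    clock = 0.0
    t_prev = 0.0
    for n_req in schedule.terms:
        pause = pause_predict(t_prev, params) * _noise_factors(rng, noise.pause_cv, 1)[0]
        run = (n_req / run_rate_predict(t_prev, params)) * _noise_factors(rng, noise.run_cv, 1)[0]
        if n_req == 1:
            resp_times = clock + pause + np.array([run])
        else:
            resp_times = clock + pause + run * np.arange(n_req) / (n_req - 1)
        # the reinforcer is delivered at the actual last response time, which
        # can differ from clock+pause+run by one ulp of rounding
        completion = float(resp_times[-1])
        if completion > session_len:
            kept = resp_times[resp_times < session_len]
            labels.extend([RESPONSE] * kept.size)
            times.extend(kept.tolist())
            break
        labels.extend([RESPONSE] * n_req)
        times.extend(resp_times.tolist())
        labels.append(REINF_START)
        times.append(completion)
        labels.append(REINF_END)
        times.append(min(completion + reinforcer_duration, session_len))
        t_prev = completion - clock  # realised pause+run, as extraction measures it
        clock = completion + reinforcer_duration
        if clock >= session_len:
            break
    labels.append(LEVER_OUT)
    times.append(float(session_len))
    return SessionEvents(
        rat_id=rat_id,
        session_id=session_id,
        group=group,
        condition=condition,
        labels=np.array(labels, dtype=object),
        times=np.array(times, dtype=float),
    )


@dataclass
class CohortDesign:
    """Description of a synthetic experiment.

    ``groups`` maps group label (reinforcer type) → group-mean ParamSet.
    ``conditions`` maps condition label → multiplicative effects on named
    parameters (missing parameters keep factor 1).  Each rat draws a base
    ParamSet lognormally around its group mean with between-rat coefficient
    of variation ``between_cv`` (scalar, or per-parameter mapping), then
    experiences every condition with the effects applied.
    """

    groups: Mapping[str, ParamSet]
    conditions: Mapping[str, Mapping[str, float]]
    n_rats: int = 12
    n_sessions: int = 10
    between_cv: float | Mapping[str, float] = 0.3
    noise: NoiseModel = field(default_factory=NoiseModel)
    schedule: RatioSchedule = field(default_factory=lambda: ratio_progression(20))
    session_len: float = DEFAULT_SESSION_LEN_S
    reinforcer_duration: float = DEFAULT_REINFORCER_DURATION_S
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ArgumentError("design needs at least one group")
        if not self.conditions:
            raise ArgumentError("design needs at least one condition")
        if self.n_rats < 1 or self.n_sessions < 1:
            raise ArgumentError("n_rats and n_sessions must be >= 1")
        for cond, effects in self.conditions.items():
            for name, f in effects.items():
                if f <= 0:
                    raise ArgumentError(
                        f"condition {cond!r}: effect on {name!r} must be > 0, got {f}"
                    )

    def cv_for(self, name: str) -> float:
        if isinstance(self.between_cv, Mapping):
            return float(self.between_cv.get(name, 0.0))
        return float(self.between_cv)


def generate_cohort(design: CohortDesign) -> tuple[list[SessionEvents], pd.DataFrame]:
    """Generate every session of a cohort plus the ground-truth design table.

    Returns (sessions, truth) where ``truth`` has one row per rat×condition
    carrying the true generating parameters (for recovery tests).  Seeding
    is hierarchical — master seed → per-rat → per-session streams — so
    identical designs reproduce identical cohorts.
    """
    master = np.random.SeedSequence(design.seed)
    rat_seqs = master.spawn(len(design.groups) * design.n_rats)
    sessions: list[SessionEvents] = []
    truth_rows: list[dict] = []
    rat_counter = 0
    for group, mean_params in design.groups.items():
        for j in range(design.n_rats):
            rat_seq = rat_seqs[rat_counter]
            rat_counter += 1
            rat_id = f"{group}_r{j + 1:02d}"
            streams = rat_seq.spawn(1 + len(design.conditions) * design.n_sessions)
            prng = np.random.default_rng(streams[0])
            base = {
                name: getattr(mean_params, name)
                * _noise_factors(prng, design.cv_for(name), 1)[0]
                for name in ("t0", "k", "a", "delta")
            }
            stream_i = 1
            for cond, effects in design.conditions.items():
                rat_params = ParamSet(**base).scaled(dict(effects))
                truth_rows.append(
                    {
                        "rat_id": rat_id,
                        "group": group,
                        "condition": cond,
                        "t0": rat_params.t0,
                        "k": rat_params.k,
                        "a": rat_params.a,
                        "delta": rat_params.delta,
                    }
                )
                for s in range(design.n_sessions):
                    sessions.append(
                        generate_session(
                            rat_params,
                            design.schedule,
                            noise=design.noise,
                            seed=streams[stream_i],
                            session_len=design.session_len,
                            reinforcer_duration=design.reinforcer_duration,
                            rat_id=rat_id,
                            session_id=f"s{s + 1:02d}",
                            group=group,
                            condition=cond,
                        )
                    )
                    stream_i += 1
    return sessions, pd.DataFrame(truth_rows)
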