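"""Deterministic model of progressive-ratio performance.

The model combines the linear-waiting principle with the rate equations of
Killeen's Mathematical Principles of Reinforcement (MPR).  For ratio i with
requirement N_i, writing T_TOT,i for the total inter-reinforcement time
(pause + run), the post-reinforcement pause and within-ratio ("running")
response rate are

    T_P,i     = T0 + k · T_TOT,i-1                    (linear waiting)
    R_RUN,i   = 1 / (δ · (1 + T_TOT,i-1 / a))         (MPR running rate)
    R_OVL,i   = N_i / T_TOT,i                         (overall rate)

with parameters

    T0  minimum post-reinforcement pause (s)
    k   slope of the linear waiting function (dimensionless)
    a   specific activation (s): seconds of behaviour activated by one
        reinforcer; interpreted as the reinforcer's incentive value
    δ   minimum time to execute one response (s): 1/δ is the motor ceiling
        on response rate.

Composing the two equations gives the forward recursion

    T_TOT,i = (T0 + k·T_TOT,i-1) + N_i · δ · (1 + T_TOT,i-1 / a)

which is affine in T_TOT,i-1.  On a constant-N schedule it contracts to the
fixed point (T0 + Nδ)/(1 − k − Nδ/a) whenever k + Nδ/a < 1; on a growing
progression the totals escalate until the session clock runs out, which is
what terminates responding in this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .schedule import RatioSchedule

#: Default session length (s): lever withdrawn 40 min after insertion.
DEFAULT_SESSION_LEN_S = 2400.0

#: Default reinforcer-delivery time (s), counted on the session clock only.
DEFAULT_REINFORCER_DURATION_S = 5.0


@dataclass(frozen=True)
class ParamSet:
    """The model's four parameters for one subject under one condition."""

    t0: float
    k: float
    a: float
    delta: float

    def __post_init__(self) -> None:
        if self.t0 < 0:
            raise ArgumentError(f"T0 must be >= 0, got {self.t0}")
        if self.k < 0:
            raise ArgumentError(f"k must be >= 0, got {self.k}")
        if self.a <= 0:
            raise ArgumentError(f"a must be > 0, got {self.a}")
        if self.delta <= 0:
            raise ArgumentError(f"delta must be > 0, got {self.delta}")

    def scaled(self, factors: dict[str, float]) -> "ParamSet":
        """Return a copy with named parameters multiplied by ``factors``."""
        vals = {"t0": self.t0, "k": self.k, "a": self.a, "delta": self.delta}
        for name, f in factors.items():
            if name not in vals:
                raise ArgumentError(f"unknown parameter {name!r}")
            if f <= 0:
                raise ArgumentError(f"multiplicative effect on {name!r} must be > 0, got {f}")
            vals[name] *= f
        return ParamSet(**vals)


def pause_predict(t_tot_prev: float, params: ParamSet) -> float:
    """Linear-waiting pause: T0 + k · (previous total inter-reinforcement time)."""
    if t_tot_prev < 0:
        raise ArgumentError("t_tot_prev must be >= 0")
    return params.t0 + params.k * t_tot_prev


def run_rate_predict(t_tot_prev: float, params: ParamSet) -> float:
    """Running response rate 1/(δ·(1 + T_TOT,i-1/a)), responses/s.

    Equals the motor ceiling 1/δ when the previous interval is zero and
    halves when it equals the specific activation a.
    """
    if np.any(np.asarray(t_tot_prev) < 0):
        raise ArgumentError("t_tot_prev must be >= 0")
    return 1.0 / (params.delta * (1.0 + t_tot_prev / params.a))


def overall_rate(n: float, t_tot: float) -> float:
    """Overall response rate N/T_TOT (responses/s) for one completed ratio."""
    if n < 1:
        raise ArgumentError("n must be >= 1")
    if t_tot <= 0:
        raise ArgumentError("t_tot must be > 0")
    return n / t_tot


@dataclass
class Trajectory:
    """Per-ratio predictions of one deterministic session.

    ``completion_time`` is the session clock at the last response of each
    ratio (pauses, runs and reinforcer deliveries all accumulate).  The
    final row may be flagged incomplete: its completion would have fallen
    after lever withdrawal.
    """

    n: np.ndarray
    pause: np.ndarray
    run_time: np.ndarray
    t_tot: np.ndarray
    r_run: np.ndarray
    r_overall: np.ndarray
    completed: np.ndarray
    completion_time: np.ndarray
    session_len: float

    def __len__(self) -> int:
        return len(self.n)

    @property
    def n_completed(self) -> int:
        return int(self.completed.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ratio_index": np.arange(1, len(self.n) + 1),
                "n": self.n,
                "pause_s": self.pause,
                "run_s": self.run_time,
                "ttot_s": self.t_tot,
                "r_run": self.r_run,
                "r_overall": self.r_overall,
                "completed": self.completed,
                "completion_time_s": self.completion_time,
            }
        )


def forward_simulate(
    params: ParamSet,
    schedule: RatioSchedule,
    session_len: float = DEFAULT_SESSION_LEN_S,
    t_tot_init: float = 0.0,
    reinforcer_duration: float = DEFAULT_REINFORCER_DURATION_S,
) -> Trajectory:
    """Iterate the pause/run recursion over a schedule within a session.

    Starts from ``t_tot_init`` (0 by default: the session opens with lever
    insertion, no reinforcer precedes ratio 1).  Run time for ratio i is
    N_i/R_RUN,i.  The reinforcer-delivery time advances the session clock
    but is not part of any ratio's T_TOT.  The first ratio whose last
    response would fall after ``session_len`` is recorded and flagged
    incomplete, and iteration stops there.
    """
    if len(schedule) == 0:
        raise ArgumentError("schedule is empty")
    if session_len <= 0:
        raise ArgumentError("session_len must be > 0")
    if t_tot_init < 0:
        raise ArgumentError("t_tot_init must be >= 0")
    rows: list[tuple] = []
    clock = 0.0
    t_prev = float(t_tot_init)
    for n_req in schedule.terms:
        pause = pause_predict(t_prev, params)
        r_run = run_rate_predict(t_prev, params)
        run = n_req / r_run
        t_tot = pause + run
        completion = clock + t_tot
        done = completion <= session_len
        rows.append((n_req, pause, run, t_tot, r_run, n_req / t_tot, done, completion))
        if not done:
            break
        clock = completion + reinforcer_duration
        t_prev = t_tot
    cols = list(zip(*rows))
    return Trajectory(
        n=np.array(cols[0], dtype=int),
        pause=np.array(cols[1]),
        run_time=np.array(cols[2]),
        t_tot=np.array(cols[3]),
        r_run=np.array(cols[4]),
        r_overall=np.array(cols[5]),
        completed=np.array(cols[6], dtype=bool),
        completion_time=np.array(cols[7]),
        session_len=float(session_len),
    )


def constant_schedule_fixed_point(params: ParamSet, n: int) -> float:
    """Fixed point (T0 + Nδ)/(1 − k − Nδ/a) of the recursion at constant N.

    Defined only when the affine recursion contracts, i.e. k + Nδ/a < 1.
    """
    if n < 1:
        raise ArgumentError("n must be >= 1")
    slope = params.k + n * params.delta / params.a
    if slope >= 1:
        raise ArgumentError(
            f"no finite fixed point: contraction condition k + N*delta/a < 1 fails ({slope:.3f})"
        )
    return (params.t0 + n * params.delta) / (1.0 - slope)
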