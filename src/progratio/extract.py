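"""Per-ratio measures from event logs, with the standard exclusion rules.

For each completed ratio the post-reinforcement pause (PRP) runs from the
end of the preceding reinforcer delivery (lever insertion for ratio 1) to
the first response; the run time from the first to the last response; the
total time is their sum.  Running rate is N/run-time, overall rate
N/total-time.  The first ratio (a single response, so no run time) and any
ratio left incomplete at lever withdrawal are recorded but excluded from
model fitting.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, IntegrityError
from .events import LEVER_IN, REINF_END, REINF_START, RESPONSE, SessionEvents
from .schedule import DEFAULT_BREAKPOINT_GAP_S, RatioSchedule, breakpoint

#: Columns of a per-ratio record table.
RATIO_COLUMNS = (
    "ratio_index",
    "n",
    "prp_s",
    "run_s",
    "ttot_s",
    "r_run",
    "r_overall",
    "completed",
    "excluded",
)


def extract_ratios(events: SessionEvents, schedule: RatioSchedule) -> pd.DataFrame:
    """Measure every ratio of one session.

    Returns one row per ratio that was at least started (had a response),
    in schedule order, with columns ``RATIO_COLUMNS``.  ``excluded`` marks
    rows that the fitting step must ignore: the first ratio, incomplete
    ratios, and any ratio whose running rate is undefined (N=1).  Response
    counts inconsistent with the schedule raise :class:`IntegrityError`
    naming the ratio index.
    """
    responses = events.times_of(RESPONSE)
    completions = events.times_of(REINF_START)
    reinf_ends = events.times_of(REINF_END)
    m = int(completions.size)
    if m > len(schedule):
        raise IntegrityError(
            f"session completed {m} ratios but the schedule defines {len(schedule)}"
        )
    if reinf_ends.size != m:
        raise IntegrityError("unmatched REINF_START/REINF_END events")
    rows: list[tuple] = []
    prev_end = 0.0  # LEVER_IN at t=0 starts the first pause
    prev_completion = -np.inf
    lo = 0
    for i in range(m):
        hi = int(np.searchsorted(responses, completions[i], side="right"))
        n_i = hi - lo
        n_req = schedule.terms[i]
        if n_i != n_req:
            raise IntegrityError(
                f"ratio {i + 1}: {n_i} responses recorded, schedule requires {n_req}"
            )
        first, last = responses[lo], responses[hi - 1]
        prp = first - prev_end
        run = last - first
        t_tot = prp + run
        r_run = n_i / run if n_i >= 2 and run > 0 else np.nan
        r_overall = n_i / t_tot
        excluded = (i == 0) or not np.isfinite(r_run)
        if excluded and i > 0:
            warnings.warn(
                f"ratio {i + 1}: running rate undefined, excluded from fitting",
                stacklevel=2,
            )
        rows.append((i + 1, n_i, prp, run, t_tot, r_run, r_overall, True, excluded))
        prev_end = reinf_ends[i]
        prev_completion = completions[i]
        lo = hi
    # trailing incomplete ratio, if it was started
    if lo < responses.size:
        n_obs = int(responses.size - lo)
        if m < len(schedule) and n_obs >= schedule.terms[m]:
            raise IntegrityError(
                f"ratio {m + 1}: {n_obs} responses but no reinforcer delivery recorded"
            )
        first, last = responses[lo], responses[-1]
        rows.append(
            (m + 1, n_obs, first - prev_end, last - first, np.nan, np.nan, np.nan, False, True)
        )
    df = pd.DataFrame(rows, columns=list(RATIO_COLUMNS))
    return df.astype({"ratio_index": int, "n": int, "completed": bool, "excluded": bool})


def extract_sessions(
    sessions: Iterable[SessionEvents], schedule: RatioSchedule
) -> pd.DataFrame:
    """Extract many sessions into one table with identifier columns."""
    frames = []
    for s in sessions:
        df = extract_ratios(s, schedule)
        df.insert(0, "rat_id", s.rat_id)
        df.insert(1, "group", s.group)
        df.insert(2, "condition", s.condition)
        df.insert(3, "session_id", s.session_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["rat_id", "group", "condition", "session_id", *RATIO_COLUMNS]
        )
    return pd.concat(frames, ignore_index=True)


def session_breakpoints(
    sessions: Iterable[SessionEvents],
    schedule: RatioSchedule,
    gap_s: float = DEFAULT_BREAKPOINT_GAP_S,
) -> pd.DataFrame:
    """Breakpoint of every session (one row each)."""
    rows = []
    for s in sessions:
        bp = breakpoint(s, schedule, gap_s=gap_s)
        rows.append(
            {
                "rat_id": s.rat_id,
                "group": s.group,
                "condition": s.condition,
                "session_id": s.session_id,
                "breakpoint": bp.breakpoint,
                "criterion_met": bp.criterion_met,
                "ratio_index": bp.ratio_index,
            }
        )
    return pd.DataFrame(rows)


def _select_last_sessions(records: pd.DataFrame, last_n_sessions: int) -> pd.DataFrame:
    order = sorted(records["session_id"].unique())
    if len(order) < last_n_sessions:
        warnings.warn(
            f"only {len(order)} sessions available, requested last {last_n_sessions}; using all",
            stacklevel=3,
        )
    keep = order[-last_n_sessions:]
    return records[records["session_id"].isin(keep)]


def average_per_ratio(records: pd.DataFrame, last_n_sessions: int = 10) -> pd.DataFrame:
    """Per-ratio-index means over the last ``last_n_sessions`` sessions.

    ``records`` is the per-ratio table of one rat under one condition with a
    ``session_id`` column.  For each ratio index the mean of r_run,
    r_overall, prp and t_tot is taken over the sessions in which that ratio
    was completed; ``n_sessions`` reports how many contributed.
    """
    if records.empty:
        raise ArgumentError("no records to average")
    sel = _select_last_sessions(records, last_n_sessions)
    done = sel[sel["completed"]]
    grouped = done.groupby("ratio_index", sort=True)
    out = grouped.agg(
        n=("n", "first"),
        prp_s=("prp_s", "mean"),
        run_s=("run_s", "mean"),
        ttot_s=("ttot_s", "mean"),
        r_run=("r_run", "mean"),
        r_overall=("r_overall", "mean"),
        n_sessions=("session_id", "nunique"),
    ).reset_index()
    out["excluded"] = (out["ratio_index"] == 1) | ~np.isfinite(out["r_run"])
    return out


def prepare_fit_table(
    records: pd.DataFrame,
    last_n_sessions: int = 10,
    method: str = "average",
) -> pd.DataFrame:
    """Build the table the fitting step consumes from one rat×condition's
    per-ratio records.

    ``method="average"`` (default): session-averaged rates per ratio index,
    each point conditioned on the mean total time of the previous index.
    ``method="pooled"``: every completed session-ratio is its own point,
    conditioned on the same session's previous total time.  Rows flagged
    ``usable=False`` (first ratio, undefined rates, missing previous total)
    are kept for reference but ignored by the fit.
    """
    if method == "average":
        table = average_per_ratio(records, last_n_sessions=last_n_sessions)
        prev = table.set_index("ratio_index")["ttot_s"]
        table["ttot_prev_s"] = (table["ratio_index"] - 1).map(prev).to_numpy()
    elif method == "pooled":
        sel = _select_last_sessions(records, last_n_sessions).copy()
        sel = sel.sort_values(["session_id", "ratio_index"])
        sel["ttot_prev_s"] = sel.groupby("session_id")["ttot_s"].shift(1)
        contiguous = sel.groupby("session_id")["ratio_index"].diff().fillna(0) == 1
        sel.loc[~contiguous, "ttot_prev_s"] = np.nan
        table = sel[sel["completed"]][
            ["ratio_index", "n", "prp_s", "run_s", "ttot_s", "r_run", "r_overall", "ttot_prev_s"]
        ].reset_index(drop=True)
        table["excluded"] = (table["ratio_index"] == 1) | ~np.isfinite(table["r_run"])
        table["n_sessions"] = 1
    else:
        raise ArgumentError(f"unknown method {method!r}")
    table["usable"] = (
        ~table["excluded"]
        & np.isfinite(table["r_run"])
        & np.isfinite(table["r_overall"])
        & np.isfinite(table["ttot_prev_s"])
    )
    return table
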