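"""Timestamped operant-session event logs and their CSV serialization.

A session is the interval between insertion and withdrawal of the response
lever.  Everything the analysis needs — post-reinforcement pauses, run
times, response counts, breakpoints — is recoverable from the ordered
sequence of lever responses and reinforcer deliveries, so that sequence is
the canonical on-disk representation (one CSV row per event).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, ParseError

LEVER_IN = "LEVER_IN"
RESPONSE = "RESPONSE"
REINF_START = "REINF_START"
REINF_END = "REINF_END"
LEVER_OUT = "LEVER_OUT"

EVENT_LABELS = (LEVER_IN, RESPONSE, REINF_START, REINF_END, LEVER_OUT)

#: CSV column order for event logs.
EVENT_COLUMNS = ("rat_id", "session_id", "group", "condition", "event", "time_s")


@dataclass
class SessionEvents:
    """One session's ordered event log plus its identifiers.

    ``labels``/``times`` are parallel arrays; times are seconds from lever
    insertion (``LEVER_IN`` at t=0, ``LEVER_OUT`` at session end).
    """

    rat_id: str
    session_id: str
    group: str
    condition: str
    labels: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        if self.labels.shape != self.times.shape:
            raise ArgumentError("labels and times must have equal length")

    # -- convenience accessors -------------------------------------------
    def times_of(self, label: str) -> np.ndarray:
        return self.times[self.labels == label]

    @property
    def session_len(self) -> float:
        out = self.times_of(LEVER_OUT)
        return float(out[-1]) if out.size else float(self.times[-1])

    def validate(self) -> None:
        """Check the structural invariants of a well-formed session."""
        if np.any(np.diff(self.times) < 0):
            raise ArgumentError("event times must be non-decreasing")
        n_in = int(np.sum(self.labels == LEVER_IN))
        n_out = int(np.sum(self.labels == LEVER_OUT))
        if n_in != 1 or n_out != 1:
            raise ArgumentError("session must have exactly one LEVER_IN and one LEVER_OUT")
        if self.labels[0] != LEVER_IN or self.times[0] != 0.0:
            raise ArgumentError("session must start with LEVER_IN at t=0")
        if self.labels[-1] != LEVER_OUT:
            raise ArgumentError("session must end with LEVER_OUT")
        unknown = set(self.labels) - set(EVENT_LABELS)
        if unknown:
            raise ArgumentError(f"unknown event labels: {sorted(unknown)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rat_id": self.rat_id,
                "session_id": self.session_id,
                "group": self.group,
                "condition": self.condition,
                "event": self.labels,
                "time_s": self.times,
            }
        )


def write_event_log(sessions: Iterable[SessionEvents], path: str | Path) -> None:
    """Write sessions to CSV (columns ``EVENT_COLUMNS``, times at 6 decimals).

    An empty collection produces a header-only file.  The format round-trips
    losslessly through :func:`read_event_log` byte-for-byte.
    """
    frames = [s.to_frame() for s in sessions]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(EVENT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_event_log(path: str | Path) -> list[SessionEvents]:
    """Read an event-log CSV back into a list of :class:`SessionEvents`.

    Sessions are keyed by (rat_id, condition, session_id) in order of first
    appearance; rows within a session keep file order, so write→read→write
    is byte-identical.  Malformed rows raise :class:`ParseError` naming the
    1-based file line.
    """
    path = Path(path)
    if not path.exists():
        raise ArgumentError(f"event log not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"missing columns: {sorted(missing)}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = np.flatnonzero(times.isna().to_numpy())
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ParseError(f"unparseable time_s value {df['time_s'].iloc[bad[0]]!r}", line=int(bad[0]) + 2)
    bad_label = np.flatnonzero(~df["event"].isin(EVENT_LABELS).to_numpy())
    if bad_label.size:
        raise ParseError(
            f"unknown event label {df['event'].iloc[bad_label[0]]!r}", line=int(bad_label[0]) + 2
        )
    df = df.assign(time_s=times.to_numpy(dtype=float))
    sessions: list[SessionEvents] = []
    for (rat, cond, sess), sub in df.groupby(["rat_id", "condition", "session_id"], sort=False):
        sessions.append(
            SessionEvents(
                rat_id=str(rat),
                session_id=str(sess),
                group=str(sub["group"].iloc[0]),
                condition=str(cond),
                labels=sub["event"].to_numpy(dtype=object),
                times=sub["time_s"].to_numpy(dtype=float),
            )
        )
    return sessions
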