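"""Ratio progressions, breakpoint computation and reinforcer arithmetic.

Under a progressive-ratio (PR) schedule the response requirement *N* grows
from one reinforcer to the next.  The exponential progression used here,

    N_n = round(5 · e^(0.2 n) − 5),   n = 1, 2, 3, ...

yields 1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, ... and roughly doubles the
requirement every 3–4 steps, so a 40-min session spans two orders of
magnitude of work per reinforcer.  The breakpoint — classically read as an
index of the subject's motivation — is the last ratio completed before a
5-min period without responding (or, failing that criterion, the highest
completed ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ArgumentError, NoBreakpointError
from .events import LEVER_IN, LEVER_OUT, REINF_START, RESPONSE, SessionEvents

#: Molar mass of sucrose, g/mol.
SUCROSE_MOLAR_MASS = 342.30

#: Response-free interval (s) that operationally defines "stopped responding".
DEFAULT_BREAKPOINT_GAP_S = 300.0


@dataclass(frozen=True)
class RatioSchedule:
    """An ordered sequence of response requirements, one per reinforcer."""

    terms: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise ArgumentError("schedule must contain at least one ratio")
        terms = tuple(int(t) for t in self.terms)
        if any(t < 1 for t in terms):
            raise ArgumentError("all ratio requirements must be >= 1")
        if any(b < a for a, b in zip(terms, terms[1:])):
            raise ArgumentError("ratio requirements must be non-decreasing")
        object.__setattr__(self, "terms", terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, i: int) -> int:
        return self.terms[i]


@dataclass(frozen=True)
class BreakpointResult:
    """Breakpoint of one session.

    ``breakpoint`` is the ratio value N; ``ratio_index`` its 1-based position
    in the schedule; ``criterion_met`` is True when a qualifying response-free
    gap occurred (False means the fallback "highest completed ratio" fired).
    """

    breakpoint: int
    criterion_met: bool
    ratio_index: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def ratio_progression(n_terms: int, *, scale: float = 5.0, rate: float = 0.2) -> RatioSchedule:
    """Exponential PR progression: term n = round(scale·e^(rate·n) − scale).

    Rounding is round-half-up to the nearest integer.  With the default
    coefficients the first eleven terms are 1, 2, 4, 6, 9, 12, 15, 20, 25,
    32, 40.
    """
    if int(n_terms) != n_terms or n_terms < 1:
        raise ArgumentError(f"n_terms must be a positive integer, got {n_terms!r}")
    terms = tuple(
        _round_half_up(scale * math.exp(rate * n) - scale) for n in range(1, int(n_terms) + 1)
    )
    return RatioSchedule(terms)


def breakpoint(
    events: SessionEvents,
    schedule: RatioSchedule,
    gap_s: float = DEFAULT_BREAKPOINT_GAP_S,
) -> BreakpointResult:
    """Breakpoint of a session: last ratio completed before the first
    response-free interval of at least ``gap_s`` seconds.

    The gap scan covers the interval from lever insertion to the first
    response, all inter-response intervals, and the interval from the last
    response to lever withdrawal; a gap of exactly ``gap_s`` counts.  When
    no qualifying gap exists the highest completed ratio is returned with
    ``criterion_met=False``.  A session with no completed ratio (or none
    completed before the first gap) has no defined breakpoint.
    """
    if gap_s <= 0:
        raise ArgumentError("gap_s must be positive")
    responses = events.times_of(RESPONSE)
    completions = events.times_of(REINF_START)
    if completions.size == 0:
        raise NoBreakpointError(
            f"session {events.rat_id}/{events.session_id}: no completed ratio"
        )
    if completions.size > len(schedule):
        raise ArgumentError("session completed more ratios than the schedule defines")
    lever_in = events.times_of(LEVER_IN)
    lever_out = events.times_of(LEVER_OUT)
    start = float(lever_in[0]) if lever_in.size else 0.0
    end = float(lever_out[-1]) if lever_out.size else float(events.times[-1])
    points = np.concatenate(([start], responses, [end]))
    gaps = np.diff(points)
    qualifying = np.flatnonzero(gaps >= gap_s)
    if qualifying.size:
        gap_start = float(points[qualifying[0]])
        k = int(np.searchsorted(completions, gap_start, side="right"))
        if k == 0:
            raise NoBreakpointError(
                f"session {events.rat_id}/{events.session_id}: "
                "no ratio completed before the first qualifying response gap"
            )
        return BreakpointResult(schedule.terms[k - 1], True, k)
    m = int(completions.size)
    return BreakpointResult(schedule.terms[m - 1], False, m)


def sucrose_mass(
    molarity: float, volume_ul: float, molar_mass: float = SUCROSE_MOLAR_MASS
) -> float:
    """Mass (mg) of solute delivered per reinforcer.

    ``molarity`` in mol/L, ``volume_ul`` in microlitres.  E.g. 50 µl of
    0.6 M sucrose carries 10.27 mg of sucrose.
    """
    if molarity < 0 or volume_ul < 0 or molar_mass < 0:
        raise ArgumentError("molarity, volume and molar mass must be non-negative")
    # mol/L × µL = µmol; µmol × g/mol = µg; /1000 → mg
    return molarity * volume_ul * molar_mass / 1000.0
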