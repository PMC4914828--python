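"""Deterministic expectation dynamics of CpG dyad states across divisions.

Each average cell division applies, in order:

1. **oxidation** — every 5mC strand becomes 5hmC with probability p3;
2. **replication** — every dyad is replaced, in expectation, by a dyad
   pairing one parent strand (drawn proportionally to strand abundance)
   with a nascent unmodified strand;
3. **maintenance** — post-replication hemi-methylated (m,u) dyads are
   restored to (m,m) with probability p2; (h,u) dyads are never maintained;
4. **de novo** — post-replication (u,u) dyads become (m,u) with
   probability p1.

Because replication pairs every surviving strand with a nascent u strand,
states carrying 5hmC opposite 5mC or 5hmC (mh, hh) cannot be produced by a
division; 5hmC is lost purely by replication dilution. The event order is
configurable for sensitivity analysis but the above is the default.

At the strand level the recursion is

    f' = [ f(1-p3)(1+p2) + (1-f-h) p1 ] / 2,      h' = [ h + f p3 ] / 2

with f, h the per-strand 5mC and 5hmC fractions, which yields the closed
form steady state implemented in :func:`steady_state`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import (
    DyadStateVector,
    GlobalLevels,
    RateParameters,
    Trajectory,
    ValidationError,
)

__all__ = [
    "division_step",
    "strand_summary",
    "steady_state",
    "steady_state_dyads",
    "p1_at",
    "simulate",
    "DEFAULT_EVENT_ORDER",
]

DEFAULT_EVENT_ORDER = ("oxidation", "replication", "maintenance", "de_novo")


def _oxidize(state: DyadStateVector, p3: float) -> DyadStateVector:
    # each m strand independently becomes h with probability p3
    q = 1.0 - p3
    return DyadStateVector(
        uu=state.uu,
        um=state.um * q,
        mm=state.mm * q * q,
        uh=state.uh + state.um * p3,
        mh=state.mh * q + 2.0 * state.mm * q * p3,
        hh=state.hh + state.mh * p3 + state.mm * p3 * p3,
    )


def _replicate(state: DyadStateVector) -> tuple[float, float, float]:
    """Expected post-replication dyad mix as (m,u), (h,u), (u,u) weights."""
    f, h = state.strand_fractions()
    return f, h, 1.0 - f - h


def division_step(
    state: DyadStateVector,
    p: RateParameters,
    p1_value: float | None = None,
    event_order: Sequence[str] = DEFAULT_EVENT_ORDER,
) -> DyadStateVector:
    """Advance the expected dyad-state distribution by one cell division.

    ``p1_value`` overrides the de novo rate for this division (used by
    :func:`simulate` to evaluate a p1 schedule at the division boundary);
    defaults to ``p.p1``.

    Alternative within-division event orders are supported for sensitivity
    checks: any permutation of the four canonical events, with
    ``replication`` present exactly once.
    """
    state.validate()
    p1 = p.p1 if p1_value is None else p1_value
    if not 0.0 <= p1 <= 1.0:
        raise ValidationError(f"p1 value {p1!r} outside [0, 1]")

    if tuple(event_order) == DEFAULT_EVENT_ORDER:
        ox = _oxidize(state, p.p3)
        fm, fh, fu = _replicate(ox)
        return DyadStateVector(
            uu=fu * (1.0 - p1),
            um=fm * (1.0 - p.p2) + fu * p1,
            mm=fm * p.p2,
            uh=fh,
            mh=0.0,
            hh=0.0,
        )
    return _step_generic(state, p, p1, tuple(event_order))


def _step_generic(
    state: DyadStateVector, p: RateParameters, p1: float, order: tuple[str, ...]
) -> DyadStateVector:
    if sorted(order) != sorted(DEFAULT_EVENT_ORDER):
        raise ValidationError(
            f"event_order must be a permutation of {DEFAULT_EVENT_ORDER}, got {order}"
        )
    cur = state
    for ev in order:
        if ev == "oxidation":
            cur = _oxidize(cur, p.p3)
        elif ev == "replication":
            fm, fh, fu = _replicate(cur)
            cur = DyadStateVector(uu=fu, um=fm, uh=fh)
        elif ev == "maintenance":
            cur = DyadStateVector(
                uu=cur.uu,
                um=cur.um * (1.0 - p.p2),
                mm=cur.mm + cur.um * p.p2,
                uh=cur.uh,
                mh=cur.mh,
                hh=cur.hh,
            )
        elif ev == "de_novo":
            cur = DyadStateVector(
                uu=cur.uu * (1.0 - p1),
                um=cur.um + cur.uu * p1,
                mm=cur.mm,
                uh=cur.uh,
                mh=cur.mh,
                hh=cur.hh,
            )
    return cur


def strand_summary(state: DyadStateVector) -> GlobalLevels:
    """Global per-strand 5mC/5hmC fractions of a dyad-state distribution:
    five_mC = mm + (um + mh)/2, five_hmC = hh + (uh + mh)/2."""
    state.validate()
    f, h = state.strand_fractions()
    return GlobalLevels(five_mC=f, five_hmC=h)


def steady_state(p: RateParameters) -> GlobalLevels:
    """Closed-form fixed point of the strand-level recursion.

    f* = p1 / (2 - (1-p3)(1+p2) + p1(1+p3)), h* = p3 f*. Requires constant
    parameters (no p1 schedule). Agrees with iterating
    :func:`division_step` to convergence (checked to 1e-9 in tests).
    """
    if not p.is_constant:
        raise ValidationError("steady_state requires constant p1 (no schedule)")
    denom = 2.0 - (1.0 - p.p3) * (1.0 + p.p2) + p.p1 * (1.0 + p.p3)
    if denom <= 0:
        # only at p1=0, p2=1, p3=0: perfect maintenance preserves any level
        raise ValidationError(
            "steady state undefined at p1=0, p2=1, p3=0 (every level is fixed)"
        )
    f = p.p1 / denom
    return GlobalLevels(five_mC=f, five_hmC=p.p3 * f)


def steady_state_dyads(p: RateParameters) -> DyadStateVector:
    """Dyad-state distribution at the steady state, i.e. the post-division
    distribution implied by the fixed-point strand fractions."""
    lv = steady_state(p)
    f, h = lv.five_mC, lv.five_hmC
    # strand mix entering replication (after oxidation)
    fm = f * (1.0 - p.p3)
    fh = h + f * p.p3
    fu = 1.0 - fm - fh
    return DyadStateVector(
        uu=fu * (1.0 - p.p1),
        um=fm * (1.0 - p.p2) + fu * p.p1,
        mm=fm * p.p2,
        uh=fh,
    )


def p1_at(t: float, p: RateParameters) -> float:
    """De novo rate at ``t`` hours after the parameter set took effect
    (exponential relaxation when a schedule is set, else constant)."""
    return p.p1_at(t)


def _normalize_schedule(
    schedule: Sequence[tuple[float, RateParameters]] | RateParameters,
    t_end: float,
) -> list[tuple[float, float, RateParameters]]:
    """Return contiguous (start, end, params) intervals covering [0, t_end]."""
    if isinstance(schedule, RateParameters):
        schedule = [(t_end, schedule)]
    if not schedule:
        raise ValidationError("schedule must contain at least one interval")
    out = []
    start = 0.0
    for duration, params in schedule:
        if duration < 0:
            raise ValidationError("schedule durations must be >= 0")
        out.append((start, start + duration, params))
        start += duration
    # extend the last interval to cover all requested times
    s, e, params = out[-1]
    out[-1] = (s, max(e, t_end), params)
    return out


def simulate(
    initial: DyadStateVector,
    schedule: Sequence[tuple[float, RateParameters]] | RateParameters,
    times: Sequence[float],
    event_order: Sequence[str] = DEFAULT_EVENT_ORDER,
) -> Trajectory:
    """Simulate dyad dynamics over a piecewise-constant parameter schedule.

    ``schedule`` is a single parameter set or a list of ``(duration_hours,
    RateParameters)`` intervals contiguous from t=0; the last interval is
    extended to cover ``max(times)``. Divisions occur every
    ``division_time`` hours of the active interval; the de novo rate is
    evaluated at each division's start, on a clock that restarts at the
    interval boundary (a medium switch resets the p1 relaxation). Global
    levels at the requested times are linearly interpolated between
    division-boundary levels, the simplest smooth surrogate for an
    unsynchronized cell population.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("times must be non-empty")
    if np.any(times < 0):
        raise ValidationError("times must be >= 0")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValidationError("times must be sorted strictly increasing")
    initial.validate()

    t_end = float(times[-1])
    intervals = _normalize_schedule(schedule, t_end)

    states = [initial]
    boundary_times = [0.0]
    t = 0.0
    state = initial
    for start, end, params in intervals:
        t = max(t, start)
        while t < end - 1e-12:
            p1 = params.p1_at(t - start)
            state = division_step(state, params, p1_value=p1,
                                  event_order=event_order)
            t += params.division_time
            states.append(state)
            boundary_times.append(t)
        if t >= t_end:
            break
    # make sure interpolation covers t_end
    last_params = intervals[-1][2]
    while boundary_times[-1] < t_end:
        start = intervals[-1][0]
        p1 = last_params.p1_at(boundary_times[-1] - start)
        state = division_step(state, last_params, p1_value=p1,
                              event_order=event_order)
        boundary_times.append(boundary_times[-1] + last_params.division_time)
        states.append(state)

    bt = np.array(boundary_times)
    levels = [s.strand_fractions() for s in states]
    f = np.array([lv[0] for lv in levels])
    h = np.array([lv[1] for lv in levels])
    return Trajectory(
        times=times,
        five_mC=np.interp(times, bt, f),
        five_hmC=np.interp(times, bt, h),
        boundary_times=bt,
        states=tuple(states),
    )
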