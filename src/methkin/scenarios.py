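"""Perturbation scenarios: knockouts, vitamin C, medium switch, in vivo.

Genetic knockouts are encoded as parameter constraints on an otherwise
unchanged wild-type parameter set: loss of Dnmt1 or Uhrf1 abolishes
maintenance (p2 = 0), loss of Dnmt3a/b abolishes de novo methylation
(p1 = 0), loss of all TETs abolishes oxidation (p3 = 0), and loss of
Aicda or Tdg changes nothing — the deaminase/glycosylase pathway is
dispensable for global demethylation, encoded here as an identity
transformation. Vitamin C acts purely as a multiplier on the TET
oxidation rate p3 (default 4-fold), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dyad_model
from .types import (
    DyadStateVector,
    RateParameters,
    Trajectory,
    ValidationError,
)

__all__ = ["ScenarioSpec", "apply_scenario", "predict_scenario",
           "compare_rates", "RateComparison", "KNOCKOUTS"]

KNOCKOUTS = ("none", "dnmt1_or_uhrf1", "dnmt3ab", "tet_any", "aicda_or_tdg")


@dataclass(frozen=True)
class ScenarioSpec:
    """A perturbation applied to both phases of a serum-to-2i time course."""

    knockout: str = "none"
    vitc_p3_multiplier: float = 1.0
    switch_time: float = 0.0          # hours; serum before, 2i after
    division_times: tuple[float, ...] | None = None  # in vivo overrides

    def __post_init__(self) -> None:
        if self.knockout not in KNOCKOUTS:
            raise ValidationError(
                f"unknown knockout {self.knockout!r}; expected one of {KNOCKOUTS}"
            )
        if self.vitc_p3_multiplier < 1.0:
            raise ValidationError("vitc_p3_multiplier must be >= 1")
        if self.switch_time < 0:
            raise ValidationError("switch_time must be >= 0")
        if self.division_times is not None and any(
            d <= 0 for d in self.division_times
        ):
            raise ValidationError("division times must be > 0")


def apply_scenario(base: RateParameters, spec: ScenarioSpec) -> RateParameters:
    """Transform a wild-type parameter set under a scenario.

    No parameter is re-fitted: a knockout prediction reuses the wild-type
    estimates with the corresponding rate zeroed.
    """
    p = base
    if spec.knockout == "dnmt1_or_uhrf1":
        p = p.updated(p2=0.0)
    elif spec.knockout == "dnmt3ab":
        if p.p1_schedule is not None:
            p = p.updated(p1_initial=0.0, p1_final=0.0)
        else:
            p = p.updated(p1=0.0)
    elif spec.knockout == "tet_any":
        p = p.updated(p3=0.0)
    elif spec.knockout == "aicda_or_tdg":
        pass  # dispensable for global demethylation: identity
    if spec.vitc_p3_multiplier != 1.0:
        p = p.updated(p3=min(1.0, p.p3 * spec.vitc_p3_multiplier))
    return p


def predict_scenario(
    initial: DyadStateVector,
    serum: RateParameters,
    two_i: RateParameters,
    spec: ScenarioSpec,
    times,
) -> Trajectory:
    """Predicted trajectory under a scenario across the medium switch.

    The scenario transformation is applied to both the serum and the 2i
    phase (knockout induction precedes the time course). A switch_time of
    0 yields a pure 2i-phase course from the supplied initial state.
    """
    serum_s = apply_scenario(serum, spec)
    two_i_s = apply_scenario(two_i, spec)
    times = np.asarray(times, dtype=float)
    t_end = float(times[-1]) if times.size else 0.0
    if spec.switch_time > 0:
        schedule = [
            (spec.switch_time, serum_s),
            (max(t_end - spec.switch_time, 0.0), two_i_s),
        ]
    else:
        schedule = [(t_end, two_i_s)]
    return dyad_model.simulate(initial, schedule, times)


@dataclass(frozen=True, eq=False)
class RateComparison:
    """Pointwise ordering of two trajectories plus level-crossing times."""

    per_time: pd.DataFrame       # time_h, a_5mC, b_5mC, diff, sign
    crossings: pd.DataFrame      # fraction, time_a_h, time_b_h


def _crossing_time(times: np.ndarray, levels: np.ndarray,
                   target: float) -> float:
    """First time the series reaches ``target`` (linear interpolation);
    NaN if it never does."""
    below = levels <= target
    if not below.any():
        return float("nan")
    i = int(np.argmax(below))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = levels[i - 1], levels[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (y0 - target) * (t1 - t0) / (y0 - y1))


def compare_rates(a: Trajectory, b: Trajectory,
                  fractions=(0.75, 0.5, 0.25)) -> RateComparison:
    """Compare demethylation speed of two trajectories on a shared grid.

    Reports the per-time sign of five_mC(a) - five_mC(b) and, for each
    requested fraction of the initial level, when each trajectory first
    crosses it (its own initial level; NaN when never reached).
    """
    if not np.array_equal(a.times, b.times):
        raise ValidationError("trajectories must share the same time grid")
    diff = a.five_mC - b.five_mC
    per_time = pd.DataFrame({
        "time_h": a.times,
        "a_5mC": a.five_mC,
        "b_5mC": b.five_mC,
        "diff": diff,
        "sign": np.sign(diff).astype(int),
    })
    rows = []
    for frac in fractions:
        rows.append({
            "fraction": frac,
            "time_a_h": _crossing_time(a.times, a.five_mC,
                                       frac * a.five_mC[0]),
            "time_b_h": _crossing_time(b.times, b.five_mC,
                                       frac * b.five_mC[0]),
        })
    return RateComparison(per_time=per_time, crossings=pd.DataFrame(rows))
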