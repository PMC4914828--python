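"""Domain types for CpG-dyad methylation kinetics.

A CpG dyad is the palindromic CpG/CpG pair on complementary strands. Each
strand's cytosine is independently unmodified (u), methylated (m, 5mC) or
hydroxymethylated (h, 5hmC), giving six unordered dyad states. Population
fractions of these states, together with three per-division rate parameters
(de novo methylation p1, maintenance methylation p2, TET oxidation p3),
fully specify the expected global 5mC/5hmC dynamics across cell divisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "DyadStateVector",
    "P1Schedule",
    "RateParameters",
    "GlobalLevels",
    "Trajectory",
    "ObservationSeries",
]

#: tolerance on the sum-to-one invariant for user-supplied states
SUM_TOL_USER = 1e-9
#: drift tolerance for internally produced states
SUM_TOL_INTERNAL = 1e-12


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class DyadStateVector:
    """Population fractions of the six unordered CpG dyad states.

    Fields are named by the pair of strand marks: ``uu`` unmethylated,
    ``um`` hemi-methylated, ``mm`` fully methylated, ``uh``/``mh``/``hh``
    the 5hmC-bearing combinations. Fractions are per-dyad and sum to 1.
    """

    uu: float = 0.0
    um: float = 0.0
    mm: float = 0.0
    uh: float = 0.0
    mh: float = 0.0
    hh: float = 0.0

    _FIELDS = ("uu", "um", "mm", "uh", "mh", "hh")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, tol: float = SUM_TOL_USER) -> None:
        for name in self._FIELDS:
            v = getattr(self, name)
            if not (-tol <= v <= 1.0 + tol):
                raise ValidationError(
                    f"dyad fraction {name}={v!r} outside [0, 1]"
                )
        s = self.total()
        if abs(s - 1.0) > tol:
            raise ValidationError(
                f"dyad fractions sum to {s!r}, expected 1 within {tol}"
            )

    def total(self) -> float:
        return self.uu + self.um + self.mm + self.uh + self.mh + self.hh

    def as_array(self) -> np.ndarray:
        """Fractions in canonical order (uu, um, mm, uh, mh, hh)."""
        return np.array(
            [self.uu, self.um, self.mm, self.uh, self.mh, self.hh]
        )

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "DyadStateVector":
        return cls(*[float(x) for x in a])

    def strand_fractions(self) -> tuple[float, float]:
        """Per-strand (5mC fraction, 5hmC fraction) — each strand of a dyad
        counts half."""
        f = self.mm + 0.5 * (self.um + self.mh)
        h = self.hh + 0.5 * (self.uh + self.mh)
        return f, h


@dataclass(frozen=True)
class P1Schedule:
    """Gradual change of the de novo rate: exponential relaxation from
    ``p1_initial`` to ``p1_final`` with the given half-life (hours)."""

    p1_initial: float
    p1_final: float
    half_life: float

    def __post_init__(self) -> None:
        for name in ("p1_initial", "p1_final"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v!r} outside [0, 1]")
        if not self.half_life > 0:
            raise ValidationError(
                f"half_life={self.half_life!r} must be > 0"
            )

    def at(self, t: float) -> float:
        if t < 0:
            raise ValidationError(f"time t={t!r} must be >= 0")
        return self.p1_final + (self.p1_initial - self.p1_final) * math.pow(
            2.0, -t / self.half_life
        )


@dataclass(frozen=True)
class RateParameters:
    """Per-average-cell-division rates of the three methylation pathways.

    p1 — proportion of unmethylated dyads gaining one methyl group per
    division (de novo, DNMT3A/B); p2 — proportion of hemi-methylated dyads
    restored to fully methylated per division (maintenance, DNMT1/UHRF1);
    p3 — proportion of methylated strands oxidized to 5hmC per division
    (TET). ``division_time`` is hours per average division. When a
    ``p1_schedule`` is set, p1 relaxes over time and the ``p1`` field holds
    the schedule's initial value.
    """

    p1: float
    p2: float
    p3: float
    division_time: float = 16.0
    p1_schedule: P1Schedule | None = None

    def __post_init__(self) -> None:
        if self.p1_schedule is not None:
            object.__setattr__(self, "p1", self.p1_schedule.p1_initial)
        for name in ("p1", "p2", "p3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v!r} outside [0, 1]")
        if not self.division_time > 0:
            raise ValidationError(
                f"division_time={self.division_time!r} must be > 0"
            )

    @classmethod
    def with_schedule(
        cls,
        p1_initial: float,
        p1_final: float,
        p1_half_life: float,
        p2: float,
        p3: float,
        division_time: float = 16.0,
    ) -> "RateParameters":
        return cls(
            p1=p1_initial,
            p2=p2,
            p3=p3,
            division_time=division_time,
            p1_schedule=P1Schedule(p1_initial, p1_final, p1_half_life),
        )

    def p1_at(self, t: float) -> float:
        """De novo rate at time ``t`` hours after this parameter set took
        effect; constant ``p1`` when no schedule is set."""
        if t < 0:
            raise ValidationError(f"time t={t!r} must be >= 0")
        if self.p1_schedule is None:
            return self.p1
        return self.p1_schedule.at(t)

    @property
    def is_constant(self) -> bool:
        return self.p1_schedule is None

    def updated(self, **changes: float) -> "RateParameters":
        """Return a copy with named parameters replaced.

        Accepted keys: p1 (constant), p1_initial, p1_final, p1_half_life,
        p2, p3, division_time. Schedule keys create or modify the schedule.
        """
        sched_keys = {"p1_initial", "p1_final", "p1_half_life"}
        plain = {
            k: v for k, v in changes.items()
            if k in ("p2", "p3", "division_time")
        }
        unknown = set(changes) - sched_keys - set(plain) - {"p1"}
        if unknown:
            raise ValidationError(f"unknown parameter name(s): {sorted(unknown)}")
        out = replace(self, **plain) if plain else self
        if "p1" in changes:
            if sched_keys & set(changes):
                raise ValidationError(
                    "give either a constant p1 or schedule fields, not both"
                )
            return replace(out, p1=changes["p1"], p1_schedule=None)
        if sched_keys & set(changes):
            base = out.p1_schedule or P1Schedule(out.p1, out.p1, 1.0)
            sched = P1Schedule(
                changes.get("p1_initial", base.p1_initial),
                changes.get("p1_final", base.p1_final),
                changes.get("p1_half_life", base.half_life),
            )
            return replace(out, p1=sched.p1_initial, p1_schedule=sched)
        return out


@dataclass(frozen=True)
class GlobalLevels:
    """Global per-CpG-strand modification fractions, the model-side analog
    of what LC-MS measures (up to instrument scaling)."""

    five_mC: float
    five_hmC: float = 0.0

    def __post_init__(self) -> None:
        if self.five_mC < -SUM_TOL_USER or self.five_hmC < -SUM_TOL_USER:
            raise ValidationError("global levels must be >= 0")
        if self.five_mC + self.five_hmC > 1.0 + SUM_TOL_USER:
            raise ValidationError("five_mC + five_hmC must be <= 1")


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Model output: dyad states at division boundaries plus global levels
    interpolated onto the requested observation times."""

    times: np.ndarray                 # requested times, hours
    five_mC: np.ndarray               # levels at `times`
    five_hmC: np.ndarray
    boundary_times: np.ndarray        # division boundaries, hours
    states: tuple[DyadStateVector, ...]  # one state per boundary (incl. t=0)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if len(self.five_mC) != len(t) or len(self.five_hmC) != len(t):
            raise ValidationError("levels length must equal times length")

    def levels_at(self, i: int) -> GlobalLevels:
        return GlobalLevels(float(self.five_mC[i]), float(self.five_hmC[i]))


@dataclass
class ObservationSeries:
    """A measured or synthetic global 5mC (and optionally 5hmC) time course.

    ``scale_mode`` records how levels relate to absolute fractions:
    ``none`` (absolute), ``to_initial`` (divided by the t=0 level) or
    ``to_reference`` (divided by a supplied reference level).
    """

    times: np.ndarray
    five_mC: np.ndarray
    five_hmC: np.ndarray | None = None
    condition: str = ""
    scale_mode: str = "none"
    noise_sd: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.five_mC = np.asarray(self.five_mC, dtype=float)
        if self.five_hmC is not None:
            self.five_hmC = np.asarray(self.five_hmC, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if len(self.five_mC) != len(self.times):
            raise ValidationError("five_mC length must equal times length")
        if self.five_hmC is not None and len(self.five_hmC) != len(self.times):
            raise ValidationError("five_hmC length must equal times length")
        if np.any(self.five_mC < 0) or (
            self.five_hmC is not None and np.any(self.five_hmC < 0)
        ):
            raise ValidationError("observed levels must be >= 0")
        if self.scale_mode not in ("none", "to_initial", "to_reference"):
            raise ValidationError(f"unknown scale_mode {self.scale_mode!r}")

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ObservationSeries):
            return NotImplemented
        same_hmc = (
            (self.five_hmC is None and other.five_hmC is None)
            or (
                self.five_hmC is not None
                and other.five_hmC is not None
                and np.array_equal(self.five_hmC, other.five_hmC)
            )
        )
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.five_mC, other.five_mC)
            and same_hmc
            and self.condition == other.condition
            and self.scale_mode == other.scale_mode
        )
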