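"""Synthetic inputs: LC-MS-like time courses, hairpin bisulfite dyad
counts, and a stochastic per-dyad simulator used as a brute-force oracle.

All generators are pure functions of their inputs and a seed.

Hairpin bisulfite sequencing reads both strands of a molecule, yielding
counts of fully methylated, hemi-methylated and unmethylated dyads.
Bisulfite chemistry cannot distinguish 5hmC from 5mC, so h-bearing strands
read as methylated; the error model is two-sided per strand — a truly
methylated strand reads unmethylated with probability 1 - conversion_rate,
a truly unmethylated strand reads methylated with probability
nonconversion_rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import dyad_model
from .types import (
    DyadStateVector,
    ObservationSeries,
    RateParameters,
    ValidationError,
)

__all__ = [
    "NoiseModel",
    "HairpinCountTable",
    "generate_timecourse",
    "generate_hairpin_counts",
    "estimate_state_from_counts",
    "stochastic_dyad_simulator",
]

logger = logging.getLogger(__name__)

#: default additive Gaussian measurement noise on global levels
#: (1 percentage point, emulating LC-MS replicate scatter)
DEFAULT_NOISE_SD = 0.01


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian measurement noise, clipped at zero."""

    sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("noise sd must be >= 0")


@dataclass(frozen=True)
class HairpinCountTable:
    """Dyad-category read counts from (simulated) hairpin bisulfite
    sequencing, with the per-strand error rates they were read under."""

    n_full: int       # mCpG/GpCm
    n_hemi: int       # mCpG/GpC, both orientations pooled
    n_unmeth: int     # CpG/GpC
    conversion_rate: float = 1.0
    nonconversion_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_full", "n_hemi", "n_unmeth"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name}={v!r} must be a nonnegative integer")
        if self.total() <= 0:
            raise ValidationError("total read count must be > 0")
        if not 0.9 <= self.conversion_rate <= 1.0:
            raise ValidationError("conversion_rate must be in [0.9, 1]")
        if not 0.0 <= self.nonconversion_rate <= 0.05:
            raise ValidationError("nonconversion_rate must be in [0, 0.05]")

    def total(self) -> int:
        return self.n_full + self.n_hemi + self.n_unmeth

    def proportions(self) -> np.ndarray:
        return np.array([self.n_full, self.n_hemi, self.n_unmeth]) / self.total()


def generate_timecourse(
    serum: RateParameters,
    two_i: RateParameters,
    switch_time: float,
    times,
    noise: NoiseModel,
    initial: DyadStateVector | None = None,
    condition: str = "",
) -> ObservationSeries:
    """Noisy global 5mC/5hmC course over a serum-to-2i switch.

    The true trajectory starts from ``initial`` (default: serum steady
    state) and follows serum parameters until ``switch_time``, 2i after.
    Gaussian noise of the given sd is added independently to both
    channels and clipped at zero.
    """
    times = np.asarray(times, dtype=float)
    if initial is None:
        initial = dyad_model.steady_state_dyads(serum)
    t_end = float(times[-1])
    if switch_time > 0:
        schedule = [(switch_time, serum),
                    (max(t_end - switch_time, 0.0), two_i)]
    else:
        schedule = [(t_end, two_i)]
    traj = dyad_model.simulate(initial, schedule, times)
    rng = np.random.default_rng(noise.seed)
    m = traj.five_mC + rng.normal(0.0, noise.sd, size=times.size)
    h = traj.five_hmC + rng.normal(0.0, noise.sd, size=times.size)
    return ObservationSeries(
        times=times,
        five_mC=np.clip(m, 0.0, None),
        five_hmC=np.clip(h, 0.0, None),
        condition=condition,
        noise_sd=noise.sd,
        seed=noise.seed,
    )


def _category_probs(
    state: DyadStateVector, conversion_rate: float, nonconversion_rate: float
) -> np.ndarray:
    """Observed (full, hemi, unmeth) probabilities under the per-strand
    error model; 5hmC strands read as methylated."""
    a = conversion_rate       # P(truly modified strand reads methylated)
    b = nonconversion_rate    # P(truly unmodified strand reads methylated)
    w_both = state.mm + state.mh + state.hh
    w_hemi = state.um + state.uh
    w_none = state.uu
    p_full = w_both * a * a + w_hemi * a * b + w_none * b * b
    p_hemi = (
        w_both * 2 * a * (1 - a)
        + w_hemi * (a * (1 - b) + (1 - a) * b)
        + w_none * 2 * b * (1 - b)
    )
    p_un = w_both * (1 - a) ** 2 + w_hemi * (1 - a) * (1 - b) + w_none * (1 - b) ** 2
    return np.array([p_full, p_hemi, p_un])


def generate_hairpin_counts(
    state: DyadStateVector,
    n_reads: int,
    conversion_rate: float = 1.0,
    nonconversion_rate: float = 0.0,
    seed: int = 0,
) -> HairpinCountTable:
    """Multinomial hairpin read counts from a true dyad-state distribution."""
    if n_reads <= 0:
        raise ValidationError("n_reads must be > 0")
    state.validate()
    probs = _category_probs(state, conversion_rate, nonconversion_rate)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs)
    return HairpinCountTable(
        n_full=int(counts[0]),
        n_hemi=int(counts[1]),
        n_unmeth=int(counts[2]),
        conversion_rate=conversion_rate,
        nonconversion_rate=nonconversion_rate,
    )


def estimate_state_from_counts(
    counts: HairpinCountTable,
    five_hmC_level: float | None = None,
) -> DyadStateVector:
    """Dyad-state fractions from hairpin counts, correcting read errors.

    Inverts the per-strand confusion model by a plug-in moment (linear)
    correction with the table's stated rates, clips small negatives
    (logged) and renormalizes. Bisulfite reads cannot separate 5hmC from
    5mC; when a global strand-level 5hmC fraction is supplied, the
    methylated-strand mass is apportioned assuming each modified strand is
    independently 5hmC with the implied probability, otherwise all
    modified mass is returned as 5mC.
    """
    q = counts.proportions()
    a, b = counts.conversion_rate, counts.nonconversion_rate
    # columns: true (both-mod, hemi-mod, unmod) -> observed categories
    m = np.array([
        [a * a, a * b, b * b],
        [2 * a * (1 - a), a * (1 - b) + (1 - a) * b, 2 * b * (1 - b)],
        [(1 - a) ** 2, (1 - a) * (1 - b), (1 - b) ** 2],
    ])
    w = np.linalg.solve(m, q)
    if np.any(w < -1e-9):
        logger.warning(
            "hairpin error correction produced negative fractions %s; clipping",
            w,
        )
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    w_both, w_hemi, w_un = (float(x) for x in w)

    if five_hmC_level is None or five_hmC_level == 0.0:
        return DyadStateVector(uu=w_un, um=w_hemi, mm=w_both)
    mod_strands = w_both + 0.5 * w_hemi
    if five_hmC_level > mod_strands:
        raise ValidationError(
            "supplied 5hmC level exceeds the modified-strand fraction"
        )
    rho = five_hmC_level / mod_strands
    return DyadStateVector(
        uu=w_un,
        um=w_hemi * (1 - rho),
        uh=w_hemi * rho,
        mm=w_both * (1 - rho) ** 2,
        mh=w_both * 2 * rho * (1 - rho),
        hh=w_both * rho * rho,
    )


# integer strand codes for the stochastic simulator
_U, _M, _H = 0, 1, 2


def _initial_strands(
    n_dyads: int, initial: DyadStateVector, rng: np.random.Generator
) -> np.ndarray:
    probs = initial.as_array()
    probs = probs / probs.sum()
    cats = rng.choice(6, size=n_dyads, p=probs)
    pairs = np.array(
        [[_U, _U], [_U, _M], [_M, _M], [_U, _H], [_M, _H], [_H, _H]]
    )
    return pairs[cats].copy()


def _tally(strands: np.ndarray) -> dict[str, int]:
    lo = np.minimum(strands[:, 0], strands[:, 1])
    hi = np.maximum(strands[:, 0], strands[:, 1])
    key = lo * 3 + hi  # uu=0, um=1, uh=2, mm=4, mh=5, hh=8
    names = {0: "uu", 1: "um", 2: "uh", 4: "mm", 5: "mh", 8: "hh"}
    out = {v: 0 for v in names.values()}
    vals, cnts = np.unique(key, return_counts=True)
    for v, c in zip(vals, cnts):
        out[names[int(v)]] = int(c)
    return out


def stochastic_dyad_simulator(
    n_dyads: int,
    initial: DyadStateVector,
    schedule,
    divisions: int,
    seed: int = 0,
) -> list[dict[str, int]]:
    """Monte-Carlo simulation of individual dyads through divisions.

    Each dyad's two strands undergo oxidation, replication (one daughter
    followed, the surviving parent strand chosen uniformly), maintenance
    and de novo methylation as independent Bernoulli events — the
    brute-force counterpart of :func:`methkin.dyad_model.division_step`.
    ``schedule`` follows :func:`methkin.dyad_model.simulate` (a single
    parameter set or contiguous ``(duration_h, RateParameters)``
    intervals); parameters and the scheduled p1 are evaluated at each
    division's start time exactly as in the deterministic model. Returns
    one six-state tally per division boundary, including the initial one.
    """
    if n_dyads < 1:
        raise ValidationError("n_dyads must be >= 1")
    if divisions < 0:
        raise ValidationError("divisions must be >= 0")
    initial.validate()
    if isinstance(schedule, RateParameters):
        intervals = [(0.0, np.inf, schedule)]
    else:
        intervals = []
        start = 0.0
        for duration, params in schedule:
            intervals.append((start, start + duration, params))
            start += duration
        s, _, params = intervals[-1]
        intervals[-1] = (s, np.inf, params)

    rng = np.random.default_rng(seed)
    strands = _initial_strands(n_dyads, initial, rng)
    tallies = [_tally(strands)]
    t = 0.0
    for _ in range(divisions):
        start, _, params = next(
            iv for iv in intervals if iv[0] <= t < iv[1] or iv[1] == np.inf
        )
        p1 = params.p1_at(t - start)
        # oxidation: each m strand -> h with probability p3
        ox = (strands == _M) & (rng.random(strands.shape) < params.p3)
        strands[ox] = _H
        # replication: keep one parent strand, pair with a nascent u strand
        keep = rng.integers(0, 2, size=n_dyads)
        parent = strands[np.arange(n_dyads), keep]
        strands = np.stack([parent, np.full(n_dyads, _U)], axis=1)
        # maintenance: (m,u) -> (m,m)
        hemi_m = strands[:, 0] == _M
        maintained = hemi_m & (rng.random(n_dyads) < params.p2)
        strands[maintained, 1] = _M
        # de novo: (u,u) -> (m,u)
        unmeth = strands[:, 0] == _U
        de_novo = unmeth & (rng.random(n_dyads) < p1)
        strands[de_novo, 0] = _M
        t += params.division_time
        tallies.append(_tally(strands))
    return tallies
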