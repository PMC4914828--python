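"""MMSE fitting of division-rate parameters to global 5mC time courses.

The estimator is a deterministic exhaustive grid search over the free
parameters (any subset of p1_initial, p1_final, p1_half_life, p2, p3),
followed by an optional bounded derivative-free polish from the best grid
point. The full error surface is retained so that parameter
identifiability can be inspected: profile valleys and multiple local
minima on the surface are how degenerate solutions (e.g. maintenance loss
versus TET oxidation trading off against each other on a fast-decay
course) manifest.

By default the objective uses 5mC only; the predicted 5hmC course is then
a genuine out-of-sample check of the fitted mechanism. A joint 5mC+5hmC
objective is available (``include_hmc=True``) and is required to identify
p3 directly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from . import dyad_model
from .types import (
    DyadStateVector,
    ObservationSeries,
    RateParameters,
    ValidationError,
)

__all__ = [
    "FitSpec",
    "FitResult",
    "Surface",
    "LocalMinimum",
    "mmse_objective",
    "grid_search",
    "r_squared",
    "find_local_minima",
    "normalize_series",
]

#: canonical ordering of fit parameters, used for lexicographic tie-breaks
PARAM_ORDER = ("p1_initial", "p1_final", "p1_half_life", "p2", "p3")

_DEFAULT_BOUNDS = {
    "p1_initial": (0.0, 1.0),
    "p1_final": (0.0, 1.0),
    "p1_half_life": (1.0, 336.0),
    "p2": (0.0, 1.0),
    "p3": (0.0, 1.0),
}


@dataclass(frozen=True)
class FitSpec:
    """Which parameters to fit, over what grid.

    ``free`` maps parameter names to grid sizes (>= 2); ``bounds`` may
    override the default [0, 1] box (hours for p1_half_life). ``base``
    supplies the fixed values of everything not in ``free``.
    """

    base: RateParameters
    free: dict[str, int] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    refine: bool = True
    include_hmc: bool = False

    def __post_init__(self) -> None:
        for name, n in self.free.items():
            if name not in PARAM_ORDER:
                raise ValidationError(f"unknown free parameter {name!r}")
            if n < 2:
                raise ValidationError(
                    f"grid resolution for {name!r} must be >= 2, got {n}"
                )
        for name, (lo, hi) in self.bounds.items():
            if name not in PARAM_ORDER:
                raise ValidationError(f"unknown bounded parameter {name!r}")
            if not lo < hi:
                raise ValidationError(f"empty bounds for {name!r}: ({lo}, {hi})")
            if name != "p1_half_life" and not (0.0 <= lo and hi <= 1.0):
                raise ValidationError(
                    f"bounds for {name!r} must lie within [0, 1]"
                )

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_ORDER if n in self.free)

    def axis(self, name: str) -> np.ndarray:
        lo, hi = self.bounds.get(name, _DEFAULT_BOUNDS[name])
        return np.linspace(lo, hi, self.free[name])

    def params_at(self, values: dict[str, float]) -> RateParameters:
        if not values:
            return self.base
        return self.base.updated(**values)


@dataclass(frozen=True, eq=False)
class Surface:
    """Gridded MMSE values over the free-parameter box."""

    axis_names: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    values: np.ndarray  # shape = tuple(len(a) for a in axes)

    def to_long_frame(self):
        """Long-format table (one row per grid point) for TSV export."""
        import pandas as pd

        grids = np.meshgrid(*self.axes, indexing="ij")
        data = {n: g.ravel() for n, g in zip(self.axis_names, grids)}
        data["mmse"] = self.values.ravel()
        return pd.DataFrame(data)


@dataclass(frozen=True)
class LocalMinimum:
    params: dict[str, float]
    mmse: float
    index: tuple[int, ...]


@dataclass(frozen=True, eq=False)
class FitResult:
    best: RateParameters
    best_values: dict[str, float]
    mmse: float
    r_squared: float
    surface: Surface
    minima: tuple[LocalMinimum, ...]
    refined: bool = False
    degenerate: bool = False  # all-equal objective over the grid


def _scaled(values: np.ndarray, mode: str, reference: float | None) -> np.ndarray:
    if mode == "none":
        return values
    if mode == "to_initial":
        ref = values[0]
    elif mode == "to_reference":
        if reference is None:
            raise ValidationError("to_reference scaling needs a reference level")
        ref = reference
    else:
        raise ValidationError(f"unknown scale_mode {mode!r}")
    if ref == 0:
        raise ValidationError("cannot scale by a zero level")
    return values / ref


def predict_levels(
    params: RateParameters,
    times: np.ndarray,
    initial: DyadStateVector,
) -> tuple[np.ndarray, np.ndarray]:
    """Model 5mC and 5hmC at the observation times, single-phase."""
    traj = dyad_model.simulate(initial, params, times)
    return traj.five_mC, traj.five_hmC


def mmse_objective(
    params: RateParameters,
    obs: ObservationSeries,
    initial: DyadStateVector,
    include_hmc: bool = False,
    reference: float | None = None,
) -> float:
    """Mean squared error between model prediction and observation.

    The observation's ``scale_mode`` is applied identically to the
    prediction (each series scaled by its own t=0 / reference level), so
    fits on scaled data recover the same parameters as fits on absolute
    levels. 5hmC residuals are pooled with 5mC only when
    ``include_hmc=True`` and the series carries a 5hmC channel.
    """
    if len(obs) < 1:
        raise ValidationError("need at least one observation")
    pred_m, pred_h = predict_levels(params, obs.times, initial)
    res = _scaled(pred_m, obs.scale_mode, reference) - _scaled(
        obs.five_mC, obs.scale_mode, reference
    )
    sq = [res * res]
    if include_hmc and obs.five_hmC is not None:
        res_h = _scaled(pred_h, obs.scale_mode, reference) - _scaled(
            obs.five_hmC, obs.scale_mode, reference
        )
        sq.append(res_h * res_h)
    all_sq = np.concatenate(sq)
    return float(all_sq.mean())


def r_squared(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (SS_tot about the
    observed mean). Undefined, hence an error, for a constant observation."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or observed.size < 2:
        raise ValidationError("need two equal-length series of length >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("R^2 undefined for a constant observed series")
    ss_res = float(np.sum((predicted - observed) ** 2))
    return 1.0 - ss_res / ss_tot


def _r2_or_nan(predicted: np.ndarray, observed: np.ndarray) -> float:
    """R^2 for fit reports; NaN instead of an error when the observed
    series is constant (e.g. a steady-state course)."""
    try:
        return r_squared(predicted, observed)
    except ValidationError:
        return float("nan")


def find_local_minima(surface: Surface) -> tuple[LocalMinimum, ...]:
    """All grid points not exceeded by any axis-neighbor, adjacent
    candidates merged into one minimum (representative: lowest value,
    lexicographically smallest index on ties), sorted by MMSE ascending."""
    v = surface.values
    cand = np.ones(v.shape, dtype=bool)
    for ax in range(v.ndim):
        lo = [slice(None)] * v.ndim
        hi = [slice(None)] * v.ndim
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        le_next = v[tuple(lo)] <= v[tuple(hi)]
        cand[tuple(lo)] &= le_next
        cand[tuple(hi)] &= ~le_next | (v[tuple(lo)] == v[tuple(hi)])
    labels, n = ndimage.label(cand)
    out = []
    for lab in range(1, n + 1):
        idxs = np.argwhere(labels == lab)
        vals = v[tuple(idxs.T)]
        best = np.lexsort((*(idxs.T[::-1]), vals))[0]
        idx = tuple(int(i) for i in idxs[best])
        params = {
            name: float(ax[i])
            for name, ax, i in zip(surface.axis_names, surface.axes, idx)
        }
        out.append(LocalMinimum(params=params, mmse=float(v[idx]), index=idx))
    out.sort(key=lambda m: (m.mmse, m.index))
    return tuple(out)


def grid_search(
    obs: ObservationSeries,
    initial: DyadStateVector,
    spec: FitSpec,
    reference: float | None = None,
) -> FitResult:
    """Exhaustive MMSE evaluation over the Cartesian parameter grid.

    Deterministic: equal-MMSE grid points are broken toward the
    lexicographically smallest parameter tuple (in the canonical
    p1_initial, p1_final, p1_half_life, p2, p3 order). When
    ``spec.refine`` is set, a bounded Nelder–Mead polish is started from
    the best grid point and kept only if it improves the objective.
    """
    if len(obs) < 3:
        raise ValidationError("need at least 3 observations to fit")
    names = spec.free_names
    axes = tuple(spec.axis(n) for n in names)

    def objective(vals: dict[str, float]) -> float:
        return mmse_objective(
            spec.params_at(vals), obs, initial,
            include_hmc=spec.include_hmc, reference=reference,
        )

    if not names:
        m = objective({})
        surf = Surface(axis_names=(), axes=(), values=np.array(m))
        pred, _ = predict_levels(spec.base, obs.times, initial)
        return FitResult(
            best=spec.base, best_values={}, mmse=m,
            r_squared=_r2_or_nan(
                _scaled(pred, obs.scale_mode, reference),
                _scaled(obs.five_mC, obs.scale_mode, reference),
            ),
            surface=surf, minima=(LocalMinimum({}, m, ()),),
        )

    shape = tuple(len(a) for a in axes)
    values = np.empty(shape)
    best_idx: tuple[int, ...] | None = None
    best_val = math.inf
    for idx in itertools.product(*(range(n) for n in shape)):
        vals = {n: float(a[i]) for n, a, i in zip(names, axes, idx)}
        m = objective(vals)
        values[idx] = m
        if m < best_val:  # strict: first (lex-smallest) of equals wins
            best_val, best_idx = m, idx

    surface = Surface(axis_names=names, axes=axes, values=values)
    degenerate = bool(np.all(values == values.flat[0]))
    minima = find_local_minima(surface)

    best_vals = {n: float(a[i]) for n, a, i in zip(names, axes, best_idx)}
    refined = False
    if spec.refine:
        bounds = [spec.bounds.get(n, _DEFAULT_BOUNDS[n]) for n in names]

        def vec_obj(x: np.ndarray) -> float:
            clipped = {
                n: float(min(max(xi, lo), hi))
                for n, xi, (lo, hi) in zip(names, x, bounds)
            }
            return objective(clipped)

        x0 = np.array([best_vals[n] for n in names])
        res = optimize.minimize(
            vec_obj, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
        )
        if res.fun < best_val:
            best_val = float(res.fun)
            best_vals = {
                n: float(min(max(xi, lo), hi))
                for n, xi, (lo, hi) in zip(names, res.x, bounds)
            }
            refined = True

    best_params = spec.params_at(best_vals)
    pred, _ = predict_levels(best_params, obs.times, initial)
    r2 = _r2_or_nan(
        _scaled(pred, obs.scale_mode, reference),
        _scaled(obs.five_mC, obs.scale_mode, reference),
    )
    return FitResult(
        best=best_params, best_values=best_vals, mmse=best_val,
        r_squared=r2, surface=surface, minima=minima, refined=refined,
        degenerate=degenerate,
    )


def normalize_series(
    obs: ObservationSeries, mode: str, reference: float | None = None
) -> ObservationSeries:
    """Rescale an observation series: ``to_initial`` divides by the t=0
    level (per channel), ``to_reference`` by a supplied level, ``none``
    returns the series unchanged."""
    if mode == "none":
        return obs
    if mode == "to_initial":
        ref_m = float(obs.five_mC[0])
        ref_h = float(obs.five_hmC[0]) if obs.five_hmC is not None else None
    elif mode == "to_reference":
        if reference is None or reference == 0:
            raise ValidationError("to_reference needs a nonzero reference level")
        ref_m = ref_h = float(reference)
    else:
        raise ValidationError(f"unknown scale_mode {mode!r}")
    if ref_m == 0 or (obs.five_hmC is not None and ref_h == 0):
        raise ValidationError("cannot normalize by a zero initial level")
    return ObservationSeries(
        times=obs.times.copy(),
        five_mC=obs.five_mC / ref_m,
        five_hmC=None if obs.five_hmC is None else obs.five_hmC / ref_h,
        condition=obs.condition,
        scale_mode=mode,
        noise_sd=obs.noise_sd,
        seed=obs.seed,
    )
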