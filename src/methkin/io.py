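"""File formats, run configuration and command dispatch.

Formats (all plain text, UTF-8, tab-separated, floats written as %.10g):

* time-course TSV — columns ``time_h``, ``five_mC``, optional
  ``five_hmC`` and ``condition``;
* hairpin TSV — one header + one data row: ``n_full``, ``n_hemi``,
  ``n_unmeth``, ``conversion_rate``, ``nonconversion_rate``;
* surface TSV — long format, one row per grid point, free-parameter
  columns plus ``mmse``;
* fit report — flat ``key<TAB>value`` lines.

Run configuration is a YAML file (config format version 1). Times are
hours; a string with a ``d`` suffix ("14d") is converted from days, an
``h`` suffix is accepted explicitly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, conditions, dyad_model, estimation, scenarios, synthetic_data
from .estimation import FitResult, FitSpec, Surface
from .scenarios import ScenarioSpec
from .synthetic_data import HairpinCountTable, NoiseModel
from .types import (
    DyadStateVector,
    ObservationSeries,
    RateParameters,
    Trajectory,
    ValidationError,
)

__all__ = [
    "read_timecourse_tsv",
    "write_timecourse_tsv",
    "read_hairpin_tsv",
    "write_hairpin_tsv",
    "write_surface_tsv",
    "write_fit_report",
    "RunConfig",
    "run_command",
    "COMMANDS",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"
CONFIG_VERSION = 1
COMMANDS = ("simulate", "fit", "scan", "scenario", "synth", "recover")


class FormatError(ValidationError):
    """Raised when an input file violates the documented format."""


# ---------------------------------------------------------------- TSV I/O

def read_timecourse_tsv(path) -> ObservationSeries:
    """Read a time-course TSV into an :class:`ObservationSeries`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("time_h", "five_mC"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.sort_values("time_h", kind="stable")
    times = df["time_h"].to_numpy(dtype=float)
    dup = np.flatnonzero(np.diff(times) == 0)
    if dup.size:
        offenders = sorted(set(times[dup]))
        raise FormatError(f"{path}: duplicate time points {offenders}")
    condition = ""
    if "condition" in df.columns and len(df):
        condition = str(df["condition"].iloc[0])
    try:
        return ObservationSeries(
            times=times,
            five_mC=df["five_mC"].to_numpy(dtype=float),
            five_hmC=(
                df["five_hmC"].to_numpy(dtype=float)
                if "five_hmC" in df.columns else None
            ),
            condition=condition,
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_timecourse_tsv(path, obs: ObservationSeries) -> None:
    data = {"time_h": obs.times, "five_mC": obs.five_mC}
    if obs.five_hmC is not None:
        data["five_hmC"] = obs.five_hmC
    if obs.condition:
        data["condition"] = [obs.condition] * len(obs)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FMT)


def trajectory_to_series(traj: Trajectory, condition: str = "") -> ObservationSeries:
    return ObservationSeries(
        times=traj.times, five_mC=traj.five_mC, five_hmC=traj.five_hmC,
        condition=condition,
    )


def read_hairpin_tsv(path) -> HairpinCountTable:
    df = pd.read_csv(path, sep="\t")
    required = ("n_full", "n_hemi", "n_unmeth")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) != 1:
        raise FormatError(f"{path}: expected exactly one data row, got {len(df)}")
    row = df.iloc[0]
    return HairpinCountTable(
        n_full=int(row["n_full"]),
        n_hemi=int(row["n_hemi"]),
        n_unmeth=int(row["n_unmeth"]),
        conversion_rate=float(row.get("conversion_rate", 1.0)),
        nonconversion_rate=float(row.get("nonconversion_rate", 0.0)),
    )


def write_hairpin_tsv(path, counts: HairpinCountTable) -> None:
    pd.DataFrame([{
        "n_full": counts.n_full,
        "n_hemi": counts.n_hemi,
        "n_unmeth": counts.n_unmeth,
        "conversion_rate": counts.conversion_rate,
        "nonconversion_rate": counts.nonconversion_rate,
    }]).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_surface_tsv(path, surface: Surface) -> None:
    surface.to_long_frame().to_csv(path, sep="\t", index=False,
                                   float_format=FLOAT_FMT)


def write_fit_report(path, fit: FitResult) -> None:
    lines = []
    for key, val in _fit_report_items(fit):
        sval = FLOAT_FMT % val if isinstance(val, float) else str(val)
        lines.append(f"{key}\t{sval}")
    Path(path).write_text("\n".join(lines) + "\n")


def _fit_report_items(fit: FitResult):
    p = fit.best
    yield "p1", p.p1
    if p.p1_schedule is not None:
        yield "p1_final", p.p1_schedule.p1_final
        yield "p1_half_life_h", p.p1_schedule.half_life
    yield "p2", p.p2
    yield "p3", p.p3
    yield "division_time_h", p.division_time
    yield "mmse", fit.mmse
    yield "r_squared", fit.r_squared
    yield "refined", fit.refined
    yield "degenerate", fit.degenerate
    yield "n_local_minima", len(fit.minima)
    for i, m in enumerate(fit.minima):
        yield f"minimum_{i}_mmse", m.mmse
        for name, val in m.params.items():
            yield f"minimum_{i}_{name}", val


# ------------------------------------------------------------ run config

def parse_time_h(value) -> float:
    """Hours from a number, or a string with an explicit 'h'/'d' suffix."""
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip()
    if s.endswith("d"):
        return float(s[:-1]) * 24.0
    if s.endswith("h"):
        return float(s[:-1])
    return float(s)


def _params_from_dict(d: dict) -> RateParameters:
    if not isinstance(d, dict):
        raise ValidationError(f"parameter set must be a mapping, got {d!r}")
    known = {"p1", "p1_initial", "p1_final", "p1_half_life", "p2", "p3",
             "division_time"}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown parameter field(s): {sorted(unknown)}")
    for req in ("p2", "p3"):
        if req not in d:
            raise ValidationError(f"parameter set missing field {req!r}")
    division_time = parse_time_h(d.get("division_time",
                                       conditions.DIVISION_TIME_H))
    if "p1_final" in d or "p1_half_life" in d:
        for req in ("p1_initial", "p1_final", "p1_half_life"):
            if req not in d:
                raise ValidationError(
                    f"a p1 schedule needs field {req!r}"
                )
        return RateParameters.with_schedule(
            p1_initial=float(d["p1_initial"]),
            p1_final=float(d["p1_final"]),
            p1_half_life=parse_time_h(d["p1_half_life"]),
            p2=float(d["p2"]),
            p3=float(d["p3"]),
            division_time=division_time,
        )
    p1 = d.get("p1", d.get("p1_initial"))
    if p1 is None:
        raise ValidationError("parameter set missing field 'p1'")
    return RateParameters(p1=float(p1), p2=float(d["p2"]), p3=float(d["p3"]),
                          division_time=division_time)


@dataclass
class RunConfig:
    """Validated run configuration for :func:`run_command`."""

    seed: int = 0
    scale_mode: str = "none"
    out_dir: Path = Path("results")
    serum: RateParameters = conditions.SERUM
    two_i: RateParameters = conditions.TWO_I
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    fit_free: dict[str, int] = field(default_factory=lambda: {"p2": 101})
    fit_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fit_refine: bool = True
    fit_include_hmc: bool = False
    times: tuple[float, ...] = tuple(float(h) for h in
                                     (0, 16, 32, 72, 120, 168, 240, 336))
    switch_time: float = 0.0
    noise_sd: float = synthetic_data.DEFAULT_NOISE_SD
    timecourse_path: Path | None = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        version = raw.get("config_version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ValidationError(
                f"{path}: unsupported config_version {version!r}"
            )
        cfg = cls(raw=raw)
        if "seed" in raw:
            if not isinstance(raw["seed"], int):
                raise ValidationError("field 'seed' must be an integer")
            cfg.seed = raw["seed"]
        if "scale_mode" in raw:
            if raw["scale_mode"] not in ("none", "to_initial", "to_reference"):
                raise ValidationError(
                    f"field 'scale_mode' has invalid value {raw['scale_mode']!r}"
                )
            cfg.scale_mode = raw["scale_mode"]
        if "out_dir" in raw:
            cfg.out_dir = Path(raw["out_dir"])
        cond = raw.get("conditions", {})
        if "serum" in cond:
            cfg.serum = _params_from_dict(cond["serum"])
        if "two_i" in cond:
            cfg.two_i = _params_from_dict(cond["two_i"])
        if "scenario" in raw:
            s = raw["scenario"]
            try:
                cfg.scenario = ScenarioSpec(
                    knockout=s.get("knockout", "none"),
                    vitc_p3_multiplier=float(s.get("vitc_p3_multiplier", 1.0)),
                    switch_time=parse_time_h(s.get("switch_time", 0.0)),
                    division_times=(
                        tuple(parse_time_h(x) for x in s["division_times"])
                        if "division_times" in s else None
                    ),
                )
            except ValidationError as exc:
                raise ValidationError(f"field 'scenario': {exc}") from exc
        if "fit" in raw:
            f = raw["fit"]
            if "free" in f:
                free = f["free"]
                if isinstance(free, list):
                    n = int(f.get("grid_points", 101))
                    cfg.fit_free = {name: n for name in free}
                else:
                    cfg.fit_free = {k: int(v) for k, v in free.items()}
            if "bounds" in f:
                cfg.fit_bounds = {
                    k: (float(v[0]), float(v[1])) for k, v in f["bounds"].items()
                }
            cfg.fit_refine = bool(f.get("refine", True))
            cfg.fit_include_hmc = bool(f.get("include_hmc", False))
        if "synth" in raw:
            s = raw["synth"]
            if "times" in s:
                cfg.times = tuple(parse_time_h(x) for x in s["times"])
            if "noise_sd" in s:
                sd = float(s["noise_sd"])
                if sd < 0:
                    raise ValidationError("field 'synth.noise_sd' must be >= 0")
                cfg.noise_sd = sd
            if "switch_time" in s:
                cfg.switch_time = parse_time_h(s["switch_time"])
        if "paths" in raw:
            p = raw["paths"]
            if "timecourse" in p:
                cfg.timecourse_path = Path(p["timecourse"])
            if "out_dir" in p:
                cfg.out_dir = Path(p["out_dir"])
        return cfg

    def fit_spec(self, base: RateParameters) -> FitSpec:
        return FitSpec(base=base, free=dict(self.fit_free),
                       bounds=dict(self.fit_bounds),
                       refine=self.fit_refine,
                       include_hmc=self.fit_include_hmc)

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# --------------------------------------------------------------- commands

def _load_observations(cfg: RunConfig) -> ObservationSeries:
    if cfg.timecourse_path is None:
        raise ValidationError(
            "this command needs paths.timecourse in the config"
        )
    if not Path(cfg.timecourse_path).exists():
        raise ValidationError(f"input file not found: {cfg.timecourse_path}")
    obs = read_timecourse_tsv(cfg.timecourse_path)
    if cfg.scale_mode != "none":
        obs = estimation.normalize_series(obs, cfg.scale_mode)
    return obs


def _initial_state(cfg: RunConfig) -> DyadStateVector:
    return dyad_model.steady_state_dyads(cfg.serum)


def _cmd_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    traj = scenarios.predict_scenario(
        _initial_state(cfg), cfg.serum, cfg.two_i,
        ScenarioSpec(switch_time=cfg.switch_time), cfg.times,
    )
    path = out / "trajectory.tsv"
    write_timecourse_tsv(path, trajectory_to_series(traj, "simulated"))
    return [path]


def _fit(cfg: RunConfig, obs: ObservationSeries) -> FitResult:
    base = conditions.two_i_after_switch(cfg.serum, cfg.two_i)
    return estimation.grid_search(obs, _initial_state(cfg), cfg.fit_spec(base))


def _cmd_fit(cfg: RunConfig, out: Path) -> list[Path]:
    fit = _fit(cfg, _load_observations(cfg))
    report, surf = out / "fit_report.tsv", out / "mmse_surface.tsv"
    write_fit_report(report, fit)
    write_surface_tsv(surf, fit.surface)
    return [report, surf]


def _cmd_scan(cfg: RunConfig, out: Path) -> list[Path]:
    fit = _fit(cfg, _load_observations(cfg))
    surf = out / "mmse_surface.tsv"
    write_surface_tsv(surf, fit.surface)
    return [surf]


def _cmd_scenario(cfg: RunConfig, out: Path) -> list[Path]:
    initial = _initial_state(cfg)
    base_traj = scenarios.predict_scenario(
        initial, cfg.serum, cfg.two_i,
        ScenarioSpec(switch_time=cfg.scenario.switch_time), cfg.times,
    )
    traj = scenarios.predict_scenario(
        initial, cfg.serum, cfg.two_i, cfg.scenario, cfg.times,
    )
    cmp_ = scenarios.compare_rates(traj, base_traj)
    t_path = out / "scenario_trajectory.tsv"
    c_path = out / "rate_comparison.tsv"
    x_path = out / "level_crossings.tsv"
    write_timecourse_tsv(t_path, trajectory_to_series(traj, cfg.scenario.knockout))
    cmp_.per_time.to_csv(c_path, sep="\t", index=False, float_format=FLOAT_FMT)
    cmp_.crossings.to_csv(x_path, sep="\t", index=False, float_format=FLOAT_FMT)
    return [t_path, c_path, x_path]


def _cmd_synth(cfg: RunConfig, out: Path) -> list[Path]:
    noise = NoiseModel(sd=cfg.noise_sd, seed=cfg.seed)
    obs = synthetic_data.generate_timecourse(
        cfg.serum, conditions.two_i_after_switch(cfg.serum, cfg.two_i),
        cfg.switch_time, cfg.times, noise, condition="synthetic",
    )
    counts = synthetic_data.generate_hairpin_counts(
        _initial_state(cfg), n_reads=100_000, seed=cfg.seed,
    )
    t_path, h_path = out / "synthetic_timecourse.tsv", out / "synthetic_hairpin.tsv"
    write_timecourse_tsv(t_path, obs)
    write_hairpin_tsv(h_path, counts)
    return [t_path, h_path]


def _cmd_recover(cfg: RunConfig, out: Path) -> list[Path]:
    """End-to-end self test: synthesize, refit, report truth vs estimate."""
    truth = conditions.two_i_after_switch(cfg.serum, cfg.two_i)
    noise = NoiseModel(sd=cfg.noise_sd, seed=cfg.seed)
    obs = synthetic_data.generate_timecourse(
        cfg.serum, truth, cfg.switch_time, cfg.times, noise,
        condition="recovery",
    )
    if cfg.scale_mode != "none":
        obs = estimation.normalize_series(obs, cfg.scale_mode)
    fit = estimation.grid_search(obs, _initial_state(cfg),
                                 cfg.fit_spec(truth))
    rows = []
    true_vals = {
        "p1_initial": truth.p1,
        "p1_final": (truth.p1_schedule.p1_final
                     if truth.p1_schedule else truth.p1),
        "p1_half_life": (truth.p1_schedule.half_life
                         if truth.p1_schedule else float("nan")),
        "p2": truth.p2,
        "p3": truth.p3,
    }
    for name, est in fit.best_values.items():
        tv = true_vals[name]
        rows.append({"parameter": name, "truth": tv, "estimate": est,
                     "abs_error": abs(est - tv)})
    path = out / "recovery_report.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FMT)
    write_fit_report(out / "fit_report.tsv", fit)
    return [path, out / "fit_report.tsv"]


_DISPATCH = {
    "simulate": _cmd_simulate,
    "fit": _cmd_fit,
    "scan": _cmd_scan,
    "scenario": _cmd_scenario,
    "synth": _cmd_synth,
    "recover": _cmd_recover,
}


def run_command(command: str, config: RunConfig) -> list[Path]:
    """Execute one pipeline command; returns the paths written.

    Every run logs the config hash, seed, package version and wall time,
    to the run log (``run.log`` in the output directory) and stderr.
    """
    if command not in _DISPATCH:
        raise ValidationError(
            f"unknown command {command!r}; expected one of {COMMANDS}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("methkin")
    root.addHandler(handler)
    t0 = time.perf_counter()
    try:
        logger.info(
            "command=%s config_hash=%s seed=%d version=%s",
            command, config.config_hash(), config.seed, __version__,
        )
        paths = _DISPATCH[command](config, out)
        logger.info("command=%s wall_time_s=%.3f outputs=%s",
                    command, time.perf_counter() - t0,
                    [str(p) for p in paths])
        return paths
    finally:
        root.removeHandler(handler)
        handler.close()
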