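# Methods

## Model

`methkin` tracks the expected population fractions of the six unordered
CpG dyad states over {u, m, h} strand marks (u unmodified, m 5mC, h 5hmC)
through discrete cell divisions. One average division applies four events
in a fixed order:

1. **Oxidation** — each m strand becomes h with probability p3. Acting
   before replication means p3 measures TET activity against the full
   pre-replication methylated pool.
2. **Replication** — every dyad is replaced by a daughter dyad pairing one
   parent strand (chosen proportionally to strand abundance, i.e. each
   parent strand survives into exactly one daughter) with a nascent,
   fully unmodified strand. This alone halves both strand-level marks per
   division (passive dilution).
3. **Maintenance** — post-replication hemi-methylated dyads (m,u) are
   restored to (m,m) with probability p2. Hemi-hydroxymethylated dyads
   (h,u) are never maintained: DNMT1/UHRF1 recognition of the
   hemi-methylated substrate does not extend to 5hmC.
4. **De novo** — post-replication unmethylated dyads (u,u) gain one
   methyl group with probability p1, producing hemi-methylated dyads.
   De novo methylation acts only on fully unmethylated dyads, not on
   hemi-methylated ones.

Consequences of this structure: no division can produce mh or hh dyads
(every surviving strand is paired with a nascent u strand), so 5hmC is
lost purely by replication dilution — there is no further oxidation or
glycosylase excision step, consistent with active demethylation
contributing little to global 5mC loss. The event order is a declared
modeling choice; `division_step` accepts any permutation of the four
events for sensitivity analysis, but all defaults and fits use the order
above.

At the strand level, writing f and h for the per-strand 5mC and 5hmC
fractions (each strand of a dyad counting one half), the recursion is

    f' = [ f(1−p3)(1+p2) + (1−f−h)·p1 ] / 2
    h' = [ h + f·p3 ] / 2

whose fixed point, implemented in `steady_state`, is

    f* = p1 / (2 − (1−p3)(1+p2) + p1(1+p3)),   h* = p3·f*.

The fixed point is undefined only at the degenerate corner p1=0, p2=1,
p3=0 (perfect maintenance preserves any level), which raises an error.
`steady_state` is cross-checked against long `division_step` iteration to
1e−6 in the tests, and `division_step` itself against a stochastic
per-dyad Monte-Carlo simulator (3-standard-error criterion at 100,000
dyads).

### Time, schedules and observation

Divisions occur every `division_time` hours (default 16 h, i.e. about two
divisions in the first ~32 h of a course). Parameter sets are
piecewise-constant over contiguous schedule intervals (e.g. serum before
the medium switch, 2i after); a division is governed by the parameters in
effect at its start. The de novo rate may relax exponentially,

    p1(t) = p1_final + (p1_initial − p1_final)·2^(−t/half_life),

evaluated at each division boundary on a clock that restarts at the
interval boundary (the switch is what triggers DNMT3A/B downregulation).
The relaxation form is pluggable in principle; the exponential is the
simplest monotone interpolant with a single time-scale parameter.

Measurements sample an unsynchronized population at arbitrary times, so
global levels between division boundaries are obtained by linear
interpolation of the boundary levels — the simplest smooth surrogate for
the population average. Model 5mC/5hmC are per-CpG-strand fractions;
LC-MS-style measurements are assumed proportional to them, which is why
fits are invariant under the `to_initial`/`to_reference` scaling modes.

## Default study conditions

| parameter | serum | 2i | units / meaning |
|---|---|---|---|
| p1 | 0.40 | 0.40 → 0.10, half-life 24 h | de novo per division |
| p2 | 0.90 | 0.50 | maintenance per division |
| p3 | 0.03 | 0.10 | oxidation per division |
| division_time | 16 h | 16 h | hours per average division |

Rationale: serum maintenance is ~90% efficient per division; with the
serum steady state at a strand 5mC fraction ≈ 0.70–0.80 this pins the
serum de novo rate near 0.4 (f* = p1/(1−p2+p1) at p3≈0). Serum p3 = 0.03
puts steady-state 5hmC at ~3% of 5mC. The 2i values encode the
demethylation mechanism — maintenance impaired (0.9 → 0.5), de novo
suppressed about 4-fold with a ~1-day relaxation after the switch,
oxidation moderately elevated — and reproduce the qualitative landmarks
of the transition: monotone 5mC decay from ≈0.70 to a naive steady state
≈0.13 reached within 14 days (within 2% by day 14), and a transient 5hmC
rise peaking near 32–72 h. Vitamin C is modeled purely as a multiplier on
p3 (default 4), capped at 1, applied from the start of the treated phase;
knockouts zero the corresponding rate with no refitting and no
protein-decay lag (induction precedes the course). The Aicda/Tdg scenario
is the identity — encoded, and tested, as a bitwise-identical trajectory.

## Estimation

The objective is the mean squared error between predicted and observed
global 5mC, with the observation's scaling mode applied identically to
both series. 5hmC is by default **held out** of the objective and used as
an out-of-sample check of the fitted mechanism; a joint 5mC+5hmC
objective (residuals of both channels pooled with uniform weight) is
available and is required to identify p3 directly, since p3 is nearly
unidentifiable from 5mC alone (see Degeneracy). Observation weighting is
uniform.

Fitting is an exhaustive grid search over any subset of {p1_initial,
p1_final, p1_half_life, p2, p3} — default 101 points per free axis on
[0, 1] for rates — followed by an optional Nelder–Mead polish from the
best grid point (bounds enforced by clipping; the polish is kept only if
it improves the objective). The search is deterministic; equal-MMSE grid
points are broken toward the lexicographically smallest parameter tuple
in the canonical order above. The full MMSE surface is retained and
exportable as long-format TSV.

Local minima are all grid points not exceeded by any axis-neighbor;
adjacent candidates (plateaus) are merged into one minimum represented by
the lowest-value, lexicographically smallest cell, and minima are
returned in ascending MMSE order. An all-equal surface is flagged
(`degenerate`), not an error. R² (1 − SSres/SStot about the observed
mean) is reported on the fitted 5mC channel; it is an error for a
constant observed series as a standalone statistic, and NaN in fit
reports (a steady-state course is legitimately constant).

The initial dyad state for fitting comes from hairpin-derived fractions
when available, else from the serum steady state.

### Degeneracy

On a fast-decay course with negligible de novo activity the 5mC
contraction per division is (1−p3)(1+p2)/2: any (p2, p3) pair on a level
set of that product yields the same 5mC curve, while predicted 5hmC
scales with p3. A 5mC-only fit therefore shows a valley of near-optimal
local minima trading maintenance against oxidation, whose 5hmC
predictions differ several-fold — the measured 5hmC course, or the joint
objective, is what discriminates "impaired maintenance" from "TET-driven"
explanations. `analysis/05_degenerate_solutions.py` quantifies this on a
germ-cell-like synthetic course (observed spread in the packaged run:
5hmC peaks differing 5.2-fold across minima that track 5mC within ~2
noise sd).

## Synthetic data

`generate_timecourse` adds i.i.d. Gaussian noise (default sd 0.01, i.e.
1 percentage point, emulating LC-MS replicate scatter) to the model
trajectory and clips at zero. `generate_hairpin_counts` draws a
multinomial over observed dyad categories after applying the per-strand
read-error model: a truly modified strand reads methylated with
probability `conversion_rate`, a truly unmodified strand reads methylated
with probability `nonconversion_rate`; 5hmC reads as methylated
(bisulfite cannot distinguish them), and the two hemi orientations are
pooled. `estimate_state_from_counts` inverts the resulting 3×3 linear
confusion system with the stated rates (a plug-in moment correction),
clips small negatives with a logged warning and renormalizes; a supplied
external 5hmC level apportions the modified-strand mass assuming each
modified strand is independently 5hmC with the implied probability.

The stochastic per-dyad simulator applies the same four events as
independent Bernoulli draws per dyad, following one daughter per dyad
(surviving parent strand chosen uniformly), with parameters evaluated at
division starts exactly as in the deterministic model — it is the
independent brute-force oracle for `division_step`, not a wrapper
around it.

What the generators emulate: sampling design (≥8 points over 0–14 days),
measurement noise magnitude, read-depth-limited dyad fractions with
conversion errors, and medium-switch dynamics. What they do not:
replicate structure and batch effects, locus heterogeneity (every dyad is
exchangeable), cell-cycle desynchronization beyond linear interpolation,
instrument scaling/calibration drift, and sequencing artifacts beyond the
two-sided conversion error. Passing tests therefore validate the
estimator under the stated noise model, not robustness to structured
real-data artifacts.

All generators are pure functions of (inputs, seed); numpy's
`default_rng` is used throughout.

## Numerical choices and validation

* Dyad fractions must lie in [0, 1] and sum to 1 within 1e−9 for
  user-supplied states; internal steps are exact linear maps whose drift
  is checked to 1e−12 in the property tests (no renormalization needed).
* All times in hours; config files accept a `d` suffix for days.
* Output floats formatted `%.10g`; TSV round-trips are byte-stable.
* Ties and degenerate inputs: documented above (lexicographic
  tie-breaks, flat-surface flag, steady-state corner case, constant-series
  R²).
* Problem sizes: test and acceptance runs use 8–23 point courses,
  20-replicate recovery studies, 31–101-point grid axes and 100,000-dyad
  Monte-Carlo checks; the whole suite runs in a few seconds on one CPU.

## Configuration and CLI

The CLI (`methkin simulate|fit|scan|scenario|synth|recover`) wraps
`methkin.io.run_command`. Configuration is YAML (format version 1):
sections `conditions` (serum/two_i parameter sets), `scenario`, `fit`
(`free`, `bounds`, `grid_points`, `refine`, `include_hmc`), `synth`
(`times`, `noise_sd`, `switch_time`), `paths`, plus `seed` and
`scale_mode`; `--seed`, `--out-dir`, `--scale-mode` and per-rate flags
override the file. Every run logs the config hash, seed, package version
and wall time to stderr and `run.log`; identical config + seed produce
byte-identical outputs.

## Limitations

* Expectation dynamics only: no cell-to-cell variance or drift; the
  Monte-Carlo simulator provides fluctuations but no estimator consumes
  them.
* Global (genome-average) resolution: no locus classes, promoter/enhancer
  stratification, or chromatin state; the model cannot represent regions
  that resist demethylation.
* 5hmC is terminal: no iterated oxidation (5fC/5caC) or base-excision
  repair pathway; h strands are inert until diluted.
* The exponential p1 relaxation and the within-division event order are
  canonical choices, not measurements; alternatives are configurable but
  untested against data.
* In vivo stage series (embryo, germ cell) require user-supplied
  divisions-per-interval; the package ships no stage-specific defaults.
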