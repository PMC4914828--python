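#!/usr/bin/env python
"""Expose the two-solution degeneracy of 5mC-only fits on fast decay.

On a rapidly demethylating course with negligible de novo activity (the
in vivo germ-cell regime), the per-division 5mC contraction is
(1-p3)(1+p2)/2: impaired maintenance (low p2, low p3) and TET-driven
oxidation (high p2, high p3) produce the same 5mC curve. A 5mC-only MMSE
surface over (p2, p3) therefore has a valley of near-equivalent minima
whose 5hmC predictions diverge — measuring 5hmC is what discriminates the
mechanisms. The script fits such a course, lists the local minima, and
quantifies the 5mC agreement and 5hmC divergence between the extreme
solutions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from methkin.estimation import FitSpec, grid_search, predict_levels
from methkin.io import write_surface_tsv
from methkin.synthetic_data import NoiseModel, generate_timecourse
from methkin.types import DyadStateVector, RateParameters

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42
NOISE_SD = 0.005


def main() -> None:
    OUT.mkdir(exist_ok=True)
    initial = DyadStateVector(uu=0.15, um=0.10, mm=0.75)
    truth = RateParameters(p1=0.02, p2=0.3, p3=0.3)
    times = np.arange(0.0, 97.0, 16.0)
    obs = generate_timecourse(truth, truth, 0.0, times,
                              NoiseModel(sd=NOISE_SD, seed=SEED),
                              initial=initial, condition="fast_decay")

    spec = FitSpec(base=truth, free={"p2": 31, "p3": 31},
                   bounds={"p2": (0.0, 0.9), "p3": (0.0, 0.6)}, refine=False)
    fit = grid_search(obs, initial, spec)
    write_surface_tsv(OUT / "degeneracy_surface.tsv", fit.surface)

    near = [m for m in fit.minima if m.mmse < 4 * fit.mmse]
    rows = []
    for m in near:
        pm, ph = predict_levels(truth.updated(**m.params), times, initial)
        rows.append({
            "p2": m.params["p2"], "p3": m.params["p3"], "mmse": m.mmse,
            "peak_5hmC": float(ph.max()),
            "max_5mC_dev": float(np.max(np.abs(pm - obs.five_mC))),
        })
    table = pd.DataFrame(rows).sort_values("p3")
    table.to_csv(OUT / "degenerate_minima.tsv", sep="\t", index=False,
                 float_format="%.10g")

    lo, hi = table.iloc[0], table.iloc[-1]
    print(f"{len(near)} near-optimal minima along the (p2, p3) valley "
          f"(grid has {len(fit.minima)} local minima total)")
    print(table.head(3).to_string(index=False))
    print("   ...")
    print(f"'impaired maintenance' end: p2={lo.p2:.2f} p3={lo.p3:.2f} "
          f"peak 5hmC={lo.peak_5hmC:.3f}")
    print(f"'TET-driven' end:           p2={hi.p2:.2f} p3={hi.p3:.2f} "
          f"peak 5hmC={hi.peak_5hmC:.3f}")
    print(f"5hmC peak ratio between solutions: "
          f"{hi.peak_5hmC / lo.peak_5hmC:.1f}-fold; "
          f"all solutions track the observed 5mC within "
          f"{table.max_5mC_dev.max():.4f} (noise sd {NOISE_SD})")
    print(f"wrote {OUT / 'degeneracy_surface.tsv'}, "
          f"{OUT / 'degenerate_minima.tsv'}")


if __name__ == "__main__":
    main()
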