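"""Default parameter sets for the serum and 2i culture conditions.

The serum (primed) state is a hypermethylated steady state with strong
maintenance (p2 = 0.9, i.e. ~90% of hemi-methylated dyads restored per
division) and active de novo methylation; switching to 2i triggers global
passive demethylation driven mainly by impaired maintenance, with de novo
activity relaxing gradually after the medium switch and a moderate rise in
TET oxidation. Division time defaults to 16 h (about two divisions in the
first ~32 h of the switch).

With these values the serum steady state sits at a strand 5mC fraction of
~0.70 with 5hmC ~3% of 5mC, and the 2i steady state at ~0.13, reached
within 14 days of the switch — the qualitative landmarks of the
serum-to-2i LC-MS time course.
"""

from __future__ import annotations

from .types import RateParameters

__all__ = ["SERUM", "TWO_I", "two_i_after_switch", "DIVISION_TIME_H"]

#: hours per average cell division in ESC culture
DIVISION_TIME_H = 16.0

#: primed (serum/LIF) steady state: strong maintenance, active de novo
SERUM = RateParameters(p1=0.4, p2=0.9, p3=0.03, division_time=DIVISION_TIME_H)

#: naive (2i) state: maintenance impaired, de novo relaxing 0.4 -> 0.1
#: with a 24 h half-life after the switch, elevated TET oxidation
TWO_I = RateParameters.with_schedule(
    p1_initial=0.4,
    p1_final=0.1,
    p1_half_life=24.0,
    p2=0.5,
    p3=0.1,
    division_time=DIVISION_TIME_H,
)


def two_i_after_switch(serum: RateParameters = SERUM,
                       two_i: RateParameters = TWO_I) -> RateParameters:
    """2i parameter set whose p1 relaxation starts from the serum value."""
    if two_i.p1_schedule is None:
        return two_i
    return two_i.updated(p1_initial=serum.p1)
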