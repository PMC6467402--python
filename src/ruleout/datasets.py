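"""Built-in model inputs for the Hong Kong PHI evaluation.

The published inputs: a single-centre prospective cohort of 569 men
with PSA 4-10 ng/ml and normal DRE who all underwent TRUS biopsy,
tabulated by Prostate Health Index score band, together with Hospital
Authority micro-costing data and the adverse-event cascade observed in
the same cohort.  These are the base-case inputs for every analysis in
this package and the defaults used by the command-line tool.
"""

from __future__ import annotations

import math

from .cohort import Band, BandedCohort
from .model import RuleOutModel
from .params import EventProbs, UnitCosts
from .sweep import SweepSpec

__all__ = [
    "hong_kong_phi_cohort",
    "hong_kong_event_probs",
    "hong_kong_costs",
    "hong_kong_cutoffs",
    "hong_kong_sweep_specs",
    "hong_kong_model",
]


def hong_kong_phi_cohort() -> BandedCohort:
    """PHI score bands of the 569-man Hong Kong cohort.

    Per band: men / any-grade cancers / high-grade (Gleason >= 7)
    cancers.  Overall prevalence 62/569 any grade, 16/569 high grade.
    """
    return BandedCohort(
        (
            Band(0.0, 25.0, 192, 7, 1),
            Band(25.0, 35.0, 225, 17, 2),
            Band(35.0, 55.0, 131, 30, 9),
            Band(55.0, math.inf, 21, 8, 4),
        )
    )


def hong_kong_event_probs() -> EventProbs:
    """Adverse-event cascade as exact count ratios.

    39 of the 569 biopsied men attended A&E; 15 of those 39 were
    hospitalised.  The exact ratios (not their two-decimal roundings)
    are what reproduce the published expected adverse-event cost.
    """
    return EventProbs(p_ae_given_biopsy=39 / 569, p_hosp_given_ae=15 / 39)


def hong_kong_costs() -> UnitCosts:
    """Hong Kong unit costs (HK$, 2016-17 Hospital Authority tariffs)."""
    return UnitCosts(
        test_cost=3000.0,
        biopsy_cost=10900.0,
        ae_attendance_cost=1300.0,
        hosp_daily_cost=4950.0,
        mean_los=4.67,
    )


def hong_kong_cutoffs() -> tuple[float, ...]:
    """The three PHI cut-offs evaluated: 25, 35 (base case) and 55."""
    return (25.0, 35.0, 55.0)


def hong_kong_sweep_specs() -> list[SweepSpec]:
    """The nine one-way sensitivity sweeps of the published analysis.

    All ranges are base +/- 50% with probabilities capped at 1, except
    that sensitivity's upper endpoint is set to 100% outright (the
    published analysis swept it to certainty, not to 1.5 x base).
    """
    return [
        SweepSpec("sensitivity", high=1.0),
        SweepSpec("specificity"),
        SweepSpec("prevalence"),
        SweepSpec("p_ae_given_biopsy"),
        SweepSpec("p_hosp_given_ae"),
        SweepSpec("test_cost"),
        SweepSpec("biopsy_cost"),
        SweepSpec("ae_attendance_cost"),
        SweepSpec("hosp_stay_cost"),
    ]


def hong_kong_model(cutoff: float = 35.0, **kwargs) -> RuleOutModel:
    """The fully parameterised Hong Kong decision model at a cut-off."""
    return RuleOutModel(
        hong_kong_phi_cohort(),
        hong_kong_costs(),
        hong_kong_event_probs(),
        cutoff,
        **kwargs,
    )
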