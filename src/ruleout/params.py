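"""Parameter vector of the rule-out decision model.

The decision tree compares two strategies for a population eligible for
an invasive confirmatory procedure (TRUS biopsy in the motivating
application): do the procedure on everyone, or administer a rule-out
test to everyone and do the procedure only on test positives.  Every
quantity the tree needs is a scalar collected here: the test's
operating characteristics, the adverse-event cascade probabilities
(procedure -> emergency attendance -> hospitalisation) and the unit
costs.  Each scalar is independently overridable, which is what the
one-way sweep and threshold machinery relies on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .cohort import BandedCohort, Grade, performance_at_cutoff

__all__ = [
    "EventProbs",
    "UnitCosts",
    "EconParams",
    "ParamsError",
    "hospitalisation_cost",
    "PROBABILITY_PARAMS",
    "COST_PARAMS",
    "SWEEPABLE_PARAMS",
]


class ParamsError(ValueError):
    """Invalid model parameterisation."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParamsError(f"{name} must lie in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ParamsError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class EventProbs:
    """Adverse-event cascade after the procedure.

    p_ae_given_biopsy
        P(accident & emergency attendance | biopsy).
    p_hosp_given_ae
        P(hospitalisation | A&E attendance).
    """

    p_ae_given_biopsy: float
    p_hosp_given_ae: float

    def __post_init__(self) -> None:
        _check_prob("p_ae_given_biopsy", self.p_ae_given_biopsy)
        _check_prob("p_hosp_given_ae", self.p_hosp_given_ae)


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs (any currency; HK$ in the motivating application).

    hosp_daily_cost and mean_los define the base-case hospitalisation
    stay cost; the full stay cost is the scalar the sweep machinery
    varies.
    """

    test_cost: float
    biopsy_cost: float
    ae_attendance_cost: float
    hosp_daily_cost: float
    mean_los: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check_nonneg(f.name, getattr(self, f.name))


def hospitalisation_cost(costs: UnitCosts) -> float:
    """Expected cost of one hospital stay: mean length of stay x daily cost."""
    return costs.mean_los * costs.hosp_daily_cost


# Scalars of EconParams that one-way sweeps and threshold solves may vary.
PROBABILITY_PARAMS = (
    "prevalence",
    "sensitivity",
    "specificity",
    "p_ae_given_biopsy",
    "p_hosp_given_ae",
)
COST_PARAMS = ("test_cost", "biopsy_cost", "ae_attendance_cost", "hosp_stay_cost")
SWEEPABLE_PARAMS = PROBABILITY_PARAMS + COST_PARAMS


@dataclass(frozen=True)
class EconParams:
    """Full scalar parameterisation of the decision model.

    The decision arm (who gets biopsied) is driven by the any-grade
    operating characteristics ``prevalence``/``sensitivity``/
    ``specificity``.  The optional high-grade pair feeds only the
    missed-high-grade consequence and never the costs.

    ``refusal_rate`` is the fraction of men who decline biopsy; it
    applies to the procedure-for-all arm and to the test-positive arm
    alike (test negatives are never offered biopsy).  Base case 0.
    """

    prevalence: float
    sensitivity: float
    specificity: float
    p_ae_given_biopsy: float
    p_hosp_given_ae: float
    test_cost: float
    biopsy_cost: float
    ae_attendance_cost: float
    hosp_stay_cost: float
    use_test: bool = True
    refusal_rate: float = 0.0
    prevalence_high: float | None = None
    sensitivity_high: float | None = None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        for name in PROBABILITY_PARAMS:
            _check_prob(name, getattr(self, name))
        _check_prob("refusal_rate", self.refusal_rate)
        for name in COST_PARAMS:
            _check_nonneg(name, getattr(self, name))
        if self.prevalence_high is not None:
            _check_prob("prevalence_high", self.prevalence_high)
        if self.sensitivity_high is not None:
            _check_prob("sensitivity_high", self.sensitivity_high)

    @classmethod
    def from_cohort(
        cls,
        cohort: BandedCohort,
        cutoff: float,
        probs: EventProbs,
        costs: UnitCosts,
        *,
        grade: Grade = "any",
        use_test: bool = True,
        refusal_rate: float = 0.0,
    ) -> "EconParams":
        """Derive the parameter vector from banded counts at a cut-off.

        ``grade`` selects which grade's operating characteristics drive
        the biopsy decision (the base case uses any-grade); the
        high-grade characteristics are always attached for the
        missed-high consequence.
        """
        perf = performance_at_cutoff(cohort, cutoff, grade)
        perf_high = performance_at_cutoff(cohort, cutoff, "high")
        return cls(
            prevalence=float(perf.prevalence),
            sensitivity=float(perf.sensitivity),
            specificity=float(perf.specificity),
            p_ae_given_biopsy=probs.p_ae_given_biopsy,
            p_hosp_given_ae=probs.p_hosp_given_ae,
            test_cost=costs.test_cost,
            biopsy_cost=costs.biopsy_cost,
            ae_attendance_cost=costs.ae_attendance_cost,
            hosp_stay_cost=hospitalisation_cost(costs),
            use_test=use_test,
            refusal_rate=refusal_rate,
            prevalence_high=float(perf_high.prevalence),
            sensitivity_high=float(perf_high.sensitivity),
            cutoff=cutoff,
        )

    def replace(self, **changes) -> "EconParams":
        """A copy with the named scalars replaced (validation re-runs)."""
        unknown = set(changes) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ParamsError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def get(self, name: str) -> float:
        if name not in SWEEPABLE_PARAMS:
            raise ParamsError(
                f"unknown sweepable parameter {name!r}; expected one of {SWEEPABLE_PARAMS}"
            )
        return getattr(self, name)
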