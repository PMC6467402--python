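"""Decision-tree cost-consequence engine and the Model/Results interface.

Two strategies are compared as expected cost per eligible patient over
the diagnostic episode (no discounting; the horizon ends at biopsy):

* procedure-for-all -- every patient is biopsied;
* rule-out-first -- every patient takes the test (cost ``C_test``),
  positives are biopsied.

With prevalence ``pi``, sensitivity ``Se`` and specificity ``Sp``, the
rule-out-first biopsy rate is ``pi*Se + (1 - pi)*(1 - Sp)``.  Each
biopsy carries an expected adverse-event cost
``p_ae*(C_ae + p_hosp*C_hosp)``: an attender pays the A&E attendance
and, if admitted, additionally the hospital stay.  Consequences are
reported alongside costs as the fraction of the population whose
cancer the strategy misses, ``pi*(1 - Se)``, per grade.

:class:`RuleOutModel` is the statsmodels-style entry point: build it
from a banded cohort plus cost/probability inputs, call
:meth:`~RuleOutModel.fit`, and read the :class:`RuleOutResults` it
returns (savings, decomposition, ``summary()``, sweeps, thresholds,
simulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import BandedCohort, Grade
from .params import EconParams, EventProbs, UnitCosts

__all__ = [
    "StrategyResult",
    "SavingDecomposition",
    "expected_ae_cost_per_biopsy",
    "evaluate_strategy",
    "saving_vs_comparator",
    "decompose_saving",
    "cost_consequence_table",
    "RuleOutModel",
    "RuleOutResults",
]


def expected_ae_cost_per_biopsy(probs: EventProbs, costs: UnitCosts) -> float:
    """Expected adverse-event cost attached to one biopsy.

    Hospitalised patients incur both the A&E attendance cost and the
    stay cost (the cascade is biopsy -> A&E -> hospitalisation).
    """
    from .params import hospitalisation_cost

    p_ae = probs.p_ae_given_biopsy
    return p_ae * costs.ae_attendance_cost + p_ae * probs.p_hosp_given_ae * hospitalisation_cost(costs)


def _ae_cost_per_biopsy(params: EconParams) -> float:
    p_ae = params.p_ae_given_biopsy
    return p_ae * (params.ae_attendance_cost + params.p_hosp_given_ae * params.hosp_stay_cost)


@dataclass(frozen=True)
class StrategyResult:
    """Expected per-patient costs and consequences of one strategy."""

    name: str
    biopsy_rate: float
    cost_biopsies: float
    cost_test: float
    cost_ae: float
    total_cost: float
    missed_any: float
    missed_high: float  # nan when high-grade characteristics not supplied


def evaluate_strategy(params: EconParams) -> StrategyResult:
    """Expected per-patient cost and missed-cancer fractions for one strategy.

    ``params.use_test`` selects the arm: False is the procedure-for-all
    comparator (biopsy rate 1, no test cost), True is rule-out-first.
    A non-zero ``refusal_rate`` removes that fraction of would-be
    biopsies in either arm; refusers' cancers count as missed.
    """
    accept = 1.0 - params.refusal_rate
    if params.use_test:
        positive_rate = (
            params.prevalence * params.sensitivity
            + (1.0 - params.prevalence) * (1.0 - params.specificity)
        )
        rate = accept * positive_rate
        cost_test = params.test_cost
        detected_any = accept * params.prevalence * params.sensitivity
        if params.prevalence_high is not None and params.sensitivity_high is not None:
            detected_high = accept * params.prevalence_high * params.sensitivity_high
            missed_high = params.prevalence_high - detected_high
        else:
            missed_high = math.nan
        name = "rule-out-first" if params.cutoff is None else f"rule-out-first (cut-off {params.cutoff:g})"
    else:
        rate = accept
        cost_test = 0.0
        detected_any = accept * params.prevalence
        missed_high = (
            params.prevalence_high - accept * params.prevalence_high
            if params.prevalence_high is not None
            else math.nan
        )
        name = "procedure-for-all"
    missed_any = params.prevalence - detected_any
    cost_biopsies = rate * params.biopsy_cost
    cost_ae = rate * _ae_cost_per_biopsy(params)
    return StrategyResult(
        name=name,
        biopsy_rate=rate,
        cost_biopsies=cost_biopsies,
        cost_test=cost_test,
        cost_ae=cost_ae,
        total_cost=cost_biopsies + cost_test + cost_ae,
        missed_any=missed_any,
        missed_high=missed_high,
    )


def saving_vs_comparator(strategy: StrategyResult, comparator: StrategyResult) -> float:
    """Per-patient cost difference; positive means the strategy saves money."""
    return comparator.total_cost - strategy.total_cost


@dataclass(frozen=True)
class SavingDecomposition:
    """Where the net saving comes from: avoided biopsies, avoided adverse events, minus testing."""

    biopsy_saving: float
    ae_saving: float
    test_cost: float

    @property
    def net_saving(self) -> float:
        return self.biopsy_saving + self.ae_saving - self.test_cost


def decompose_saving(params: EconParams) -> SavingDecomposition:
    """Decompose the rule-out strategy's saving against procedure-for-all."""
    strategy = evaluate_strategy(params.replace(use_test=True))
    comparator = evaluate_strategy(params.replace(use_test=False))
    avoided = comparator.biopsy_rate - strategy.biopsy_rate
    return SavingDecomposition(
        biopsy_saving=avoided * params.biopsy_cost,
        ae_saving=avoided * _ae_cost_per_biopsy(params),
        test_cost=strategy.cost_test,
    )


def cost_consequence_table(
    cohort: BandedCohort,
    probs: EventProbs,
    costs: UnitCosts,
    cutoffs: Sequence[float],
    *,
    grade: Grade = "any",
    refusal_rate: float = 0.0,
) -> pd.DataFrame:
    """One row per strategy (procedure-for-all first, then each cut-off).

    Columns: strategy, biopsy_rate, cost_biopsies, cost_test, cost_ae,
    total_cost, saving_vs_biopsy_all, missed_any, missed_high.  Rates
    and missed fractions are fractions of the population in [0, 1];
    costs are per patient at full precision.
    """
    rows = []
    comparator_params = EconParams.from_cohort(
        cohort, cohort.bands[0].lower, probs, costs,
        grade=grade, use_test=False, refusal_rate=refusal_rate,
    )
    comparator = evaluate_strategy(comparator_params)
    rows.append((comparator, math.nan))
    for cutoff in cutoffs:
        params = EconParams.from_cohort(
            cohort, cutoff, probs, costs,
            grade=grade, use_test=True, refusal_rate=refusal_rate,
        )
        result = evaluate_strategy(params)
        rows.append((result, saving_vs_comparator(result, comparator)))
    return pd.DataFrame(
        {
            "strategy": [r.name for r, _ in rows],
            "biopsy_rate": [r.biopsy_rate for r, _ in rows],
            "cost_biopsies": [r.cost_biopsies for r, _ in rows],
            "cost_test": [r.cost_test for r, _ in rows],
            "cost_ae": [r.cost_ae for r, _ in rows],
            "total_cost": [r.total_cost for r, _ in rows],
            "saving_vs_biopsy_all": [s for _, s in rows],
            "missed_any": [r.missed_any for r, _ in rows],
            "missed_high": [r.missed_high for r, _ in rows],
        }
    )


class RuleOutModel:
    """Cost-consequence decision model of a rule-out test before a procedure.

    Parameters
    ----------
    cohort
        Banded score counts defining prevalence and the operating
        characteristics at each admissible cut-off.
    costs, probs
        Unit costs and adverse-event cascade probabilities.
    cutoff
        Base-case rule-out cut-off (must be a band boundary).
    grade
        Cancer-grade definition driving the biopsy decision.
    refusal_rate
        Fraction of men declining biopsy in either arm (base case 0).

    Examples
    --------
    >>> from ruleout.datasets import hong_kong_phi_cohort, hong_kong_costs, hong_kong_event_probs
    >>> model = RuleOutModel(hong_kong_phi_cohort(), hong_kong_costs(),
    ...                      hong_kong_event_probs(), cutoff=35)
    >>> res = model.fit()
    >>> round(res.saving)
    5500
    """

    def __init__(
        self,
        cohort: BandedCohort,
        costs: UnitCosts,
        probs: EventProbs,
        cutoff: float,
        *,
        grade: Grade = "any",
        refusal_rate: float = 0.0,
    ) -> None:
        self.cohort = cohort
        self.costs = costs
        self.probs = probs
        self.cutoff = cutoff
        self.grade: Grade = grade
        self.refusal_rate = refusal_rate

    @classmethod
    def from_dataframe(
        cls,
        bands: pd.DataFrame,
        costs: UnitCosts,
        probs: EventProbs,
        cutoff: float,
        **kwargs,
    ) -> "RuleOutModel":
        """Build from a DataFrame with columns lower, upper, n, n_any, n_high."""
        records = bands[["lower", "upper", "n", "n_any", "n_high"]].itertuples(index=False)
        return cls(BandedCohort.from_records(records), costs, probs, cutoff, **kwargs)

    def params(self, cutoff: float | None = None, *, use_test: bool = True) -> EconParams:
        """The scalar parameter vector at a cut-off (defaults to the base case)."""
        return EconParams.from_cohort(
            self.cohort,
            self.cutoff if cutoff is None else cutoff,
            self.probs,
            self.costs,
            grade=self.grade,
            use_test=use_test,
            refusal_rate=self.refusal_rate,
        )

    def fit(self, cutoff: float | None = None) -> "RuleOutResults":
        """Evaluate both arms of the decision tree at a cut-off."""
        params = self.params(cutoff)
        strategy = evaluate_strategy(params)
        comparator = evaluate_strategy(params.replace(use_test=False))
        return RuleOutResults(self, params, strategy, comparator)


class RuleOutResults:
    """Fitted decision-model results: costs, savings, consequences, analyses."""

    def __init__(
        self,
        model: RuleOutModel,
        params: EconParams,
        strategy: StrategyResult,
        comparator: StrategyResult,
    ) -> None:
        self.model = model
        self.params = params
        self.strategy = strategy
        self.comparator = comparator

    # -- headline quantities ----------------------------------------

    @property
    def saving(self) -> float:
        """Net per-patient saving of rule-out-first vs procedure-for-all."""
        return saving_vs_comparator(self.strategy, self.comparator)

    @property
    def decomposition(self) -> SavingDecomposition:
        return decompose_saving(self.params)

    @property
    def biopsy_rate(self) -> float:
        return self.strategy.biopsy_rate

    @property
    def missed_any(self) -> float:
        return self.strategy.missed_any

    @property
    def missed_high(self) -> float:
        return self.strategy.missed_high

    # -- derived analyses -------------------------------------------

    def cost_consequence(self, cutoffs: Sequence[float]) -> pd.DataFrame:
        return cost_consequence_table(
            self.model.cohort, self.model.probs, self.model.costs, cutoffs,
            grade=self.model.grade, refusal_rate=self.model.refusal_rate,
        )

    def sweep(self, spec) -> "TornadoEntry":  # noqa: F821 (forward ref to sweep module)
        from .sweep import one_way_sweep

        return one_way_sweep(self.params, spec)

    def tornado(self, param_names: Sequence[str] | None = None):
        from .sweep import tornado
        from .params import SWEEPABLE_PARAMS

        return tornado(self.params, list(param_names or SWEEPABLE_PARAMS))

    def threshold(self, param_name: str):
        from .sweep import threshold_solve

        return threshold_solve(self.params, param_name)

    def simulate(self, n_patients: int, seed: int, *, strategy: str | float | None = None) -> pd.DataFrame:
        """Patient-level microsimulation of this model's generative structure."""
        from .simulate import SimConfig, simulate_cohort

        config = SimConfig.from_cohort(
            self.model.cohort, self.model.probs, self.model.costs,
            n_patients=n_patients, seed=seed,
        )
        if strategy is None:
            strategy = self.model.cutoff
        return simulate_cohort(config, strategy=strategy)

    # -- reporting ---------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the base-case comparison."""
        d = self.decomposition
        lines = [
            "Rule-out decision model results",
            "=" * 54,
            f"{'Cut-off':38s}{self.params.cutoff:>16g}",
            f"{'Prevalence (decision grade)':38s}{self.params.prevalence:>15.1%}",
            f"{'Sensitivity':38s}{self.params.sensitivity:>15.1%}",
            f"{'Specificity':38s}{self.params.specificity:>15.1%}",
            "-" * 54,
            f"{'Biopsy rate (rule-out-first)':38s}{self.strategy.biopsy_rate:>15.2%}",
            f"{'Total cost, rule-out-first':38s}{self.strategy.total_cost:>16,.0f}",
            f"{'Total cost, procedure-for-all':38s}{self.comparator.total_cost:>16,.0f}",
            f"{'Net saving per patient':38s}{self.saving:>16,.0f}",
            "-" * 54,
            f"{'  saving from avoided biopsies':38s}{d.biopsy_saving:>16,.0f}",
            f"{'  saving from avoided adverse events':38s}{d.ae_saving:>16,.0f}",
            f"{'  cost of testing everyone':38s}{-d.test_cost:>16,.0f}",
            "-" * 54,
            f"{'Missed cancers, any grade':38s}{self.strategy.missed_any:>15.2%}",
            f"{'Missed cancers, high grade':38s}{self.strategy.missed_high:>15.2%}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<RuleOutResults cutoff={self.params.cutoff:g} "
            f"saving={self.saving:,.0f} biopsy_rate={self.biopsy_rate:.2%}>"
        )
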