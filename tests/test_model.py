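"""Decision-tree expected costs, savings and consequences."""

from fractions import Fraction

import pytest

from ruleout.cohort import performance_at_cutoff
from ruleout.model import (
    RuleOutModel,
    cost_consequence_table,
    decompose_saving,
    evaluate_strategy,
    expected_ae_cost_per_biopsy,
    saving_vs_comparator,
)
from ruleout.params import EconParams, EventProbs, ParamsError, UnitCosts, hospitalisation_cost

# Expected per-biopsy adverse-event cost from the exact count ratios:
# (39/569)*1300 + (15/569)*(4.67*4950), worked out by hand as a single rational.
AE_PER_BIOPSY = float(Fraction(39, 569) * 1300 + Fraction(15, 569) * Fraction(231165, 10))


@pytest.mark.parametrize(
    "los, daily, expected",
    [(4.67, 4950.0, 23116.5), (0.0, 4950.0, 0.0), (1.0, 4950.0, 4950.0)],
)
def test_hospitalisation_cost_is_stay_times_daily_rate(los, daily, expected):
    costs = UnitCosts(3000, 10900, 1300, daily, los)
    assert hospitalisation_cost(costs) == pytest.approx(expected)


def test_ae_cost_per_biopsy_matches_cascade_arithmetic(hk_probs, hk_costs):
    assert expected_ae_cost_per_biopsy(hk_probs, hk_costs) == pytest.approx(AE_PER_BIOPSY)
    assert AE_PER_BIOPSY == pytest.approx(698.5, abs=0.1)


def test_ae_cost_zero_without_attendances(hk_costs):
    assert expected_ae_cost_per_biopsy(EventProbs(0.0, 0.5), hk_costs) == 0.0


def test_ae_cost_with_certain_cascade_sums_both_events(hk_costs):
    got = expected_ae_cost_per_biopsy(EventProbs(1.0, 1.0), hk_costs)
    assert got == pytest.approx(1300 + 23116.5)


def test_rule_out_strategy_costs_match_exact_enumeration(hk_params):
    """Closed-form expected cost equals the mean over the 569 cohort members.

    Independent oracle: walk every man in the banded cohort; below the
    cut-off he pays only the test, at or above it the test, the biopsy
    and the expected adverse-event cost.
    """
    result = evaluate_strategy(hk_params)
    total = 0.0
    for n_band, positive in ((192, False), (225, False), (131, True), (21, True)):
        per_man = 3000.0 + (10900.0 + AE_PER_BIOPSY if positive else 0.0)
        total += n_band * per_man
    assert result.total_cost == pytest.approx(total / 569, rel=1e-9)
    assert result.biopsy_rate == pytest.approx(152 / 569, rel=1e-12)
    assert result.cost_test == 3000.0
    assert result.total_cost == pytest.approx(
        result.cost_biopsies + result.cost_test + result.cost_ae, rel=1e-12
    )


def test_procedure_for_all_costs_match_exact_enumeration(hk_params):
    result = evaluate_strategy(hk_params.replace(use_test=False))
    assert result.biopsy_rate == 1.0
    assert result.cost_test == 0.0
    assert result.total_cost == pytest.approx(10900.0 + AE_PER_BIOPSY, rel=1e-12)


def test_test_that_rejects_everyone_costs_only_the_test(hk_params):
    params = hk_params.replace(sensitivity=0.0, specificity=1.0)
    result = evaluate_strategy(params)
    assert result.biopsy_rate == 0.0
    assert result.total_cost == params.test_cost
    assert result.missed_any == pytest.approx(params.prevalence)


def test_invalid_probability_is_rejected(hk_params):
    with pytest.raises(ParamsError):
        hk_params.replace(sensitivity=1.2)
    with pytest.raises(ParamsError):
        hk_params.replace(p_ae_given_biopsy=-0.1)


def test_saving_is_cost_difference_between_arms(hk_params):
    strategy = evaluate_strategy(hk_params)
    comparator = evaluate_strategy(hk_params.replace(use_test=False))
    saving = saving_vs_comparator(strategy, comparator)
    # (1 - 152/569) * (10900 + AE) - 3000, worked out independently
    assert saving == pytest.approx((1 - 152 / 569) * (10900 + AE_PER_BIOPSY) - 3000, rel=1e-12)
    assert saving_vs_comparator(strategy, strategy) == 0.0


def test_saving_decomposition_sums_to_net_saving(hk_params):
    d = decompose_saving(hk_params)
    strategy = evaluate_strategy(hk_params)
    comparator = evaluate_strategy(hk_params.replace(use_test=False))
    assert d.net_saving == pytest.approx(saving_vs_comparator(strategy, comparator), rel=1e-12)
    assert d.test_cost == 3000.0


def test_cost_consequence_table_layout_and_row_sums(hk_cohort, hk_probs, hk_costs):
    table = cost_consequence_table(hk_cohort, hk_probs, hk_costs, [25.0, 35.0, 55.0])
    assert len(table) == 4
    assert table.loc[0, "strategy"] == "procedure-for-all"
    assert list(table["biopsy_rate"])[0] == 1.0
    # internal-consistency oracle: each row's total is the sum of its components
    for rec in table.itertuples(index=False):
        assert rec.total_cost == pytest.approx(
            rec.cost_biopsies + rec.cost_test + rec.cost_ae, rel=1e-12
        )
    # savings are consistent with the totals column
    for i in range(1, 4):
        assert table.loc[i, "saving_vs_biopsy_all"] == pytest.approx(
            table.loc[0, "total_cost"] - table.loc[i, "total_cost"], rel=1e-12
        )


def test_cost_consequence_table_without_cutoffs_is_comparator_only(hk_cohort, hk_probs, hk_costs):
    table = cost_consequence_table(hk_cohort, hk_probs, hk_costs, [])
    assert len(table) == 1
    assert table.loc[0, "strategy"] == "procedure-for-all"


@pytest.mark.parametrize(
    "param, delta, direction",
    [
        ("specificity", 0.01, +1),   # better rule-out -> bigger saving
        ("test_cost", 100.0, -1),    # dearer test -> smaller saving
        ("biopsy_cost", 100.0, +1),  # dearer biopsy -> bigger saving
    ],
)
def test_saving_moves_in_the_expected_direction(hk_params, param, delta, direction):
    def saving(p):
        return saving_vs_comparator(
            evaluate_strategy(p), evaluate_strategy(p.replace(use_test=False))
        )

    base = saving(hk_params)
    bumped = saving(hk_params.replace(**{param: hk_params.get(param) + delta}))
    assert direction * (bumped - base) > 0


def test_free_test_with_any_specificity_always_saves(hk_params):
    for sp in (0.05, 0.3, 0.9):
        p = hk_params.replace(test_cost=0.0, specificity=sp)
        saving = saving_vs_comparator(
            evaluate_strategy(p), evaluate_strategy(p.replace(use_test=False))
        )
        assert evaluate_strategy(p).biopsy_rate < 1.0
        assert saving > 0


def test_missed_plus_detected_equals_prevalence(hk_params):
    for se in (0.0, 0.3, 0.613, 1.0):
        p = hk_params.replace(sensitivity=se)
        r = evaluate_strategy(p)
        assert r.missed_any + p.prevalence * se == pytest.approx(p.prevalence, rel=1e-12)


def test_refusal_shrinks_saving_and_breaks_even_near_two_thirds(hk_model):
    """Refusers skip biopsy in both arms; the test arm still pays for testing.

    Under that model the saving declines linearly in the refusal rate
    and crosses zero at 1 - C_test / base_saving_before_test, about 65%.
    """
    def saving_at_refusal(r):
        return hk_model.__class__(
            hk_model.cohort, hk_model.costs, hk_model.probs, 35.0, refusal_rate=r
        ).fit().saving

    base = saving_at_refusal(0.0)
    assert saving_at_refusal(0.3) < base
    from scipy.optimize import brentq

    r_star = brentq(saving_at_refusal, 0.0, 1.0)
    assert 0.60 < r_star < 0.70


def test_model_from_dataframe_matches_direct_construction(hk_model, hk_costs, hk_probs):
    import pandas as pd

    df = pd.DataFrame(
        [(b.lower, b.upper, b.n, b.n_any, b.n_high) for b in hk_model.cohort.bands],
        columns=["lower", "upper", "n", "n_any", "n_high"],
    )
    model = RuleOutModel.from_dataframe(df, hk_costs, hk_probs, 35.0)
    assert model.fit().saving == pytest.approx(hk_model.fit().saving, rel=1e-12)


def test_summary_reports_headline_figures(hk_model):
    text = hk_model.fit().summary()
    assert "5,500" in text
    assert "26.71%" in text
    assert "7,988" in text


def test_high_grade_consequences_track_high_grade_performance(hk_cohort, hk_model):
    res = hk_model.fit()
    perf_high = performance_at_cutoff(hk_cohort, 35.0, "high")
    assert res.missed_high == pytest.approx(
        float(perf_high.prevalence * (1 - perf_high.sensitivity)), rel=1e-12
    )
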