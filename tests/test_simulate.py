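"""Synthetic patient-level cohorts: determinism, cascade logic, recovery."""

import math

import pytest

from ruleout.cohort import performance_at_cutoff
from ruleout.params import EventProbs, ParamsError, UnitCosts
from ruleout.simulate import SimConfig, simulate_cohort, summarize_to_bands


@pytest.fixture(scope="module")
def sim_config(hk_cohort, hk_probs, hk_costs):
    return SimConfig.from_cohort(hk_cohort, hk_probs, hk_costs, n_patients=2000, seed=123)


def test_identical_seed_and_config_give_identical_cohorts(sim_config):
    a = simulate_cohort(sim_config, strategy=35.0)
    b = simulate_cohort(sim_config, strategy=35.0)
    assert a.equals(b)
    assert a.to_csv(index=False) == b.to_csv(index=False)


def test_different_seeds_give_different_cohorts(hk_cohort, hk_probs, hk_costs):
    a = simulate_cohort(SimConfig.from_cohort(hk_cohort, hk_probs, hk_costs, n_patients=200, seed=1))
    b = simulate_cohort(SimConfig.from_cohort(hk_cohort, hk_probs, hk_costs, n_patients=200, seed=2))
    assert not a["phi_score"].equals(b["phi_score"])


def test_empty_cohort_has_columns_but_no_rows(hk_cohort, hk_probs, hk_costs):
    df = simulate_cohort(SimConfig.from_cohort(hk_cohort, hk_probs, hk_costs, n_patients=0, seed=5))
    assert len(df) == 0
    assert list(df.columns) == [
        "phi_score", "band_index", "cancer", "biopsied",
        "ae_attended", "hospitalised", "los", "accrued_cost",
    ]


def test_no_attendances_when_cascade_probability_is_zero(hk_cohort, hk_costs):
    cfg = SimConfig.from_cohort(hk_cohort, EventProbs(0.0, 0.5), hk_costs, n_patients=500, seed=9)
    df = simulate_cohort(cfg)
    assert not df["ae_attended"].any()
    assert not df["hospitalised"].any()


def test_event_cascade_is_nested_and_stay_only_when_hospitalised(sim_config):
    df = simulate_cohort(sim_config, strategy="biopsy_all")
    assert (df.loc[df["hospitalised"], "ae_attended"]).all()
    assert (df.loc[df["ae_attended"], "biopsied"]).all()
    assert ((df["los"] > 0) == df["hospitalised"]).all()
    assert (df.loc[df["hospitalised"], "los"] >= 1).all()


def test_rule_out_strategy_biopsies_only_scores_at_or_above_cutoff(sim_config):
    df = simulate_cohort(sim_config, strategy=35.0)
    assert (df["biopsied"] == (df["phi_score"] >= 35.0)).all()
    # everyone pays at least the test
    assert (df["accrued_cost"] >= 3000.0).all()


def test_invalid_generative_parameters_are_rejected(hk_probs, hk_costs):
    with pytest.raises(ParamsError):
        SimConfig(
            n_patients=10, band_edges=(0.0, 25.0, 50.0), band_weights=(0.7, 0.7),
            p_any=(0.1, 0.1), p_high=(0.05, 0.05), probs=hk_probs, costs=hk_costs, seed=1,
        )
    with pytest.raises(ParamsError):
        SimConfig(
            n_patients=10, band_edges=(0.0, 25.0, 50.0), band_weights=(0.5, 0.5),
            p_any=(0.1, 0.1), p_high=(0.2, 0.05), probs=hk_probs, costs=hk_costs, seed=1,
        )
    with pytest.raises(ParamsError):
        simulate_cohort(
            SimConfig(
                n_patients=1, band_edges=(0.0, 25.0), band_weights=(1.0,),
                p_any=(0.1,), p_high=(0.0,), probs=hk_probs, costs=hk_costs, seed=1,
            ),
            strategy="do_everything",
        )


def test_band_shares_converge_to_configured_weights(hk_cohort, hk_probs, hk_costs):
    """Law-of-large-numbers check against the configured band proportions."""
    cfg = SimConfig.from_cohort(hk_cohort, hk_probs, hk_costs, n_patients=56_900, seed=2024)
    df = simulate_cohort(cfg)
    shares = df["band_index"].value_counts(normalize=True).sort_index()
    for i, weight in enumerate(cfg.band_weights):
        assert shares.get(i, 0.0) == pytest.approx(weight, abs=0.005)


def test_summarize_single_patient(hk_cohort, hk_probs, hk_costs):
    cfg = SimConfig.from_cohort(hk_cohort, hk_probs, hk_costs, n_patients=1, seed=3)
    df = simulate_cohort(cfg)
    cohort = summarize_to_bands(df, cfg.band_edges)
    assert cohort.n_total == 1
    assert cohort.bands[df.loc[0, "band_index"]].n == 1


def test_summarize_round_trip_recovers_operating_characteristics(hk_cohort, hk_probs, hk_costs):
    """Band the simulated patients back up and re-derive Se/Sp at cut-off 35."""
    n = 40_000
    cfg = SimConfig.from_cohort(hk_cohort, hk_probs, hk_costs, n_patients=n, seed=77)
    df = simulate_cohort(cfg, strategy=35.0)
    cohort = summarize_to_bands(df, cfg.band_edges)
    got = performance_at_cutoff(cohort, 35.0, "any")
    want = performance_at_cutoff(hk_cohort, 35.0, "any")
    n_cancers = cohort.n_cancer("any")
    se_tol = 3 * math.sqrt(float(want.sensitivity) * (1 - float(want.sensitivity)) / n_cancers)
    sp_tol = 3 * math.sqrt(float(want.specificity) * (1 - float(want.specificity)) / (n - n_cancers))
    assert float(got.sensitivity) == pytest.approx(float(want.sensitivity), abs=se_tol)
    assert float(got.specificity) == pytest.approx(float(want.specificity), abs=sp_tol)
    # high-grade tallies are a subset of any-grade tallies in every band
    for band in cohort.bands:
        assert band.n_high <= band.n_any <= band.n


def test_cascade_frequencies_converge_to_configured_probabilities(hk_cohort, hk_probs, hk_costs):
    cfg = SimConfig.from_cohort(hk_cohort, hk_probs, hk_costs, n_patients=30_000, seed=11)
    df = simulate_cohort(cfg, strategy="biopsy_all")
    n_ae = int(df["ae_attended"].sum())
    p_ae_hat = n_ae / len(df)
    p_hosp_hat = df["hospitalised"].sum() / n_ae
    tol_ae = 3 * math.sqrt(hk_probs.p_ae_given_biopsy * (1 - hk_probs.p_ae_given_biopsy) / len(df))
    tol_hosp = 3 * math.sqrt(hk_probs.p_hosp_given_ae * (1 - hk_probs.p_hosp_given_ae) / n_ae)
    assert p_ae_hat == pytest.approx(hk_probs.p_ae_given_biopsy, abs=tol_ae)
    assert p_hosp_hat == pytest.approx(hk_probs.p_hosp_given_ae, abs=tol_hosp)
    # length of stay is 1 + Poisson(mean_los - 1): mean within 3 SE among the hospitalised
    stays = df.loc[df["hospitalised"], "los"]
    tol_los = 3 * stays.std() / math.sqrt(len(stays))
    assert stays.mean() == pytest.approx(4.67, abs=tol_los)


def test_mean_accrued_cost_matches_closed_form_expectation(hk_model):
    """Monte-Carlo microsimulation against the decision model's closed form."""
    res = hk_model.fit()
    df = res.simulate(30_000, seed=42, strategy="biopsy_all")
    se = df["accrued_cost"].std() / math.sqrt(len(df))
    assert df["accrued_cost"].mean() == pytest.approx(res.comparator.total_cost, abs=3 * se)
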