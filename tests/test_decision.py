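import itertools

import numpy as np
import pandas as pd
import pytest

from pewlsim import SimulationConfig
from pewlsim.decision import (
    allocate_surgeries,
    cases_prevented,
    conditional_risk_curves,
    population_case_probability,
    threshold_sweep,
)


def _naive_case_probability(alpha, p_t, p_u, tau):
    """Direct loop transcription of the printed population-probability formula."""
    treated = [p for a, p in zip(alpha, p_t) if a > tau]
    untreated = [p for a, p in zip(alpha, p_u) if a <= tau]
    if not treated:
        return sum(untreated) / len(untreated)
    if not untreated:
        return sum(treated) / len(treated)
    return (sum(treated) / len(treated) + sum(untreated) / len(untreated)) / 2


def test_case_probability_hand_example(toy_risks):
    risks, predictions = toy_risks
    # ((0.1 + 0.2)/2 + (0.5 + 0.7)/2) / 2 = 0.375
    got = population_case_probability(risks, predictions, 70.0, "t2dm")
    assert got == pytest.approx(0.375)


def test_case_probability_constant_field(toy_risks):
    risks, predictions = toy_risks
    risks = risks.assign(p_t2dm_treated=0.2, p_t2dm_untreated=0.2)
    for tau in (40.0, 70.0, 95.0):
        assert population_case_probability(risks, predictions, tau) == pytest.approx(0.2)


def test_case_probability_empty_group_conventions(toy_risks):
    risks, predictions = toy_risks
    # tau above every prediction: mean of all untreated probabilities
    got = population_case_probability(risks, predictions, 95.0, "t2dm")
    assert got == pytest.approx(np.mean([0.3, 0.4, 0.5, 0.7]))
    # tau below every prediction: mean of all treated probabilities
    got = population_case_probability(risks, predictions, 10.0, "t2dm")
    assert got == pytest.approx(np.mean([0.1, 0.2, 0.45, 0.65]))


def test_case_probability_weighted_variant(toy_risks):
    risks, predictions = toy_risks
    got = population_case_probability(risks, predictions, 70.0, "t2dm", weighted=True)
    assert got == pytest.approx((0.1 + 0.2 + 0.5 + 0.7) / 4)


def test_case_probability_matches_naive_oracle_on_random_cohorts():
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = rng.integers(2, 30)
        alpha = rng.normal(63, 7.6, n)
        p_t = rng.uniform(0, 1, n)
        p_u = rng.uniform(0, 1, n)
        risks = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "p_t2dm_treated": p_t,
                "p_t2dm_untreated": p_u,
                "p_adverse_event": rng.uniform(0, 0.2, n),
            }
        )
        predictions = pd.DataFrame(
            {"subject_id": np.arange(n), "predicted_pewl": alpha}
        )
        tau = rng.uniform(45, 80)
        assert population_case_probability(
            risks, predictions, tau
        ) == pytest.approx(_naive_case_probability(alpha, p_t, p_u, tau))


def test_allocation_ranking_cap_and_ties():
    preds = pd.DataFrame(
        {"subject_id": [10, 11, 12, 13, 14], "predicted_pewl": [70, 90, 80, 60, 85]}
    )
    assert allocate_surgeries(preds, 0.0, 3).tolist() == [11, 14, 12]
    assert allocate_surgeries(preds, 95.0, 3).size == 0
    tie = pd.DataFrame(
        {"subject_id": [5, 2, 9], "predicted_pewl": [80.0, 80.0, 70.0]}
    )
    assert allocate_surgeries(tie, 75.0, 1).tolist() == [2]  # lower id wins the tie
    # threshold is strict: a prediction exactly at tau is not allocated
    assert allocate_surgeries(tie, 80.0, 3).size == 0


def test_allocation_is_optimal_by_brute_force():
    """Among all equal-size subsets, the allocated one maximizes mean prediction."""
    rng = np.random.default_rng(7)
    for n in (5, 9, 12):
        alpha = rng.normal(63, 7.6, n)
        preds = pd.DataFrame({"subject_id": np.arange(n), "predicted_pewl": alpha})
        chosen = allocate_surgeries(preds, alpha.min() - 1, 4)
        best = max(
            (np.mean(alpha[list(s)]) for s in itertools.combinations(range(n), 4))
        )
        assert np.mean(alpha[np.isin(np.arange(n), chosen)]) == pytest.approx(best)


def test_cases_prevented_hand_example(toy_risks):
    risks, predictions = toy_risks
    cfg = SimulationConfig(n_surgeries=2)
    got = cases_prevented(risks, predictions, 70.0, cfg, "t2dm", "untreated_baseline")
    assert got == pytest.approx(2 * (0.475 - 0.15))
    got = cases_prevented(risks, predictions, 70.0, cfg, "t2dm", "random_allocation")
    assert got == pytest.approx(2 * (0.35 - 0.15))


def test_no_selection_benefit_for_identical_risks(toy_risks):
    risks, predictions = toy_risks
    risks = risks.assign(p_t2dm_treated=0.2, p_t2dm_untreated=0.5)
    cfg = SimulationConfig(n_surgeries=2)
    assert cases_prevented(
        risks, predictions, 70.0, cfg, "t2dm", "random_allocation"
    ) == pytest.approx(0.0)
    assert cases_prevented(
        risks, predictions, 70.0, cfg, "t2dm", "untreated_baseline"
    ) == pytest.approx(2 * 0.3)


def test_cases_prevented_empty_allocation_errors(toy_risks):
    risks, predictions = toy_risks
    with pytest.raises(ValueError):
        cases_prevented(risks, predictions, 95.0, SimulationConfig())


def test_sweep_grid_shape_and_consistency(toy_risks):
    risks, predictions = toy_risks
    cfg = SimulationConfig(n_surgeries=2)
    sweep = threshold_sweep(risks, predictions, cfg)
    assert len(sweep) == 26
    assert sweep["tau"].iloc[0] == 55.0 and sweep["tau"].iloc[-1] == 80.0
    assert (sweep["n_treated"] + sweep["n_untreated"] == 4).all()
    assert (np.diff(sweep["n_treated"]) <= 0).all()
    # every row equals an independent per-tau evaluation
    for _, row in sweep.iterrows():
        tau = row["tau"]
        assert row["p_case_t2dm"] == pytest.approx(
            population_case_probability(risks, predictions, tau, "t2dm")
        )
        expected = cases_prevented(risks, predictions, tau, cfg, "ae", "random_allocation")
        assert row["n_prevented_ae_random_allocation"] == pytest.approx(expected)


def test_sweep_single_threshold(toy_risks):
    risks, predictions = toy_risks
    cfg = SimulationConfig(tau_min=60.0, tau_max=60.0)
    sweep = threshold_sweep(risks, predictions, cfg)
    assert len(sweep) == 1


def test_sweep_records_missing_allocation_as_nan(toy_risks):
    risks, predictions = toy_risks
    cfg = SimulationConfig(tau_min=85.0, tau_max=95.0, tau_step=5.0)
    sweep = threshold_sweep(risks, predictions, cfg)
    assert sweep["n_prevented_t2dm_random_allocation"].isna().tolist() == [
        False,
        True,
        True,
    ]


def test_treated_set_utility_is_monotone_in_threshold(default_run, config):
    """Raising the threshold concentrates treatment on better responders:
    mean actual PEWL of the treated rises and mean AE probability falls."""
    outcomes = default_run["outcomes"]
    risks = default_run["risks"]
    data = outcomes.merge(risks, on="subject_id")
    pewl_means, ae_means = [], []
    for tau in config.tau_grid():
        ids = allocate_surgeries(outcomes, tau, config.n_surgeries)
        sel = data.set_index("subject_id").loc[ids]
        pewl_means.append(sel["pewl"].mean())
        ae_means.append(sel["p_adverse_event"].mean())
    assert pewl_means[-1] > pewl_means[0]
    assert ae_means[-1] < ae_means[0]
    # allow only small sampling wobble against the monotone trend (the
    # treated set shrinks to ~45 subjects at the top threshold)
    assert np.min(np.diff(pewl_means)) > -2.0
    assert np.max(np.diff(ae_means)) < 5e-4


def test_null_predictor_gives_no_expected_selection_benefit():
    """With zero predictor-outcome correlation, test-guided allocation prevents
    no cases on average relative to first-come-first-serve."""
    from pewlsim.pipeline import simulate_cohort, simulate_outcomes
    from pewlsim.population import filter_eligible
    from pewlsim.risk import build_risk_profiles

    cfg = SimulationConfig(predictor_pewl_corr=0.0)
    values = []
    for seed in range(5):
        cohort = simulate_cohort(cfg, seed)
        eligible = filter_eligible(cohort)
        outc = simulate_outcomes(eligible, cfg, seed)
        risks, _, _ = build_risk_profiles(eligible, outc, cfg)
        values.append(
            cases_prevented(risks, outc, 55.0, cfg, "t2dm", "random_allocation")
        )
    # per-seed MC noise on N is a few cases; the 5-seed mean should sit near 0
    assert abs(np.mean(values)) < 8.0


def test_conditional_curves_constant_risks(toy_risks):
    rng = np.random.default_rng(3)
    n = 200
    risks = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "p_t2dm_treated": 0.17,
            "p_t2dm_untreated": 0.42,
            "p_adverse_event": 0.05,
        }
    )
    predictions = pd.DataFrame(
        {"subject_id": np.arange(n), "predicted_pewl": rng.normal(63, 7.6, n)}
    )
    grid = np.linspace(
        predictions["predicted_pewl"].min(), predictions["predicted_pewl"].max(), 11
    )
    curves = conditional_risk_curves(risks, predictions, grid)
    assert np.allclose(curves["p_t2dm_treated"], 0.17, atol=1e-8)
    assert np.allclose(curves["p_t2dm_untreated"], 0.42, atol=1e-8)


def test_conditional_curves_match_binned_means(default_run):
    outcomes = default_run["outcomes"]
    risks = default_run["risks"]
    alpha = outcomes["predicted_pewl"].to_numpy()
    lo, hi = np.quantile(alpha, [0.05, 0.95])
    deciles = np.quantile(alpha, np.linspace(0.05, 0.95, 10))
    curves = conditional_risk_curves(risks, outcomes, deciles)
    merged = outcomes.merge(risks, on="subject_id")
    # binned conditional means around each evaluation point
    for col in ("p_t2dm_treated", "p_t2dm_untreated"):
        for i, a in enumerate(deciles):
            window = merged.loc[(alpha > a - 2.0) & (alpha < a + 2.0), col]
            assert abs(curves[col].iloc[i] - window.mean()) < 0.03
    # with the default negative weight-PEWL association the treated curve falls
    slope = np.polyfit(deciles, curves["p_t2dm_treated"], 1)[0]
    assert slope < 0


def test_conditional_curves_refuse_extrapolation(default_run):
    outcomes = default_run["outcomes"]
    risks = default_run["risks"]
    grid = np.array([outcomes["predicted_pewl"].max() + 5.0])
    with pytest.raises(ValueError):
        conditional_risk_curves(risks, outcomes, grid)
    with pytest.raises(ValueError):
        conditional_risk_curves(risks.head(5), outcomes.head(5), np.array([63.0]))
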