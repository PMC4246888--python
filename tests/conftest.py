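import numpy as np
import pandas as pd
import pytest

from pewlsim import SimulationConfig
from pewlsim.decision import cases_prevented, threshold_sweep
from pewlsim.pipeline import simulate_cohort, simulate_outcomes
from pewlsim.population import filter_eligible
from pewlsim.risk import build_risk_profiles

REPLICATE_SEEDS = (101, 102, 103, 104, 105)


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_run(config):
    """One full-size simulation with every intermediate table retained."""
    cohort = simulate_cohort(config, REPLICATE_SEEDS[0])
    eligible = filter_eligible(cohort)
    outcomes = simulate_outcomes(eligible, config, REPLICATE_SEEDS[0])
    risks, dmap, ae_model = build_risk_profiles(eligible, outcomes, config)
    sweep = threshold_sweep(risks, outcomes, config)
    return {
        "cohort": cohort,
        "eligible": eligible,
        "outcomes": outcomes,
        "risks": risks,
        "diabetes_map": dmap,
        "ae_model": ae_model,
        "sweep": sweep,
    }


@pytest.fixture(scope="session")
def replicate_stats(config):
    """Per-seed summary statistics over five independent replicates."""
    from pewlsim.population import simulate_population
    from pewlsim.seeding import stage_rng

    rows = []
    for seed in REPLICATE_SEEDS:
        cohort = simulate_cohort(config, seed)
        eligible = filter_eligible(cohort)
        outcomes = simulate_outcomes(eligible, config, seed)
        risks, _, _ = build_risk_profiles(eligible, outcomes, config)
        # parameter recovery is judged on the pre-filter draw: outlier
        # removal truncates the tails and would bias the location checks
        raw = simulate_population(
            config, stage_rng(seed, "population"), apply_filters=False
        )
        females = raw.loc[~raw["is_male"]]
        rows.append(
            {
                "n_simulated": len(cohort),
                "n_eligible": len(eligible),
                "n_female": len(females),
                "female_height_mean": females["height_cm"].mean(),
                "pewl_mean": outcomes["pewl"].mean(),
                "pewl_sd": outcomes["pewl"].std(ddof=1),
                "predictor_sd": outcomes["predicted_pewl"].std(ddof=1),
                "predictor_corr": np.corrcoef(
                    outcomes["pewl"], outcomes["predicted_pewl"]
                )[0, 1],
                "mean_ae": risks["p_adverse_event"].mean(),
                "mean_t2dm_untreated": risks["p_t2dm_untreated"].mean(),
                "n80_random": cases_prevented(
                    risks, outcomes, 80.0, config, "t2dm", "random_allocation"
                ),
                "n80_untreated": cases_prevented(
                    risks, outcomes, 80.0, config, "t2dm", "untreated_baseline"
                ),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_risks():
    """Four-subject cohort with hand-checkable risk and prediction values."""
    risks = pd.DataFrame(
        {
            "subject_id": [1, 2, 3, 4],
            "p_t2dm_treated": [0.1, 0.2, 0.45, 0.65],
            "p_t2dm_untreated": [0.3, 0.4, 0.5, 0.7],
            "p_adverse_event": [0.05, 0.06, 0.07, 0.08],
        }
    )
    predictions = pd.DataFrame(
        {"subject_id": [1, 2, 3, 4], "predicted_pewl": [90.0, 85.0, 60.0, 50.0]}
    )
    return risks, predictions
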