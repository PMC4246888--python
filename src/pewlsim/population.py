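"""Synthetic cohort: correlated height/weight, sex offsets, eligibility.

Heights and log-weights are drawn from a bivariate normal whose
parameters describe US adult females; sex is assigned by a uniform draw
and male subjects receive additive offsets on the natural scales
(+13 cm, +9.4 kg by default). Implausible records (weight > 180 kg or
< 38 kg, height < 145 cm) are dropped rather than resampled, so the
cohort may be slightly smaller than ``n_population``. Subjects with
BMI >= 35 (inclusive) form the surgery-eligible subset.

The cohort is a :class:`pandas.DataFrame` with columns
``id, is_male, height_cm, weight_kg, bmi, ideal_weight_kg,
excess_weight_kg, eligible``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from pewlsim.config import ConfigurationError, SimulationConfig
from pewlsim.seeding import as_rng

COHORT_COLUMNS = [
    "id",
    "is_male",
    "height_cm",
    "weight_kg",
    "bmi",
    "ideal_weight_kg",
    "excess_weight_kg",
    "eligible",
]


def simulate_population(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    apply_filters: bool = True,
) -> pd.DataFrame:
    """Simulate the full cohort and derive body measures.

    Draw order is fixed (sex first, then the multivariate-normal
    height/log-weight sample) so a given ``(config, seed)`` pair always
    yields the identical table. Male offsets are applied after the
    log-weight is exponentiated; outlier filtering happens last.

    ``apply_filters=False`` keeps the outlier rows; use it to check
    recovery of the generative location/shape parameters, which tail
    truncation would otherwise bias (dropping heights below 145 cm
    alone shifts the female mean up by ~0.1 cm).
    """
    rng = as_rng(seed)
    n = config.n_population
    if n <= 0:
        raise ConfigurationError("n_population must be positive")
    cov = config.covariance_matrix()
    # eigenvalue check admits the degenerate (zero-variance) case
    if np.min(np.linalg.eigvalsh(cov)) < -1e-9:
        raise ConfigurationError("height/log-weight covariance matrix is not PSD")

    is_male = rng.uniform(size=n) > config.male_fraction_cutoff
    draws = rng.multivariate_normal(
        [config.height_mean_f, config.logweight_mean_f], cov, size=n, method="svd"
    )
    height = draws[:, 0] + config.male_height_offset * is_male
    weight = np.exp(draws[:, 1]) + config.male_weight_offset * is_male

    if apply_filters:
        keep = (
            (weight <= config.weight_max)
            & (weight >= config.weight_min)
            & (height >= config.height_min)
        )
    else:
        keep = np.ones(n, dtype=bool)
    cohort = pd.DataFrame(
        {
            "id": np.arange(n)[keep],
            "is_male": is_male[keep],
            "height_cm": height[keep],
            "weight_kg": weight[keep],
        }
    ).reset_index(drop=True)
    return derive_body_measures(cohort, config)


def derive_body_measures(
    cohort: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Fill ``bmi``, ``ideal_weight_kg``, ``excess_weight_kg``, ``eligible``.

    Ideal weight is the weight at the ideal BMI (25 kg/m^2 by default)
    for the subject's height; excess weight is the difference from it.
    Eligibility is BMI at or above the surgical cutoff.
    """
    if (cohort["height_cm"] <= 0).any() or (cohort["weight_kg"] <= 0).any():
        raise ValueError("heights and weights must be positive")
    out = cohort.copy()
    h_m = out["height_cm"].to_numpy() / 100.0
    w = out["weight_kg"].to_numpy()
    out["bmi"] = w / h_m**2
    out["ideal_weight_kg"] = config.ideal_bmi * h_m**2
    out["excess_weight_kg"] = w - out["ideal_weight_kg"]
    out["eligible"] = out["bmi"] >= config.bmi_eligibility
    return out[COHORT_COLUMNS] if set(COHORT_COLUMNS) <= set(out.columns) else out


def filter_eligible(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return the surgery-eligible subjects, original order preserved."""
    return cohort.loc[cohort["eligible"]].reset_index(drop=True)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    out = cohort.copy()
    out["is_male"] = out["is_male"].astype(int)
    out["eligible"] = out["eligible"].astype(int)
    out.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort file {path} is missing columns {sorted(missing)}")
    cohort["is_male"] = cohort["is_male"].astype(bool)
    cohort["eligible"] = cohort["eligible"].astype(bool)
    return cohort[COHORT_COLUMNS]
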