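"""Surgical weight loss (PEWL), its genomic prediction, and post-surgery BMI.

Percentage of excess weight loss (PEWL) is built by the
standardize-mix-rescale recipe: the standardized baseline weight is mixed
with an independent standard-normal residual, and the mixture is then
affinely rescaled to the target mean and SD (63 ± 23 % by default). The
genomic predictor of PEWL is built from actual PEWL by the same recipe,
targeting mean 63, SD 7.6 and correlation 0.316 (predictive R^2 = 0.1).

The default association between PEWL and baseline weight is negative
(heavier patients lose a smaller fraction of their excess weight), which
is the sign required for predictor-guided selection to favour lighter,
lower-surgical-risk patients.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from pewlsim.config import ConfigurationError, SimulationConfig
from pewlsim.seeding import as_rng

OUTCOME_COLUMNS = ["subject_id", "pewl", "predicted_pewl", "post_weight_kg", "post_bmi"]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant sample")
    return (x - x.mean()) / sd


def _rescale(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return mean + sd * _standardize(x)


def _mix(z: np.ndarray, coef: float, resid_coef: float, rng: np.random.Generator) -> np.ndarray:
    return coef * z + resid_coef * rng.standard_normal(z.shape[0])


def simulate_pewl(
    eligible: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate actual PEWL (%) for each eligible subject.

    The sample is rescaled to have mean ``pewl_mean`` and SD ``pewl_sd``
    exactly, and correlates with baseline weight at
    ``pewl_weight_assoc_sign * pewl_weight_assoc`` up to Monte Carlo
    error. Values are not truncated to [0, 100]; the normal tails are
    kept as simulated.
    """
    if len(eligible) < 2:
        raise ValueError("need at least two subjects to standardize weight")
    rng = as_rng(seed)
    zw = _standardize(eligible["weight_kg"].to_numpy())
    coef = config.pewl_weight_assoc_sign * config.pewl_weight_assoc
    raw = _mix(zw, coef, config.pewl_residual_coef(), rng)
    return _rescale(raw, config.pewl_mean, config.pewl_sd)


def simulate_predictor(
    pewl: np.ndarray,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the genomic prediction of PEWL (%) from actual PEWL."""
    r = config.predictor_pewl_corr
    if abs(r) > 1:
        raise ConfigurationError("predictor_pewl_corr must lie in [-1, 1]")
    pewl = np.asarray(pewl, dtype=float)
    if pewl.size < 2:
        raise ValueError("need at least two subjects to standardize PEWL")
    rng = as_rng(seed)
    raw = _mix(_standardize(pewl), r, float(np.sqrt(1.0 - r**2)), rng)
    return _rescale(raw, config.predictor_mean, config.predictor_sd)


def apply_surgery(
    weight_kg: np.ndarray | float,
    excess_weight_kg: np.ndarray | float,
    height_cm: np.ndarray | float,
    pewl: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Post-surgery weight and BMI: subtract ``excess_weight * PEWL/100``."""
    post_weight = np.asarray(weight_kg, dtype=float) - np.asarray(
        excess_weight_kg, dtype=float
    ) * np.asarray(pewl, dtype=float) / 100.0
    post_bmi = post_weight / (np.asarray(height_cm, dtype=float) / 100.0) ** 2
    return post_weight, post_bmi


def build_outcomes(
    eligible: pd.DataFrame,
    config: SimulationConfig,
    pewl_seed: int | np.random.Generator | None = None,
    predictor_seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate PEWL and its prediction, apply surgery, return one table."""
    pewl = simulate_pewl(eligible, config, pewl_seed)
    predicted = simulate_predictor(pewl, config, predictor_seed)
    post_weight, post_bmi = apply_surgery(
        eligible["weight_kg"].to_numpy(),
        eligible["excess_weight_kg"].to_numpy(),
        eligible["height_cm"].to_numpy(),
        pewl,
    )
    return pd.DataFrame(
        {
            "subject_id": eligible["id"].to_numpy(),
            "pewl": pewl,
            "predicted_pewl": predicted,
            "post_weight_kg": post_weight,
            "post_bmi": post_bmi,
        }
    )


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    outcomes[OUTCOME_COLUMNS].to_csv(path, index=False)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    outcomes = pd.read_csv(path)
    missing = set(OUTCOME_COLUMNS) - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcome file {path} is missing columns {sorted(missing)}")
    return outcomes[OUTCOME_COLUMNS]
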