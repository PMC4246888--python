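"""Risk models: BMI -> lifetime T2DM probability; weight/sex -> AE probability.

Two monotone BMI-to-diabetes maps are provided:

``anchored_spline``
    A monotone (PCHIP) interpolating spline through (BMI, lifetime-risk)
    anchors placed at BMI-category midpoints, following published
    dose-response estimates of adult lifetime diabetes risk.

``ecdf``
    The literal grid construction: standardize a dense uniform BMI grid
    over the reference range, multiply by a scale, and read probabilities
    off the empirical CDF of the scaled grid values. Because the ECDF of
    a monotone transform of a uniform grid is the uniform CDF, this is a
    linear ramp over the reference range (the scale has no effect); it is
    retained for fidelity to the original construction.

Either map can be calibrated by a single additive shift on the log-odds
scale so its mean over the eligible cohort's baseline BMIs matches a
target lifetime risk (0.28 by default). The shift preserves monotonicity
and the [0, 1] range. BMI outside the reference range is clamped to the
boundary value rather than extrapolated.

The adverse-event (AE) model is logistic in the standardized baseline
covariate (weight by default, optionally BMI) plus a male indicator,
with the intercept calibrated so the eligible-cohort mean equals a
target rate (0.049 by default). The positive weight coefficient encodes
that surgical complications are more likely in heavier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.special import expit, logit

from pewlsim.config import CalibrationError, ConfigurationError, SimulationConfig

RISK_COLUMNS = ["subject_id", "p_t2dm_untreated", "p_t2dm_treated", "p_adverse_event"]

_P_EPS = 1e-12  # probability clip before the logit transform
_ECDF_GRID_N = 2001


def _shift_logodds(p: np.ndarray, c: float) -> np.ndarray:
    return expit(logit(np.clip(p, _P_EPS, 1.0 - _P_EPS)) + c)


@dataclass
class DiabetesRiskMap:
    """Monotone map from BMI to lifetime probability of Type-2 diabetes."""

    strategy: str
    reference_bmi_range: tuple[float, float]
    scale: float = 0.8
    anchors: tuple[tuple[float, float], ...] | None = None
    calibration_scalar: float = 0.0  # additive log-odds shift; 0 = uncalibrated
    _interp: PchipInterpolator | None = field(default=None, repr=False, compare=False)
    _grid_sorted: np.ndarray | None = field(default=None, repr=False, compare=False)
    _grid_mean: float = field(default=0.0, repr=False, compare=False)
    _grid_sd: float = field(default=1.0, repr=False, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.reference_bmi_range
        if self.strategy == "anchored_spline":
            if self.anchors is None:
                raise ConfigurationError("anchored_spline strategy requires anchors")
            a = np.asarray(self.anchors, dtype=float)
            if np.any(np.diff(a[:, 0]) <= 0) or np.any(np.diff(a[:, 1]) <= 0):
                raise ConfigurationError(
                    "anchors must be strictly increasing in BMI and probability"
                )
            self._interp = PchipInterpolator(a[:, 0], a[:, 1], extrapolate=True)
        elif self.strategy == "ecdf":
            grid = np.linspace(lo, hi, _ECDF_GRID_N)
            self._grid_mean = float(grid.mean())
            self._grid_sd = float(grid.std(ddof=1))
            self._grid_sorted = np.sort(self.scale * (grid - self._grid_mean) / self._grid_sd)
        else:
            raise ConfigurationError(f"unknown diabetes map strategy {self.strategy!r}")

    def _uncalibrated(self, bmi: np.ndarray) -> np.ndarray:
        lo, hi = self.reference_bmi_range
        b = np.clip(np.asarray(bmi, dtype=float), lo, hi)
        if self.strategy == "anchored_spline":
            return np.clip(self._interp(b), 0.0, 1.0)
        # ecdf: fraction of the reference grid strictly below the scaled
        # z-score, normalized so the range endpoints map to exactly 0 and 1
        z = self.scale * (b - self._grid_mean) / self._grid_sd
        ranks = np.searchsorted(self._grid_sorted, z, side="left")
        return ranks / (self._grid_sorted.size - 1)

    def __call__(self, bmi: np.ndarray | float) -> np.ndarray:
        """Evaluate the (calibrated) lifetime T2DM probability at ``bmi``."""
        p = self._uncalibrated(np.atleast_1d(np.asarray(bmi, dtype=float)))
        if self.calibration_scalar != 0.0:
            p = _shift_logodds(p, self.calibration_scalar)
        return p if np.ndim(bmi) else float(p[0])


def build_diabetes_map(config: SimulationConfig) -> DiabetesRiskMap:
    """Construct the (uncalibrated) diabetes risk map from the configuration."""
    return DiabetesRiskMap(
        strategy=config.diabetes_map_strategy,
        reference_bmi_range=config.diabetes_ref_bmi_range,
        scale=config.diabetes_scale,
        anchors=config.diabetes_anchors
        if config.diabetes_map_strategy == "anchored_spline"
        else None,
    )


def calibrate_diabetes_map(
    risk_map: DiabetesRiskMap,
    eligible_untreated_bmis: np.ndarray,
    target_mean: float,
    tol: float = 1e-9,
) -> DiabetesRiskMap:
    """Shift the map on the log-odds scale to hit a target cohort mean risk.

    Finds the additive log-odds constant ``c`` such that the mean of the
    shifted map over the supplied baseline BMIs equals ``target_mean``.
    The shift is monotone in ``c`` and preserves the map's monotonicity
    in BMI, so the root is unique when reachable.
    """
    if not 0.0 < target_mean < 1.0:
        raise CalibrationError("target_mean must lie strictly inside (0, 1)")
    bmis = np.asarray(eligible_untreated_bmis, dtype=float)
    if bmis.size == 0:
        raise CalibrationError("cannot calibrate against an empty cohort")
    base = risk_map._uncalibrated(bmis)
    existing = risk_map.calibration_scalar

    def gap(c: float) -> float:
        return float(_shift_logodds(base, existing + c).mean() - target_mean)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"target mean {target_mean} unreachable by a log-odds shift"
        )
    c = brentq(gap, lo, hi, xtol=tol)
    return DiabetesRiskMap(
        strategy=risk_map.strategy,
        reference_bmi_range=risk_map.reference_bmi_range,
        scale=risk_map.scale,
        anchors=risk_map.anchors,
        calibration_scalar=existing + c,
    )


def evaluate_diabetes_risk(risk_map: DiabetesRiskMap, bmi: np.ndarray | float):
    """Functional alias for ``risk_map(bmi)``."""
    return risk_map(bmi)


@dataclass
class AdverseEventModel:
    """Logistic adverse-event risk in standardized baseline weight (or BMI) and sex."""

    covariate: str  # "weight" or "bmi"
    weight_coef: float
    male_coef: float
    intercept: float
    covariate_mean: float
    covariate_sd: float

    def _covariate_values(self, eligible: pd.DataFrame) -> np.ndarray:
        col = "weight_kg" if self.covariate == "weight" else "bmi"
        return eligible[col].to_numpy(dtype=float)

    def __call__(
        self, covariate_value: np.ndarray | float, is_male: np.ndarray | bool
    ) -> np.ndarray | float:
        z = (np.asarray(covariate_value, dtype=float) - self.covariate_mean)
        if self.covariate_sd > 0:
            z = z / self.covariate_sd
        eta = self.intercept + self.weight_coef * z + self.male_coef * np.asarray(
            is_male, dtype=float
        )
        return expit(eta)

    def predict(self, eligible: pd.DataFrame) -> np.ndarray:
        return np.asarray(
            self(self._covariate_values(eligible), eligible["is_male"].to_numpy())
        )


def fit_adverse_event_model(
    eligible: pd.DataFrame, config: SimulationConfig
) -> AdverseEventModel:
    """Calibrate the AE intercept so the eligible-cohort mean matches target."""
    col = "weight_kg" if config.ae_covariate == "weight" else "bmi"
    x = eligible[col].to_numpy(dtype=float)
    if x.size == 0:
        raise CalibrationError("cannot calibrate against an empty cohort")
    mean, sd = float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0
    model = AdverseEventModel(
        covariate=config.ae_covariate,
        weight_coef=config.ae_weight_coef,
        male_coef=config.ae_male_coef,
        intercept=0.0,
        covariate_mean=mean,
        covariate_sd=sd,
    )
    male = eligible["is_male"].to_numpy()

    def gap(b0: float) -> float:
        model.intercept = b0
        return float(np.mean(model(x, male)) - config.ae_target_mean)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"AE target mean {config.ae_target_mean} unreachable by intercept shift"
        )
    model.intercept = brentq(gap, lo, hi, xtol=1e-12)
    return model


def adverse_event_probability(
    weight_kg: np.ndarray | float,
    is_male: np.ndarray | bool,
    model: AdverseEventModel,
) -> np.ndarray | float:
    """Per-subject adverse-event probability under a fitted model."""
    if np.any(np.asarray(weight_kg, dtype=float) <= 0):
        raise ValueError("weights must be positive")
    return model(weight_kg, is_male)


def build_risk_profiles(
    eligible: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, DiabetesRiskMap, AdverseEventModel]:
    """Build calibrated risk maps and the per-subject risk table.

    Returns the risk table (``subject_id, p_t2dm_untreated,
    p_t2dm_treated, p_adverse_event``) together with the calibrated
    diabetes map and AE model used to produce it.
    """
    merged = eligible.merge(outcomes, left_on="id", right_on="subject_id", how="inner")
    if len(merged) != len(eligible):
        raise ValueError("eligible cohort and outcomes do not align on subject_id")
    dmap = calibrate_diabetes_map(
        build_diabetes_map(config),
        merged["bmi"].to_numpy(),
        config.diabetes_target_eligible_mean,
    )
    ae_model = fit_adverse_event_model(merged, config)
    risks = pd.DataFrame(
        {
            "subject_id": merged["subject_id"].to_numpy(),
            "p_t2dm_untreated": dmap(merged["bmi"].to_numpy()),
            "p_t2dm_treated": dmap(merged["post_bmi"].to_numpy()),
            "p_adverse_event": ae_model.predict(merged),
        }
    )
    return risks, dmap, ae_model


def write_risks(risks: pd.DataFrame, path: str | Path) -> None:
    risks[RISK_COLUMNS].to_csv(path, index=False)


def read_risks(path: str | Path) -> pd.DataFrame:
    risks = pd.read_csv(path)
    missing = set(RISK_COLUMNS) - set(risks.columns)
    if missing:
        raise ValueError(f"risk file {path} is missing columns {sorted(missing)}")
    return risks[RISK_COLUMNS]
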