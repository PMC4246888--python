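"""Simulation configuration: every tunable parameter with its default.

The defaults describe a US-adult anthropometric population (female height
160.6 ± 6.2 cm, log-weight 4.2 ± 0.19 log(kg), covariance 0.59 between
height and log-weight, additive male offsets of +13 cm and +9.4 kg), a
typical gastric-bypass weight-loss distribution (PEWL 63 ± 23 % of excess
weight), a genomic predictor of PEWL with correlation 0.316 to the actual
outcome, and a budget of 1000 surgeries ($20M at $20k per procedure).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value or file is invalid."""


class CalibrationError(RuntimeError):
    """Raised when a risk-model calibration target cannot be reached."""


#: Lifetime diabetes-risk anchors: (BMI, probability of ever developing
#: T2DM) at BMI-category midpoints, sex-averaged adult lifetime risks in
#: the spirit of published dose-response estimates; the last anchor is a
#: monotone extension so the map covers the reference BMI range.
DEFAULT_DIABETES_ANCHORS: tuple[tuple[float, float], ...] = (
    (17.0, 0.10),
    (21.75, 0.185),
    (27.5, 0.325),
    (32.5, 0.56),
    (42.5, 0.72),
    (55.0, 0.78),
)


@dataclass
class SimulationConfig:
    """All numeric parameters of the cohort simulation and decision analysis.

    Units are stated per field. Defaults reproduce the reference study
    conditions; any field may be overridden from a flat YAML/JSON file via
    :func:`load_config`.
    """

    # population
    n_population: int = 150_000
    height_mean_f: float = 160.6          # cm, female
    height_sd_f: float = 6.2              # cm
    logweight_mean_f: float = 4.2         # log(kg), female
    logweight_sd_f: float = 0.19          # log(kg)
    height_logweight_cov: float = 0.59    # cm * log(kg)
    cov_is_correlation: bool = False      # reinterpret the 0.59 as a correlation
    male_height_offset: float = 13.0      # cm
    male_weight_offset: float = 9.4       # kg
    male_fraction_cutoff: float = 0.5     # uniform draw above this -> male
    weight_max: float = 180.0             # kg, outlier filter
    weight_min: float = 38.0              # kg
    height_min: float = 145.0             # cm
    bmi_eligibility: float = 35.0         # kg/m^2, inclusive surgery cutoff
    ideal_bmi: float = 25.0               # kg/m^2

    # surgery outcomes
    pewl_mean: float = 63.0               # % of excess weight
    pewl_sd: float = 23.0                 # %
    pewl_weight_assoc: float = 0.59       # association magnitude with weight
    pewl_weight_assoc_sign: int = -1      # heavier patients lose a smaller %
    pewl_residual_mode: str = "exact"     # "exact": sqrt(1-a^2); "literal": 0.85
    pewl_residual_coef_literal: float = 0.85
    predictor_mean: float = 63.0          # %
    predictor_sd: float = 7.6             # %
    predictor_pewl_corr: float = 0.316    # r, i.e. R^2 = 0.1

    # risk models
    diabetes_map_strategy: str = "anchored_spline"  # or "ecdf"
    diabetes_scale: float = 0.8
    diabetes_ref_bmi_range: tuple[float, float] = (20.0, 55.0)
    diabetes_anchors: tuple[tuple[float, float], ...] = DEFAULT_DIABETES_ANCHORS
    diabetes_target_eligible_mean: float = 0.28   # calibration target
    ae_covariate: str = "weight"          # or "bmi"
    ae_weight_coef: float = 0.5           # log-odds per SD of baseline covariate
    ae_male_coef: float = 0.3             # log-odds for male sex
    ae_target_mean: float = 0.049         # calibration target

    # decision analysis
    n_surgeries: int = 1000
    budget_usd: float = 20_000_000.0
    tau_min: float = 55.0                 # % predicted PEWL
    tau_max: float = 80.0
    tau_step: float = 1.0
    comparator: str = "random_allocation"  # or "untreated_baseline"
    eq1_weighted: bool = False            # population-size-weighted Eq.(1) variant

    rng_seed: int = 2014

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        if self.n_population <= 0:
            raise ConfigurationError("n_population must be positive")
        for name in ("height_sd_f", "logweight_sd_f", "pewl_sd", "predictor_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for name in (
            "male_fraction_cutoff",
            "diabetes_target_eligible_mean",
            "ae_target_mean",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.tau_min > self.tau_max:
            raise ConfigurationError("tau_min must not exceed tau_max")
        if self.tau_step <= 0:
            raise ConfigurationError("tau_step must be positive")
        if self.n_surgeries <= 0:
            raise ConfigurationError("n_surgeries must be positive")
        if abs(self.predictor_pewl_corr) > 1:
            raise ConfigurationError("predictor_pewl_corr must lie in [-1, 1]")
        if not 0 <= self.pewl_weight_assoc <= 1:
            raise ConfigurationError("pewl_weight_assoc must lie in [0, 1]")
        if self.pewl_weight_assoc_sign not in (-1, 1):
            raise ConfigurationError("pewl_weight_assoc_sign must be +1 or -1")
        if self.pewl_residual_mode not in ("exact", "literal"):
            raise ConfigurationError("pewl_residual_mode must be 'exact' or 'literal'")
        if self.diabetes_map_strategy not in ("anchored_spline", "ecdf"):
            raise ConfigurationError(
                "diabetes_map_strategy must be 'anchored_spline' or 'ecdf'"
            )
        if self.ae_covariate not in ("weight", "bmi"):
            raise ConfigurationError("ae_covariate must be 'weight' or 'bmi'")
        if self.comparator not in ("random_allocation", "untreated_baseline"):
            raise ConfigurationError(
                "comparator must be 'random_allocation' or 'untreated_baseline'"
            )
        lo, hi = self.diabetes_ref_bmi_range
        if not lo < hi:
            raise ConfigurationError("diabetes_ref_bmi_range must be increasing")
        anchors = np.asarray(self.diabetes_anchors, dtype=float)
        if anchors.ndim != 2 or anchors.shape[1] != 2:
            raise ConfigurationError("diabetes_anchors must be (bmi, probability) pairs")
        if np.any(np.diff(anchors[:, 0]) <= 0) or np.any(np.diff(anchors[:, 1]) <= 0):
            raise ConfigurationError(
                "diabetes_anchors must be strictly increasing in BMI and probability"
            )
        if np.any((anchors[:, 1] < 0) | (anchors[:, 1] > 1)):
            raise ConfigurationError("diabetes_anchors probabilities outside [0, 1]")
        # covariance matrix must be positive semidefinite
        cov = self.height_logweight_covariance()
        sd_h, sd_w = self.height_sd_f, self.logweight_sd_f
        if abs(cov) > sd_h * sd_w + 1e-12:
            raise ConfigurationError(
                f"|height_logweight_cov|={abs(cov)} exceeds the product of the "
                f"marginal SDs ({sd_h * sd_w}); covariance matrix is invalid"
            )

    # -- derived quantities ---------------------------------------------

    def height_logweight_covariance(self) -> float:
        """Covariance (cm·log(kg)) between height and log-weight.

        The headline value 0.59 is ambiguous between a covariance and a
        correlation; it is treated as a covariance by default, with
        ``cov_is_correlation=True`` selecting the other reading.
        """
        if self.cov_is_correlation:
            return self.height_logweight_cov * self.height_sd_f * self.logweight_sd_f
        return self.height_logweight_cov

    def covariance_matrix(self) -> np.ndarray:
        c = self.height_logweight_covariance()
        return np.array(
            [[self.height_sd_f**2, c], [c, self.logweight_sd_f**2]], dtype=float
        )

    def pewl_residual_coef(self) -> float:
        """Residual mixing coefficient for the PEWL-weight construction.

        ``exact`` mode uses sqrt(1 - a^2) so the target association is the
        population correlation of the mixture; ``literal`` mode uses the
        fixed historical coefficient 0.85 (implied correlation ~0.570 for
        a = 0.59).
        """
        if self.pewl_residual_mode == "literal":
            return self.pewl_residual_coef_literal
        return math.sqrt(max(0.0, 1.0 - self.pewl_weight_assoc**2))

    def tau_grid(self) -> np.ndarray:
        n = int(round((self.tau_max - self.tau_min) / self.tau_step)) + 1
        return self.tau_min + self.tau_step * np.arange(n)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["diabetes_ref_bmi_range"] = list(self.diabetes_ref_bmi_range)
        d["diabetes_anchors"] = [list(a) for a in self.diabetes_anchors]
        return d


def _coerce(raw: dict) -> dict:
    out = dict(raw)
    if "diabetes_ref_bmi_range" in out:
        rng = out["diabetes_ref_bmi_range"]
        if not (isinstance(rng, Sequence) and len(rng) == 2):
            raise ConfigurationError("diabetes_ref_bmi_range must be a [lo, hi] pair")
        out["diabetes_ref_bmi_range"] = (float(rng[0]), float(rng[1]))
    if "diabetes_anchors" in out:
        out["diabetes_anchors"] = tuple(
            (float(a[0]), float(a[1])) for a in out["diabetes_anchors"]
        )
    return out


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a flat YAML or JSON file.

    Keys are the field names of :class:`SimulationConfig`; unknown keys
    are an error, missing keys take their defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping of parameters")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"{path}: unknown configuration keys: {unknown}")
    try:
        return SimulationConfig(**_coerce(raw))
    except TypeError as exc:  # wrong value type
        raise ConfigurationError(f"{path}: {exc}") from exc
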