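"""Decision-threshold analysis: case probabilities, allocation, cases prevented.

The predictor-guided policy treats subjects whose predicted PEWL exceeds
a decision threshold tau, ranked from highest to lowest prediction and
capped at the number of surgeries the budget affords. Two summary
quantities are computed per threshold:

* the population case probability ``P(C)|tau`` — the unweighted average
  of the treated-group mean case probability and the untreated-group
  mean case probability, exactly as the source formula is printed (a
  population-size-weighted variant is available via ``weighted=True``);

* the additional cases prevented ``N|tau`` by using the predictor to
  allocate the fixed surgical capacity, against either of two
  comparators: ``random_allocation`` (the same capacity allocated first
  come, first serve, i.e. without the test) or ``untreated_baseline``
  (nobody treated).

Subjects with a prediction exactly equal to tau fall on the untreated
side; with a continuous predictor this is a measure-zero convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from pewlsim.config import SimulationConfig

SWEEP_COLUMNS = [
    "tau",
    "n_treated",
    "n_untreated",
    "p_case_t2dm",
    "p_case_ae",
    "n_prevented_t2dm_untreated_baseline",
    "n_prevented_t2dm_random_allocation",
    "n_prevented_ae_untreated_baseline",
    "n_prevented_ae_random_allocation",
]

CURVE_COLUMNS = ["predicted_pewl", "p_t2dm_treated", "p_t2dm_untreated"]

COMPARATORS = ("untreated_baseline", "random_allocation")


def _case_columns(outcome: str) -> tuple[str, str]:
    """Treated/untreated probability columns for a given outcome."""
    if outcome == "t2dm":
        return "p_t2dm_treated", "p_t2dm_untreated"
    if outcome == "ae":
        # adverse events only occur with surgery: untreated risk is zero
        return "p_adverse_event", "_zero"
    raise ValueError(f"unknown outcome {outcome!r}; expected 't2dm' or 'ae'")


def _aligned(risks: pd.DataFrame, predictions: pd.DataFrame) -> pd.DataFrame:
    merged = risks.merge(
        predictions[["subject_id", "predicted_pewl"]], on="subject_id", how="inner"
    )
    if len(merged) != len(risks):
        raise ValueError("risks and predictions do not align on subject_id")
    merged["_zero"] = 0.0
    return merged


def population_case_probability(
    risks: pd.DataFrame,
    predictions: pd.DataFrame,
    tau: float,
    outcome: str = "t2dm",
    weighted: bool = False,
) -> float:
    """Population case probability ``P(C)|tau`` for one outcome.

    With ``weighted=False`` (the printed form) the result is the plain
    average of the two group means; when one group is empty the mean of
    the nonempty group is returned, since halving a single group mean
    would introduce a spurious discontinuity at the extreme thresholds.
    """
    data = _aligned(risks, predictions)
    if data.empty:
        raise ValueError("no eligible subjects")
    col_t, col_u = _case_columns(outcome)
    treated = data["predicted_pewl"] > tau
    p_t = data.loc[treated, col_t].to_numpy()
    p_u = data.loc[~treated, col_u].to_numpy()
    if weighted:
        return float((p_t.sum() + p_u.sum()) / len(data))
    if p_t.size == 0:
        return float(p_u.mean())
    if p_u.size == 0:
        return float(p_t.mean())
    return float((p_t.mean() + p_u.mean()) / 2.0)


def allocate_surgeries(
    predictions: pd.DataFrame, tau: float, n_surgeries: int
) -> np.ndarray:
    """Subject ids allocated surgery at threshold ``tau``.

    Candidates are the subjects with predicted PEWL strictly above tau,
    ranked by prediction descending and truncated to the surgical
    capacity; ties in the prediction break by ascending subject id so
    the allocation is deterministic.
    """
    if n_surgeries <= 0:
        raise ValueError("n_surgeries must be positive")
    above = predictions.loc[predictions["predicted_pewl"] > tau]
    ranked = above.sort_values(
        ["predicted_pewl", "subject_id"], ascending=[False, True], kind="mergesort"
    )
    return ranked["subject_id"].to_numpy()[:n_surgeries]


def cases_prevented(
    risks: pd.DataFrame,
    predictions: pd.DataFrame,
    tau: float,
    config: SimulationConfig,
    outcome: str = "t2dm",
    comparator: str = "random_allocation",
) -> float:
    """Additional cases prevented ``N|tau`` by predictor-guided allocation.

    ``random_allocation`` compares against spending the same capacity
    first come, first serve (every eligible subject equally likely to be
    treated), so N = S * (mean treated-risk over the cohort - mean
    treated-risk over the selected set). ``untreated_baseline`` compares
    against treating nobody, the literal printed formula: N = S * (mean
    untreated-risk over the cohort - mean treated-risk over the selected
    set). S is the surgical capacity.
    """
    if comparator not in COMPARATORS:
        raise ValueError(f"comparator must be one of {COMPARATORS}")
    data = _aligned(risks, predictions)
    treated_ids = allocate_surgeries(data, tau, config.n_surgeries)
    if treated_ids.size == 0:
        raise ValueError(f"no subjects allocated at tau={tau}; N is undefined")
    col_t, col_u = _case_columns(outcome)
    selected = data.set_index("subject_id").loc[treated_ids]
    s = config.n_surgeries
    if comparator == "untreated_baseline":
        baseline = data[col_u].mean()
    else:
        baseline = data[col_t].mean()
    return float(s * (baseline - selected[col_t].mean()))


def threshold_sweep(
    risks: pd.DataFrame,
    predictions: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Evaluate both outcome equations on the configured threshold grid.

    Returns one row per tau with the allocated/unallocated counts, the
    population case probabilities for T2DM and adverse events, and the
    cases prevented under both comparators. Thresholds where no subject
    is allocated carry NaN in the prevented-cases columns.
    """
    data = _aligned(risks, predictions)
    n = len(data)
    rows = []
    for tau in config.tau_grid():
        n_treated = int(allocate_surgeries(data, tau, config.n_surgeries).size)
        row = {
            "tau": float(tau),
            "n_treated": n_treated,
            "n_untreated": n - n_treated,
            "p_case_t2dm": population_case_probability(
                risks, predictions, tau, "t2dm", weighted=config.eq1_weighted
            ),
            "p_case_ae": population_case_probability(
                risks, predictions, tau, "ae", weighted=config.eq1_weighted
            ),
        }
        for outcome in ("t2dm", "ae"):
            for comparator in COMPARATORS:
                key = f"n_prevented_{outcome}_{comparator}"
                try:
                    row[key] = cases_prevented(
                        risks, predictions, tau, config, outcome, comparator
                    )
                except ValueError:
                    row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


# -- conditional risk curves (individual decision support) ---------------


def _spline_basis(x: np.ndarray, knots_x: np.ndarray, df: int, degree: int = 3):
    """B-spline design matrix with ``df`` basis functions, knots at quantiles."""
    n_interior = max(df - degree - 1, 0)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(knots_x, qs)
    else:
        interior = np.array([])
    lo = knots_x.min() - 1e-9
    hi = knots_x.max() + 1e-9
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    return BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()


def _gcv_fit(x: np.ndarray, y: np.ndarray, grid: np.ndarray, df_candidates):
    """OLS on a B-spline basis, degrees of freedom chosen by GCV."""
    best = None
    for df in df_candidates:
        basis = _spline_basis(x, x, df)
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        rss = float(np.sum((y - basis @ coef) ** 2))
        k = basis.shape[1]
        n = x.size
        gcv = (rss / n) / (1.0 - k / n) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, df, coef)
    _, df, coef = best
    return _spline_basis(grid, x, df) @ coef


def conditional_risk_curves(
    risks: pd.DataFrame,
    predictions: pd.DataFrame,
    grid: np.ndarray,
    df_candidates=(4, 5, 6, 7, 8),
) -> pd.DataFrame:
    """Smooth conditional T2DM risk, with and without surgery, vs. the predictor.

    Fits a low-degrees-of-freedom regression spline (degrees of freedom
    chosen by generalized cross-validation) of each per-subject risk on
    the predicted PEWL and evaluates it on ``grid``. These are the
    individual decision-support curves: what a patient with a given
    genomic prediction can expect their lifetime diabetes probability to
    be with and without surgery.
    """
    data = _aligned(risks, predictions)
    if len(data) < 10:
        raise ValueError("need at least 10 subjects to fit conditional curves")
    alpha = data["predicted_pewl"].to_numpy()
    grid = np.asarray(grid, dtype=float)
    if grid.min() < alpha.min() or grid.max() > alpha.max():
        raise ValueError("grid extends outside the observed predictor range")
    curves = {"predicted_pewl": grid}
    for col, out in (
        ("p_t2dm_treated", "p_t2dm_treated"),
        ("p_t2dm_untreated", "p_t2dm_untreated"),
    ):
        fit = _gcv_fit(alpha, data[col].to_numpy(), grid, df_candidates)
        curves[out] = np.clip(fit, 0.0, 1.0)
    return pd.DataFrame(curves, columns=CURVE_COLUMNS)


def write_sweep(sweep: pd.DataFrame, path: str | Path) -> None:
    sweep[SWEEP_COLUMNS].to_csv(path, index=False)


def read_sweep(path: str | Path) -> pd.DataFrame:
    sweep = pd.read_csv(path)
    missing = set(SWEEP_COLUMNS) - set(sweep.columns)
    if missing:
        raise ValueError(f"sweep file {path} is missing columns {sorted(missing)}")
    return sweep[SWEEP_COLUMNS]


def write_curves(curves: pd.DataFrame, path: str | Path) -> None:
    curves[CURVE_COLUMNS].to_csv(path, index=False)
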