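"""Baseline association models: clinical score ~ TPF + covariates.

Ordinary least squares of a clinical score on the thin-patch fraction with
age, sex, handedness, and symptom duration as confounders; models with a
restricted (domain-specific) vs. unrestricted (whole-brain) TPF are
compared by adjusted R².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: the 14 lateralized extremity sub-items of the MDS-UPDRS III motor exam:
#: rigidity of the four extremities (3.3, neck excluded), finger tapping
#: (3.4), hand movements (3.5), pronation-supination (3.6), toe tapping
#: (3.7), and leg agility (3.8), each rated 0-4 per side.
EXTREMITY_SUBITEMS: tuple[str, ...] = (
    "3.3_RUE", "3.3_LUE", "3.3_RLE", "3.3_LLE",
    "3.4_R", "3.4_L",
    "3.5_R", "3.5_L",
    "3.6_R", "3.6_L",
    "3.7_R", "3.7_L",
    "3.8_R", "3.8_L",
)

#: maximum attainable extremity subscore (14 sub-items x 4)
EXTREMITY_SUBSCORE_MAX = 4 * len(EXTREMITY_SUBITEMS)

COVARIATE_COLUMNS = ("age", "sex", "handedness", "symptom_duration")


class MissingItemError(ValueError):
    """A required MDS-UPDRS III sub-item is absent (no imputation is done)."""


class FitError(ValueError):
    """Raised for rank-deficient or otherwise unfittable designs."""


def extremity_subscore(item_scores: Mapping[str, int]) -> int:
    """Composite extremity motor subscore: sum of the 14 lateralized sub-items.

    Raises
    ------
    MissingItemError
        If any required sub-item is absent.
    ValueError
        If a sub-item score falls outside [0, 4].
    """
    total = 0
    for item in EXTREMITY_SUBITEMS:
        if item not in item_scores:
            raise MissingItemError(f"missing MDS-UPDRS III sub-item {item!r}")
        score = int(item_scores[item])
        if not 0 <= score <= 4:
            raise ValueError(f"sub-item {item!r} score {score} outside [0, 4]")
        total += score
    return total


@dataclass(frozen=True)
class GlmFit:
    """Summary of one OLS fit of a clinical score on TPF plus covariates."""

    outcome_name: str
    predictor_name: str
    n: int
    coefficients: dict[str, float]
    tpf_coefficient: float
    tpf_p_value: float
    r2: float
    r2_adjusted: float

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "predictor": self.predictor_name,
            "n": self.n,
            "coefficients": self.coefficients,
            "tpf_coefficient": self.tpf_coefficient,
            "tpf_p_value": self.tpf_p_value,
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
        }


def build_design(tpf: np.ndarray, covariates: pd.DataFrame | None,
                 predictor_name: str = "tpf") -> pd.DataFrame:
    """Design matrix: intercept, TPF, and dummy-coded covariates.

    Sex is one dummy (female = 1, male reference); handedness two dummies
    (L and A vs. the R reference) — a level absent from the data contributes
    no column.  Zero-variance or collinear columns raise :class:`FitError`
    naming the offending column.
    """
    n = len(tpf)
    design = pd.DataFrame({predictor_name: np.asarray(tpf, dtype=float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        if len(cov) != n:
            raise FitError("covariate table length differs from TPF vector")
        if "age" in cov:
            design["age"] = cov["age"].astype(float)
        if "sex" in cov:
            design["sex_F"] = (cov["sex"].astype(str) == "F").astype(float)
        if "handedness" in cov:
            hand = cov["handedness"].astype(str)
            for level in ("L", "A"):
                if (hand == level).any():
                    design[f"hand_{level}"] = (hand == level).astype(float)
        if "symptom_duration" in cov:
            design["symptom_duration"] = cov["symptom_duration"].astype(float)
    for col in design.columns:
        if np.ptp(design[col].to_numpy()) == 0:
            raise FitError(f"column {col!r} has zero variance (collinear with the intercept)")
    design = sm.add_constant(design, prepend=True)
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # find a column whose removal restores full rank
        for j, col in enumerate(design.columns):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                raise FitError(f"design is rank deficient; column {col!r} is collinear")
        raise FitError("design is rank deficient")
    return design


def fit_tpf_model(outcome: np.ndarray, tpf: np.ndarray,
                  covariates: pd.DataFrame | None = None,
                  outcome_name: str = "outcome",
                  predictor_name: str = "tpf") -> GlmFit:
    """OLS of a clinical score on TPF with demographic confounders.

    The TPF p-value is the two-sided t-test on the TPF coefficient;
    adjusted R² uses the fitted design's actual regressor count.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(tpf, dtype=float)
    if y.size != x.size:
        raise FitError("outcome and TPF vectors differ in length")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise FitError("non-finite values in outcome or TPF")
    design = build_design(x, covariates, predictor_name=predictor_name)
    if y.size <= design.shape[1]:
        raise FitError(f"n={y.size} too small for {design.shape[1]} parameters")
    res = sm.OLS(y, design).fit()
    return GlmFit(
        outcome_name=outcome_name,
        predictor_name=predictor_name,
        n=int(y.size),
        coefficients={name: float(val) for name, val in res.params.items()},
        tpf_coefficient=float(res.params[predictor_name]),
        tpf_p_value=float(res.pvalues[predictor_name]),
        r2=float(res.rsquared),
        r2_adjusted=float(res.rsquared_adj),
    )


@dataclass(frozen=True)
class ModelComparison:
    """Adjusted-R² comparison of a restricted vs. an unrestricted TPF model."""

    outcome_name: str
    winner: str                    # "restricted", "unrestricted", or "tie"
    restricted_r2_adjusted: float
    unrestricted_r2_adjusted: float
    restricted_tpf_p: float
    unrestricted_tpf_p: float
    alpha: float = 0.05

    @property
    def restricted_significant(self) -> bool:
        return self.restricted_tpf_p < self.alpha

    @property
    def unrestricted_significant(self) -> bool:
        return self.unrestricted_tpf_p < self.alpha

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "winner": self.winner,
            "restricted_r2_adjusted": self.restricted_r2_adjusted,
            "unrestricted_r2_adjusted": self.unrestricted_r2_adjusted,
            "restricted_tpf_p": self.restricted_tpf_p,
            "unrestricted_tpf_p": self.unrestricted_tpf_p,
            "restricted_significant": self.restricted_significant,
            "unrestricted_significant": self.unrestricted_significant,
        }


def compare_by_adjusted_r2(fit_restricted: GlmFit, fit_unrestricted: GlmFit,
                           alpha: float = 0.05) -> ModelComparison:
    """Declare the model with the higher adjusted R² the winner."""
    if fit_restricted.outcome_name != fit_unrestricted.outcome_name:
        raise ValueError("model comparison requires the same outcome")
    if fit_restricted.n != fit_unrestricted.n:
        raise ValueError("model comparison requires the same n")
    a, b = fit_restricted.r2_adjusted, fit_unrestricted.r2_adjusted
    winner = "tie" if a == b else ("restricted" if a > b else "unrestricted")
    return ModelComparison(
        outcome_name=fit_restricted.outcome_name,
        winner=winner,
        restricted_r2_adjusted=a,
        unrestricted_r2_adjusted=b,
        restricted_tpf_p=fit_restricted.tpf_p_value,
        unrestricted_tpf_p=fit_unrestricted.tpf_p_value,
        alpha=alpha,
    )
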