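"""Stabilized inverse-probability weights for exposure and mediator.

The marginal structural model is fitted on a pseudo-population in which
maternal education (exposure A) is unconfounded by ethnicity (baseline C) and
daily energy intake (mediator M) is unconfounded by the intermediate
confounders L. Each child receives

    exposure weight  sw_A = P(A = a_i) / P(A = a_i | C_i)
    mediator weight  sw_M = f(M_i | A_i) / f(M_i | A_i, C_i, L_i)

with the exposure denominator from a 3-category multinomial logistic model and
the mediator densities normal on the log-kcal scale (two linear regressions of
log intake with maximum-likelihood residual variances). The combined weight is
their product, truncated at the empirical 1st and 99th percentiles.

Stabilized weights average ~1 under correct specification; the diagnostics on
:class:`WeightSet` make gross misspecification visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .cohort import EDUCATION_LEVELS

__all__ = [
    "WeightSet",
    "ExposureWeightModel",
    "MediatorWeightModel",
    "fit_exposure_weights",
    "fit_mediator_weights",
    "truncate_weights",
    "combine_weights",
    "build_weight_set",
]


class WeightFittingError(RuntimeError):
    """A weight model failed to converge or produced degenerate estimates."""


MEDIATOR_CONFOUNDERS = ["ethnicity", "birthweight_cat", "health", "activity_cat", "tv_cat"]


def _require_complete(cohort: pd.DataFrame, columns: list[str], context: str) -> None:
    for col in columns:
        if cohort[col].isna().any():
            raise ValueError(f"{context} requires complete {col!r} (impute upstream)")


class ExposureWeightModel(BaseEstimator):
    """Stabilized IPW for a 3-level exposure given the baseline confounder.

    Parameters
    ----------
    stabilized : bool
        Use the marginal exposure distribution as numerator (default); if
        False the numerator is 1 (conventional IPW).
    """

    def __init__(self, stabilized: bool = True):
        self.stabilized = stabilized

    def fit(self, cohort: pd.DataFrame, y=None) -> "ExposureWeightModel":
        _require_complete(cohort, ["education", "ethnicity"], "exposure weights")
        codes = pd.Categorical(cohort["education"], categories=EDUCATION_LEVELS).codes
        X = sm.add_constant(
            (cohort["ethnicity"] == "non-white").to_numpy(dtype=float), has_constant="add"
        )
        try:
            res = sm.MNLogit(codes, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # noqa: BLE001 - surface as a fitting error
            raise WeightFittingError(f"multinomial exposure model failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise WeightFittingError("multinomial exposure model did not converge")
        probs = res.predict(X)  # n x 3, columns in code order
        denom = probs[np.arange(len(codes)), codes]
        if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
            raise WeightFittingError("degenerate exposure probabilities (separation?)")
        marginal = np.bincount(codes, minlength=3) / len(codes)
        numer = marginal[codes] if self.stabilized else 1.0
        self.model_result_ = res
        self.marginal_ = marginal
        self.weights_ = numer / denom
        return self

    def transform(self, cohort: pd.DataFrame) -> np.ndarray:
        return self.weights_


class MediatorWeightModel(BaseEstimator):
    """Stabilized density-ratio weight for a continuous mediator.

    Both densities are normal on the log-kcal scale: the numerator mean comes
    from a regression of log intake on exposure (plus sex when
    ``include_sex``), the denominator adds ethnicity and the four intermediate
    confounders. Sex sits in both models by default because child energy
    intake is strongly sex-patterned; being in numerator and denominator it
    does not de-stabilize the weights.
    """

    def __init__(self, include_sex: bool = True):
        self.include_sex = include_sex

    def fit(self, cohort: pd.DataFrame, y=None) -> "MediatorWeightModel":
        needed = ["intake_kcal", "education", *MEDIATOR_CONFOUNDERS]
        _require_complete(cohort, needed, "mediator weights")
        data = cohort.copy()
        data["log_intake"] = np.log(data["intake_kcal"].to_numpy(dtype=float))
        sex_term = " + C(sex)" if self.include_sex else ""
        num_formula = "log_intake ~ C(education)"
        den_formula = "log_intake ~ C(education) + " + " + ".join(
            f"C({c})" for c in MEDIATOR_CONFOUNDERS
        )
        num_res = smf.ols(num_formula + sex_term, data=data).fit()
        den_res = smf.ols(den_formula + sex_term, data=data).fit()
        n = len(data)
        sd_num = float(np.sqrt(num_res.ssr / n))  # MLE variance
        sd_den = float(np.sqrt(den_res.ssr / n))
        if sd_num <= 0 or sd_den <= 0:
            raise WeightFittingError("zero residual variance in mediator model")
        m = data["log_intake"].to_numpy()
        num_pdf = norm.pdf(m, loc=num_res.fittedvalues.to_numpy(), scale=sd_num)
        den_pdf = norm.pdf(m, loc=den_res.fittedvalues.to_numpy(), scale=sd_den)
        if np.any(den_pdf <= 0) or not np.all(np.isfinite(den_pdf)):
            raise WeightFittingError("degenerate mediator density")
        self.numerator_result_ = num_res
        self.denominator_result_ = den_res
        self.residual_sds_ = (sd_num, sd_den)
        self.weights_ = num_pdf / den_pdf
        return self

    def transform(self, cohort: pd.DataFrame) -> np.ndarray:
        return self.weights_


def fit_exposure_weights(cohort: pd.DataFrame) -> np.ndarray:
    """Per-child stabilized exposure weights P(A)/P(A|C)."""
    return ExposureWeightModel().fit(cohort).weights_


def fit_mediator_weights(cohort: pd.DataFrame, include_sex: bool = True) -> np.ndarray:
    """Per-child stabilized mediator density-ratio weights f(M|A)/f(M|A,C,L)."""
    return MediatorWeightModel(include_sex=include_sex).fit(cohort).weights_


def truncate_weights(weights, lower_pct: float = 1.0, upper_pct: float = 99.0) -> np.ndarray:
    """Clip weights at empirical percentiles of the input vector."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("cannot truncate an empty weight vector")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    lo = np.percentile(w, lower_pct)
    hi = np.percentile(w, upper_pct)
    return np.clip(w, lo, hi)


def combine_weights(exposure_w, mediator_w) -> np.ndarray:
    """Elementwise product of the two stabilized weights."""
    a = np.asarray(exposure_w, dtype=float)
    b = np.asarray(mediator_w, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"weight length mismatch: {a.shape} vs {b.shape}")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("weights must be positive")
    return a * b


@dataclass
class WeightSet:
    """Per-child weights with summary diagnostics."""

    exposure: np.ndarray
    mediator: np.ndarray
    combined: np.ndarray
    truncated: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = []
        for name, vec in (
            ("exposure", self.exposure),
            ("mediator", self.mediator),
            ("combined", self.combined),
            ("truncated", self.truncated),
        ):
            rows.append(
                {
                    "weight": name,
                    "mean": float(np.mean(vec)),
                    "min": float(np.min(vec)),
                    "p1": float(np.percentile(vec, 1)),
                    "p99": float(np.percentile(vec, 99)),
                    "max": float(np.max(vec)),
                }
            )
        return pd.DataFrame(rows)


def build_weight_set(
    cohort: pd.DataFrame,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    include_sex: bool = True,
) -> WeightSet:
    """Exposure + mediator weights, combined and truncated, with diagnostics."""
    ew = fit_exposure_weights(cohort)
    mw = fit_mediator_weights(cohort, include_sex=include_sex)
    cw = combine_weights(ew, mw)
    tw = truncate_weights(cw, lower_pct, upper_pct)
    diag = {
        "mean_exposure": float(np.mean(ew)),
        "mean_mediator": float(np.mean(mw)),
        "mean_combined": float(np.mean(cw)),
        "mean_truncated": float(np.mean(tw)),
        "truncation_bounds": (float(np.percentile(cw, lower_pct)), float(np.percentile(cw, upper_pct))),
    }
    return WeightSet(ew, mw, cw, tw, diag)
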