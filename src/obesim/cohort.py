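"""Synthetic cohort generator with a known causal structure.

Emulates a UK birth-cohort analytic sample linking maternal education (a
3-level socioeconomic exposure A), child ethnicity (baseline confounder C),
four intermediate confounders L (birthweight category, general health,
moderate activity, TV time), mean daily energy intake at age 3 (mediator M,
kcal/day) and obesity at 6-7 years (outcome Y). Generation follows the causal
ordering

    C -> A -> L -> M -> Y   with C -> Y and direct A -> Y

so every structural coefficient is known and downstream causal estimators can
be tested for parameter recovery. Intake is log-normal (dietary energy is
right-skewed); sex-specific log-medians default to 1311.5 kcal (boys) and
1273.5 kcal (girls). Obesity at each age is drawn from a logistic model and
the accompanying BMI z-score is drawn from the normal tail consistent with
the obesity flag and the 95th-centile cut-off, so the binary outcome obeys an
exact logit model (the coefficients a weighted logistic analysis should
recover) while the z-score column stays internally consistent.

Default marginals are calibrated to a real mother-offspring survey of ~2000
children: 51.3% boys, education split 9.4/66.4/24.2 (low/mid/high), 96.1%
white, 6.7% obese at 3y and 8.3% obese at 6-7y.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .growth import OBESE_Z

__all__ = [
    "CohortParams",
    "IntakeModel",
    "OutcomeModel",
    "MissingnessSpec",
    "generate_cohort",
    "impose_missingness",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
    "calibrate_intercepts",
    "education_code",
    "COHORT_COLUMNS",
    "EDUCATION_LEVELS",
    "PROTECTED_COLUMNS",
]

EDUCATION_LEVELS = ("low", "mid", "high")
THREE_LEVELS = ("low", "mid", "high")

#: reference kcal at which the intake term of the outcome model is centred
INTAKE_REF_KCAL = 1292.6

COHORT_COLUMNS = [
    "id",
    "sex",
    "ethnicity",
    "education",
    "birthweight_cat",
    "health",
    "activity_cat",
    "tv_cat",
    "imd_score",
    "imd_quintile",
    "intake_kcal",
    "bmi_z_3y",
    "obese_3y",
    "bmi_z_6y",
    "obese_6y",
]

#: exposure and outcome (and the row identifier) may never be masked
PROTECTED_COLUMNS = frozenset({"id", "education", "bmi_z_6y", "obese_6y"})

_CATEGORICAL_LEVELS = {
    "sex": ("male", "female"),
    "ethnicity": ("white", "non-white"),
    "education": EDUCATION_LEVELS,
    "birthweight_cat": THREE_LEVELS,
    "health": ("good", "fair_bad"),
    "activity_cat": THREE_LEVELS,
    "tv_cat": THREE_LEVELS,
}

# Table-2-style marginal targets for the intermediate confounders, used to
# anchor the category intercepts at the population-average education code.
_CONFOUNDER_MARGINALS = {
    "birthweight_cat": (0.131, 0.728, 0.141),
    "health": 0.044,  # fair_bad
    "activity_cat": (0.243, 0.680, 0.077),
    "tv_cat": (0.209, 0.690, 0.101),
}


def education_code(education) -> np.ndarray:
    """Disadvantage coding: high = 0, mid = 1, low = 2.

    Higher codes mean lower maternal education, so positive outcome
    coefficients read as excess risk with disadvantage.
    """
    mapping = {"high": 0.0, "mid": 1.0, "low": 2.0}
    arr = pd.Series(education).map(mapping)
    if arr.isna().any():
        bad = sorted(set(pd.Series(education)[arr.isna()].astype(str)))
        raise ValueError(f"unknown education labels: {bad}")
    return arr.to_numpy(dtype=float)


@dataclass
class IntakeModel:
    """Log-normal model for daily energy intake (kcal) at age 3.

    ``log_median_male/female`` are natural-log medians; ``log_sd`` the log-scale
    SD (a dispersion calibration, not an observed quantity); ``education_effect``
    the log-kcal shift per unit disadvantage code (0 by default: the data this
    generator emulates showed no education-intake association); and
    ``confounder_effects`` log-kcal shifts keyed like the outcome-model
    confounder coefficients.
    """

    log_median_male: float = math.log(1311.5)
    log_median_female: float = math.log(1273.5)
    log_sd: float = 0.24
    education_effect: float = 0.0
    confounder_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class OutcomeModel:
    """Logistic model for obesity: logit p = intercept + education_coef * code
    + intake_coef * (kcal - 1292.6)/100 + ethnicity/confounder shifts."""

    intercept: float
    education_coef: float
    intake_coef: float  # per 100 kcal
    ethnicity_coef: float = 0.0  # non-white vs white
    confounder_coefs: dict[str, float] = field(default_factory=dict)


def _default_outcome_model() -> OutcomeModel:
    # intercept calibrated (see calibrate_intercepts) for 8.3% marginal
    # prevalence at 6-7y under the default generator; education gradient and
    # intake slope sized to give an unadjusted low/high risk ratio near 2.
    return OutcomeModel(
        intercept=-2.9298,
        education_coef=0.39,
        intake_coef=0.10,
        ethnicity_coef=0.2,
        confounder_coefs={
            "birthweight_low": -0.10,
            "birthweight_high": 0.40,
            "health_fair": 0.30,
            "activity_low": 0.15,
            "activity_high": -0.15,
            "tv_low": -0.20,
            "tv_high": 0.20,
        },
    )


def _default_prior_obesity_model() -> OutcomeModel:
    # calibrated for 6.7% obesity at age 3; intake does not enter (BMI and
    # diet are measured contemporaneously at 3y, neither causes the other here)
    return OutcomeModel(
        intercept=-3.0203,
        education_coef=0.25,
        intake_coef=0.0,
        ethnicity_coef=0.1,
        confounder_coefs={"birthweight_high": 0.50, "tv_high": 0.20, "activity_low": 0.20},
    )


@dataclass
class CohortParams:
    """Parameters of the structural model used to generate a cohort."""

    n_children: int = 2001
    seed: int = 0
    male_fraction: float = 0.513
    education_probs: tuple[float, float, float] = (0.094, 0.664, 0.242)
    ethnicity_white_prob: float = 0.961
    #: logit shifts for (low, high) education (vs mid) among non-white children
    ethnicity_education_effect: tuple[float, float] = (0.3, -0.4)
    #: logit shifts per unit disadvantage code for the intermediate confounders
    confounder_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "birthweight_low": 0.20,
            "birthweight_high": 0.00,
            "health_fair": 0.30,
            "activity_low": 0.20,
            "activity_high": -0.10,
            "tv_low": -0.30,
            "tv_high": 0.40,
        }
    )
    intake_model: IntakeModel = field(default_factory=IntakeModel)
    outcome_model: OutcomeModel = field(default_factory=_default_outcome_model)
    prior_obesity_model: OutcomeModel = field(default_factory=_default_prior_obesity_model)

    def validate(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        probs = [self.male_fraction, self.ethnicity_white_prob, *self.education_probs]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.education_probs) - 1.0) > 1e-12:
            raise ValueError("education_probs must sum to 1")
        if self.intake_model.log_sd <= 0:
            raise ValueError("intake log_sd must be positive")

    @property
    def mean_education_code(self) -> float:
        p_low, p_mid, _ = self.education_probs
        return 2.0 * p_low + 1.0 * p_mid

    def replace(self, **kwargs) -> "CohortParams":
        return dataclasses.replace(self, **kwargs)


def recovery_benchmark_params(n_children: int = 20000, seed: int = 0) -> CohortParams:
    """Generator configuration for coefficient-recovery benchmarks.

    Education->confounder links are switched off so the marginal education
    effect equals the direct logit coefficient exactly (with them on, the
    education->confounder->outcome pathway is part of the controlled direct
    effect and the marginal coefficient legitimately exceeds the direct one).
    Exposure confounding (ethnicity) and mediator confounding (confounder
    effects on both intake and outcome) stay on, so the inverse-probability
    weighting is doing real work.
    """
    return CohortParams(
        n_children=n_children,
        seed=seed,
        confounder_coefs={k: 0.0 for k in CohortParams().confounder_coefs},
        ethnicity_white_prob=0.9,
        ethnicity_education_effect=(0.6, -0.6),
        intake_model=IntakeModel(confounder_effects={"tv_high": 0.05, "activity_low": 0.04}),
        outcome_model=OutcomeModel(
            intercept=-2.8,
            education_coef=0.39,
            intake_coef=0.10,
            ethnicity_coef=0.4,
            confounder_coefs={"tv_high": 0.3, "activity_low": 0.2},
        ),
    )


def null_direct_effect_params(n_children: int = 5000, seed: int = 0) -> CohortParams:
    """Generator configuration with a zero direct education effect.

    Confounding remains: ethnicity drives both education and obesity, and the
    intermediate confounders drive both intake and obesity, so an unweighted
    education-obesity association exists but the weighted CDE risk ratio
    should centre on 1. Used for null-calibration (CI coverage) checks.
    """
    return CohortParams(
        n_children=n_children,
        seed=seed,
        ethnicity_white_prob=0.9,
        ethnicity_education_effect=(0.8, -0.8),
        confounder_coefs={k: 0.0 for k in CohortParams().confounder_coefs},
        intake_model=IntakeModel(confounder_effects={"tv_high": 0.05, "activity_low": 0.04}),
        outcome_model=OutcomeModel(
            intercept=-2.6,
            education_coef=0.0,
            intake_coef=0.10,
            ethnicity_coef=0.5,
            confounder_coefs={"tv_high": 0.3, "activity_low": 0.2, "birthweight_high": 0.3},
        ),
    )


@dataclass
class MissingnessSpec:
    """Per-column masking probabilities under MCAR or MAR-on-education.

    Under MAR, the column probability is multiplied by an education-specific
    factor (low, mid, high) and clipped to [0, 1), so attrition can be steeper
    for disadvantaged families as in real cohort follow-up.
    """

    column_probs: dict[str, float]
    mechanism: str = "MCAR"
    education_factors: tuple[float, float, float] = (1.5, 1.0, 0.6)
    seed: int = 0

    def validate(self) -> None:
        if self.mechanism not in ("MCAR", "MAR-on-education"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for col, p in self.column_probs.items():
            if not (0.0 <= p < 1.0):
                raise ValueError(f"missingness probability for {col!r} must be in [0, 1)")
            if col in PROTECTED_COLUMNS:
                raise ValueError(f"column {col!r} (exposure/outcome/id) may not be masked")


def _three_level_probs(marginals, coef_low, coef_high, code, mean_code, extra_low=0.0, extra_high=0.0):
    """Multinomial-logit probabilities for a 3-level confounder.

    Intercepts are anchored so the target marginals hold at the population-
    average education code; ``code`` may be a vector.
    """
    p_low, p_mid, p_high = marginals
    a_low = math.log(p_low / p_mid) - coef_low * mean_code
    a_high = math.log(p_high / p_mid) - coef_high * mean_code
    eta_low = a_low + coef_low * code + extra_low
    eta_high = a_high + coef_high * code + extra_high
    denom = 1.0 + np.exp(eta_low) + np.exp(eta_high)
    return np.exp(eta_low) / denom, 1.0 / denom, np.exp(eta_high) / denom


def _draw_categorical(rng, probs_by_level, levels):
    """Vectorised draw given per-level probability vectors."""
    stacked = np.column_stack(probs_by_level)
    cum = np.cumsum(stacked, axis=1)
    u = rng.random(stacked.shape[0])
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(levels, dtype=object)[idx]


def _confounder_shift(coefs: dict[str, float], frame: pd.DataFrame) -> np.ndarray:
    """Sum of logit/log shifts implied by confounder category indicators."""
    shift = np.zeros(len(frame))
    key_map = {
        "birthweight_low": ("birthweight_cat", "low"),
        "birthweight_high": ("birthweight_cat", "high"),
        "health_fair": ("health", "fair_bad"),
        "activity_low": ("activity_cat", "low"),
        "activity_high": ("activity_cat", "high"),
        "tv_low": ("tv_cat", "low"),
        "tv_high": ("tv_cat", "high"),
    }
    for key, value in coefs.items():
        if key not in key_map:
            raise ValueError(f"unknown confounder coefficient {key!r}")
        col, level = key_map[key]
        shift += value * (frame[col].to_numpy() == level)
    return shift


def _outcome_linear_predictor(model: OutcomeModel, frame: pd.DataFrame, include_intercept=True):
    lp = np.zeros(len(frame))
    if include_intercept:
        lp += model.intercept
    lp += model.education_coef * education_code(frame["education"])
    if model.intake_coef:
        lp += model.intake_coef * (frame["intake_kcal"].to_numpy() - INTAKE_REF_KCAL) / 100.0
    lp += model.ethnicity_coef * (frame["ethnicity"].to_numpy() == "non-white")
    lp += _confounder_shift(model.confounder_coefs, frame)
    return lp


def _zscore_given_status(rng, obese: np.ndarray) -> np.ndarray:
    """BMI z consistent with the obesity flag: the standard-normal tail above
    (obese) or below (not obese) the 95th-centile cut-off."""
    n = obese.size
    z = np.empty(n)
    n_ob = int(obese.sum())
    if n_ob:
        z[obese] = truncnorm.rvs(OBESE_Z, np.inf, size=n_ob, random_state=rng)
    if n - n_ob:
        z[~obese] = truncnorm.rvs(-np.inf, OBESE_Z, size=n - n_ob, random_state=rng)
    return z


def _generate_covariates(params: CohortParams, rng: np.random.Generator) -> pd.DataFrame:
    """Everything upstream of the two obesity draws (C, A, L, IMD, M)."""
    n = params.n_children
    df = pd.DataFrame({"id": np.arange(1, n + 1)})
    df["sex"] = np.where(rng.random(n) < params.male_fraction, "male", "female")
    df["ethnicity"] = np.where(
        rng.random(n) < params.ethnicity_white_prob, "white", "non-white"
    )

    # education | ethnicity: white group hits the target split exactly; the
    # non-white minority is shifted on the (low, high) logits
    p_low, p_mid, p_high = params.education_probs
    nonwhite = (df["ethnicity"] == "non-white").to_numpy()
    s_low, s_high = params.ethnicity_education_effect
    eta_low = math.log(p_low / p_mid) + s_low * nonwhite
    eta_high = math.log(p_high / p_mid) + s_high * nonwhite
    denom = 1.0 + np.exp(eta_low) + np.exp(eta_high)
    df["education"] = _draw_categorical(
        rng,
        (np.exp(eta_low) / denom, 1.0 / denom, np.exp(eta_high) / denom),
        EDUCATION_LEVELS,
    )
    code = education_code(df["education"])
    mean_code = params.mean_education_code
    cc = params.confounder_coefs

    for col in ("birthweight_cat", "activity_cat", "tv_cat"):
        prefix = {"birthweight_cat": "birthweight", "activity_cat": "activity", "tv_cat": "tv"}[col]
        probs = _three_level_probs(
            _CONFOUNDER_MARGINALS[col],
            cc.get(f"{prefix}_low", 0.0),
            cc.get(f"{prefix}_high", 0.0),
            code,
            mean_code,
        )
        df[col] = _draw_categorical(rng, probs, THREE_LEVELS)

    p_fair = _CONFOUNDER_MARGINALS["health"]
    a_fair = math.log(p_fair / (1 - p_fair)) - cc.get("health_fair", 0.0) * mean_code
    df["health"] = np.where(
        rng.random(n) < expit(a_fair + cc.get("health_fair", 0.0) * code),
        "fair_bad",
        "good",
    )

    df["imd_score"] = rng.standard_normal(n)
    # quintile 5 = most deprived (highest score); theoretical N(0,1) cuts
    from scipy.stats import norm as _norm

    cuts = _norm.ppf([0.2, 0.4, 0.6, 0.8])
    df["imd_quintile"] = (np.searchsorted(cuts, df["imd_score"]) + 1).astype(int)

    im = params.intake_model
    log_mu = np.where(df["sex"] == "male", im.log_median_male, im.log_median_female)
    log_mu = log_mu + im.education_effect * code
    if im.confounder_effects:
        log_mu = log_mu + _confounder_shift(im.confounder_effects, df)
    df["intake_kcal"] = np.exp(log_mu + im.log_sd * rng.standard_normal(n))
    return df


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Generate a cohort table; deterministic given ``params.seed``.

    The returned DataFrame carries the generating parameters (including the
    true outcome-model coefficients) in ``df.attrs["params"]`` so estimator
    tests can assert parameter recovery.
    """
    if params is None:
        params = CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    df = _generate_covariates(params, rng)

    lp3 = _outcome_linear_predictor(params.prior_obesity_model, df)
    df["obese_3y"] = rng.random(len(df)) < expit(lp3)
    df["bmi_z_3y"] = _zscore_given_status(rng, df["obese_3y"].to_numpy())

    lp6 = _outcome_linear_predictor(params.outcome_model, df)
    df["obese_6y"] = rng.random(len(df)) < expit(lp6)
    df["bmi_z_6y"] = _zscore_given_status(rng, df["obese_6y"].to_numpy())

    df = df[COHORT_COLUMNS]
    df = df.astype({"obese_3y": "boolean", "obese_6y": "boolean"})
    df.attrs["params"] = _params_to_dict(params)
    validate_cohort(df)
    return df


def calibrate_intercepts(
    params: CohortParams,
    target_3y: float = 0.067,
    target_6y: float = 0.083,
    n: int = 500_000,
    seed: int = 12345,
) -> tuple[float, float]:
    """Solve the obesity-model intercepts so the marginal prevalences hit their
    targets, by root-finding on a large simulated covariate draw."""
    rng = np.random.default_rng(seed)
    big = params.replace(n_children=n)
    df = _generate_covariates(big, rng)

    def solve(model: OutcomeModel, target: float) -> float:
        offset = _outcome_linear_predictor(model, df, include_intercept=False)

        def gap(b0):
            return float(np.mean(expit(b0 + offset))) - target

        return brentq(gap, -15.0, 5.0, xtol=1e-10)

    return solve(params.prior_obesity_model, target_3y), solve(params.outcome_model, target_6y)


def impose_missingness(cohort: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Return a copy with values masked; exposure/outcome are never masked."""
    spec.validate()
    unknown = set(spec.column_probs) - set(cohort.columns)
    if unknown:
        raise ValueError(f"columns not in cohort: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    out = cohort.copy()
    if spec.mechanism == "MAR-on-education":
        factor_map = dict(zip(EDUCATION_LEVELS, spec.education_factors))
        factors = cohort["education"].map(factor_map).to_numpy(dtype=float)
    else:
        factors = np.ones(len(cohort))
    for col, p in spec.column_probs.items():
        probs = np.clip(p * factors, 0.0, 0.999999)
        mask = rng.random(len(cohort)) < probs
        if str(out[col].dtype) == "boolean":
            out.loc[mask, col] = pd.NA
        elif out[col].dtype == object:
            out.loc[mask, col] = np.nan
        else:
            if np.issubdtype(out[col].dtype, np.integer):
                out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    out.attrs = dict(cohort.attrs)
    return out


def validate_cohort(cohort: pd.DataFrame, check_consistency: bool = True) -> None:
    """Schema and invariant checks; raises ValueError naming the offence."""
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort missing columns: {missing_cols}")
    if cohort["id"].duplicated().any():
        raise ValueError("cohort ids must be unique")
    for col, levels in _CATEGORICAL_LEVELS.items():
        vals = cohort[col].dropna()
        bad = set(vals) - set(levels)
        if bad:
            raise ValueError(f"column {col!r} has unknown labels: {sorted(bad)}")
    intake = cohort["intake_kcal"].dropna()
    if (intake <= 0).any():
        raise ValueError("intake_kcal must be positive")
    if check_consistency:
        for age in ("3y", "6y"):
            both = cohort[[f"bmi_z_{age}", f"obese_{age}"]].dropna()
            flag = both[f"obese_{age}"].astype(bool).to_numpy()
            implied = both[f"bmi_z_{age}"].to_numpy() > OBESE_Z
            if (flag != implied).any():
                raise ValueError(f"obese_{age} inconsistent with bmi_z_{age} at the 95th-centile cut-off")


def _params_to_dict(params: CohortParams) -> dict:
    # tuples become lists so the dict round-trips through JSON unchanged
    d = dataclasses.asdict(params)
    d["education_probs"] = list(d["education_probs"])
    d["ethnicity_education_effect"] = list(d["ethnicity_education_effect"])
    return d


def _params_from_dict(d: dict) -> CohortParams:
    d = dict(d)
    d["intake_model"] = IntakeModel(**d["intake_model"])
    d["outcome_model"] = OutcomeModel(**d["outcome_model"])
    d["prior_obesity_model"] = OutcomeModel(**d["prior_obesity_model"])
    d["education_probs"] = tuple(d["education_probs"])
    d["ethnicity_education_effect"] = tuple(d["ethnicity_education_effect"])
    return CohortParams(**d)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort as CSV (empty cell = missing) plus a JSON sidecar with
    the generating parameters when present."""
    path = Path(path)
    cohort.to_csv(path, index=False)
    if "params" in cohort.attrs:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(cohort.attrs["params"], indent=2))


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`; validates on load."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            dtype={
                "obese_3y": "boolean",
                "obese_6y": "boolean",
                "imd_quintile": "float",
            },
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed cohort file {path}: {exc}") from exc
    if df["imd_quintile"].notna().all():
        df["imd_quintile"] = df["imd_quintile"].astype(int)
    validate_cohort(df)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        df.attrs["params"] = json.loads(sidecar.read_text())
    return df
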