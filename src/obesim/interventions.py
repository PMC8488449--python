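"""Counterfactual calorie-reduction scenarios and their g-computation impact.

Four built-in scenarios mirror a policy-simulation design:

1. universal: shift each sex's median intake down to the estimated average
   requirement (EAR), 75% uptake, normal jitter around the adjusted level;
2. targeted intensive: -21.3% intake for children in highly deprived areas
   (IMD score >= mean + 1 SD), 75% uptake;
3. indicated intensive: -21.3% for children living with obesity at age 3,
   100% uptake;
4. truncation: intake capped at the sex-specific EAR for every child
   consuming above it, 100% uptake.

Every scenario floors adjusted intake at 2 SD below the mean observed intake
(a child already below the floor is untouched) and never increases intake.
Impacts are evaluated by g-computation: per-child obesity probabilities are
re-predicted from the already-fitted CDE model with the modified intake — the
model is not refitted — then averaged overall and by education group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np
import pandas as pd

from .growth import EARTable, load_default_ears
from .msm import (
    CDEResult,
    InequalityMetrics,
    PrevalenceReport,
    _delta_inequality,
    _prevalence_from_fit,
)

__all__ = [
    "ScenarioSpec",
    "UniversalReduction",
    "InterventionResult",
    "compute_universal_reduction",
    "select_eligible",
    "apply_scenario",
    "proportion_at_or_below_ear",
    "simulate_impact",
    "build_builtin_scenarios",
]

ELIGIBILITY_RULES = ("all", "deprived", "prior_obese", "above_ear")
REDUCTION_RULES = ("shift_median_to_ear", "percent", "truncate_to_ear")

#: intensive-intervention effectiveness: a 21.3% intake reduction, the
#: child-population analogue of "500 kcal/day fewer" adult weight-loss advice
INTENSIVE_PERCENT = 0.213


@dataclass
class ScenarioSpec:
    """Declarative intervention description.

    ``variability_sd`` is the SD (kcal) of the normal jitter added around the
    adjusted intake; ``None`` selects the rule default (25% of the mean
    absolute reduction among treated children; 0 for the truncation rule),
    0 disables jitter. ``lower_bound`` floors adjusted intake at
    mean - 2 SD of the observed intake distribution.
    """

    name: str
    eligibility: str = "all"
    reduction_rule: str = "shift_median_to_ear"
    reduction_value: Optional[float] = None  # fraction for the percent rule
    uptake: float = 1.0
    variability_sd: Optional[float] = None
    lower_bound: bool = True
    lower_bound_kcal: Optional[float] = None  # explicit floor overrides mean - 2 SD
    seed: int = 0

    def validate(self) -> None:
        if self.eligibility not in ELIGIBILITY_RULES:
            raise ValueError(f"unknown eligibility rule {self.eligibility!r}")
        if self.reduction_rule not in REDUCTION_RULES:
            raise ValueError(f"unknown reduction rule {self.reduction_rule!r}")
        if not (0.0 <= self.uptake <= 1.0):
            raise ValueError("uptake must be in [0, 1]")
        if self.variability_sd is not None and self.variability_sd < 0:
            raise ValueError("variability_sd must be >= 0")
        if self.reduction_rule == "percent":
            if self.reduction_value is None or not (0.0 <= self.reduction_value < 1.0):
                raise ValueError("percent rule needs reduction_value in [0, 1)")


@dataclass
class UniversalReduction:
    """Sex-specific arithmetic of the universal shift-to-EAR intervention."""

    median_intake: dict[str, float]
    ear: dict[str, float]
    absolute_reduction: dict[str, float]
    percent_reduction: dict[str, float]
    overall_percent: float


def compute_universal_reduction(
    median_by_sex: dict[str, float], ear_by_sex: dict[str, float], male_fraction: float
) -> UniversalReduction:
    """kcal and percent reductions that bring each sex's median to its EAR.

    absolute = max(median - EAR, 0); percent = absolute / median; the overall
    percentage is the male-fraction-weighted mean of the sex percentages.
    """
    for d in (median_by_sex, ear_by_sex):
        if any(v <= 0 for v in d.values()):
            raise ValueError("medians and EARs must be positive")
    if not (0.0 <= male_fraction <= 1.0):
        raise ValueError("male_fraction must be in [0, 1]")
    absolute = {
        sex: max(median_by_sex[sex] - ear_by_sex[sex], 0.0) for sex in median_by_sex
    }
    percent = {sex: absolute[sex] / median_by_sex[sex] for sex in median_by_sex}
    overall = male_fraction * percent["male"] + (1.0 - male_fraction) * percent["female"]
    return UniversalReduction(
        median_intake=dict(median_by_sex),
        ear=dict(ear_by_sex),
        absolute_reduction=absolute,
        percent_reduction=percent,
        overall_percent=overall,
    )


def _ears_for(cohort: pd.DataFrame, ear_table: EARTable, age: float = 3.0) -> np.ndarray:
    by_sex = ear_table.by_sex(age)
    return cohort["sex"].map(by_sex).to_numpy(dtype=float)


def select_eligible(
    cohort: pd.DataFrame, spec: ScenarioSpec, ear_table: EARTable | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Eligibility mask per the targeting rule; treated = eligible children
    winning an independent Bernoulli(uptake) draw under ``spec.seed``."""
    spec.validate()
    if ear_table is None:
        ear_table = load_default_ears()
    if spec.eligibility == "all":
        eligible = np.ones(len(cohort), dtype=bool)
    elif spec.eligibility == "deprived":
        if cohort["imd_score"].isna().any():
            raise ValueError("deprivation targeting requires complete imd_score")
        score = cohort["imd_score"].to_numpy(dtype=float)
        eligible = score >= score.mean() + score.std(ddof=0)
    elif spec.eligibility == "prior_obese":
        if cohort["obese_3y"].isna().any():
            raise ValueError("prior-obesity targeting requires complete obese_3y")
        eligible = cohort["obese_3y"].to_numpy(dtype=bool)
    else:  # above_ear
        if cohort["intake_kcal"].isna().any():
            raise ValueError("intake targeting requires complete intake_kcal")
        eligible = cohort["intake_kcal"].to_numpy(dtype=float) > _ears_for(cohort, ear_table)
    rng = np.random.default_rng(spec.seed)
    treated = eligible & (rng.random(len(cohort)) < spec.uptake)
    return eligible, treated


def apply_scenario(
    cohort: pd.DataFrame, spec: ScenarioSpec, ear_table: EARTable | None = None
) -> dict:
    """Apply the reduction rule to treated children.

    Returns a dict with the modified cohort, the masks, the lower bound used
    and pre/post proportions at or below the EAR. Adjusted intake is floored
    at mean - 2 SD of observed intake, and never exceeds the child's original
    intake.
    """
    spec.validate()
    if ear_table is None:
        ear_table = load_default_ears()
    if cohort["intake_kcal"].isna().any():
        raise ValueError("intake_kcal must be complete before applying a scenario")
    intake = cohort["intake_kcal"].to_numpy(dtype=float)
    eligible, treated = select_eligible(cohort, spec, ear_table)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    ears = _ears_for(cohort, ear_table)
    male = (cohort["sex"] == "male").to_numpy()

    adjusted = intake.copy()
    if spec.reduction_rule == "shift_median_to_ear":
        medians = {
            "male": float(np.median(intake[male])),
            "female": float(np.median(intake[~male])),
        }
        red = compute_universal_reduction(medians, ear_table.by_sex(3.0), float(male.mean()))
        for sex, mask_sex in (("male", male), ("female", ~male)):
            sel = treated & mask_sex
            if not sel.any():
                continue
            shift = red.absolute_reduction[sex]
            sd = spec.variability_sd if spec.variability_sd is not None else 0.25 * shift
            jitter = sd * rng.standard_normal(int(sel.sum()))
            jitter -= jitter.mean()  # re-centre: mean treated shift == target
            adjusted[sel] = intake[sel] - shift + jitter
    elif spec.reduction_rule == "percent":
        p = spec.reduction_value
        sel = treated
        if sel.any():
            base = intake[sel] * (1.0 - p)
            mean_red = float((intake[sel] * p).mean())
            sd = spec.variability_sd if spec.variability_sd is not None else 0.25 * mean_red
            jitter = sd * rng.standard_normal(int(sel.sum()))
            if jitter.size:
                jitter -= jitter.mean()
            adjusted[sel] = base + jitter
    else:  # truncate_to_ear — a hard cap, jitter would defeat it
        adjusted[treated] = np.minimum(intake[treated], ears[treated])

    if np.any(adjusted <= 0):
        n_bad = int((adjusted <= 0).sum())
        if n_bad > 0.01 * len(adjusted):
            warnings.warn(f"{n_bad} adjusted intakes fell at or below zero before flooring")

    if spec.lower_bound:
        if spec.lower_bound_kcal is not None:
            bound = float(spec.lower_bound_kcal)
        else:
            bound = float(intake.mean() - 2.0 * intake.std(ddof=0))
        adjusted = np.maximum(adjusted, bound)
    else:
        bound = float("-inf")
    # never increase intake: also restores children already below the floor
    adjusted = np.minimum(adjusted, intake)

    modified = cohort.copy()
    modified["intake_kcal"] = adjusted
    modified.attrs = dict(cohort.attrs)
    return {
        "cohort": modified,
        "eligible": eligible,
        "treated": treated,
        "lower_bound": bound,
        "pre_le_ear": proportion_at_or_below_ear(cohort, ear_table),
        "post_le_ear": proportion_at_or_below_ear(modified, ear_table),
    }


def proportion_at_or_below_ear(
    cohort: pd.DataFrame, ear_table: EARTable | None = None
) -> dict[str, float]:
    """Fraction of each sex with intake at or below ('<=', inclusive) the EAR."""
    if ear_table is None:
        ear_table = load_default_ears()
    ears = _ears_for(cohort, ear_table)
    intake = cohort["intake_kcal"].to_numpy(dtype=float)
    out = {}
    for sex in ("male", "female"):
        mask = (cohort["sex"] == sex).to_numpy()
        out[sex] = float((intake[mask] <= ears[mask]).mean()) if mask.any() else float("nan")
    return out


@dataclass
class InterventionResult:
    scenario: ScenarioSpec
    cohort: pd.DataFrame
    treated_fraction: float
    eligible_fraction: float
    pre_le_ear: dict[str, float]
    post_le_ear: dict[str, float]
    prevalence: PrevalenceReport
    inequality: InequalityMetrics
    pct_change_vs_cde: dict[str, float]


def simulate_impact(
    cohort: pd.DataFrame,
    spec: ScenarioSpec,
    cde: CDEResult,
    ear_table: EARTable | None = None,
) -> InterventionResult:
    """Post-intervention prevalence and inequalities by g-computation.

    Predictions reuse ``cde``'s fitted coefficients with the modified intake;
    percent changes are relative to the CDE reference report.
    """
    if len(cohort) != len(cde.weights):
        raise ValueError("cohort does not match the CDE fit (length mismatch)")
    applied = apply_scenario(cohort, spec, ear_table)
    new_intake = applied["cohort"]["intake_kcal"].to_numpy(dtype=float)
    report = _prevalence_from_fit(
        cde.fit_categorical, cohort, model_tag=spec.name, intake=new_intake
    )
    ineq = _delta_inequality(cde.fit_continuous, cohort, intake=new_intake)
    ref = cde.prevalence
    pct = {"overall": 100.0 * (report.overall - ref.overall) / ref.overall}
    for lvl, p in report.by_education.items():
        pct[lvl] = 100.0 * (p - ref.by_education[lvl]) / ref.by_education[lvl]
    return InterventionResult(
        scenario=spec,
        cohort=applied["cohort"],
        treated_fraction=float(applied["treated"].mean()),
        eligible_fraction=float(applied["eligible"].mean()),
        pre_le_ear=applied["pre_le_ear"],
        post_le_ear=applied["post_le_ear"],
        prevalence=report,
        inequality=ineq,
        pct_change_vs_cde=pct,
    )


def build_builtin_scenarios(seed: int = 0) -> list[ScenarioSpec]:
    """The four standard scenarios with deterministic per-scenario sub-seeds."""
    sub = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(4)]
    return [
        ScenarioSpec(
            name="S1_universal_to_ear",
            eligibility="all",
            reduction_rule="shift_median_to_ear",
            uptake=0.75,
            seed=sub[0],
        ),
        ScenarioSpec(
            name="S2_targeted_deprived",
            eligibility="deprived",
            reduction_rule="percent",
            reduction_value=INTENSIVE_PERCENT,
            uptake=0.75,
            seed=sub[1],
        ),
        ScenarioSpec(
            name="S3_indicated_prior_obese",
            eligibility="prior_obese",
            reduction_rule="percent",
            reduction_value=INTENSIVE_PERCENT,
            uptake=1.0,
            seed=sub[2],
        ),
        ScenarioSpec(
            name="S4_truncate_to_ear",
            eligibility="above_ear",
            reduction_rule="truncate_to_ear",
            uptake=1.0,
            seed=sub[3],
        ),
    ]
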