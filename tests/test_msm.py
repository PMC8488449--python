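import math

import numpy as np
import pandas as pd
import pytest

from obesim.cohort import CohortParams, IntakeModel, MissingnessSpec, OutcomeModel, generate_cohort, impose_missingness
from obesim.msm import (
    MarginalStructuralLogit,
    chained_imputation,
    estimate_cde,
    estimate_unadjusted,
    fit_weighted_logistic,
    inequality_metrics,
    rubin_pool,
)
from obesim.weights import build_weight_set

from conftest import toy_cohort


def _recovery_params(n, seed):
    """Correctly specified outcome (no confounder terms) so the weighted
    marginal fit targets exactly the generating logit coefficients."""
    return CohortParams(
        n_children=n,
        seed=seed,
        outcome_model=OutcomeModel(
            intercept=-2.9, education_coef=0.39, intake_coef=0.10,
            ethnicity_coef=0.0, confounder_coefs={},
        ),
        intake_model=IntakeModel(confounder_effects={"tv_high": 0.04, "activity_low": 0.03}),
    )


class TestWeightedLogistic:
    def test_constant_weights_equal_unweighted(self, default_cohort_small):
        unweighted = fit_weighted_logistic(default_cohort_small, include_intake=True)
        weighted = fit_weighted_logistic(
            default_cohort_small, include_intake=True, weights=np.full(3000, 2.0)
        )
        np.testing.assert_allclose(unweighted.coef_, weighted.coef_, atol=1e-8)

    def test_duplicated_rows_equal_weight_two(self):
        base = toy_cohort(
            intakes=[1200, 1400, 1000, 1600, 1300, 900, 1100, 1250, 1700, 950, 1450, 1350] * 20,
            educations=["low", "mid", "high"] * 80,
            obese_6y=[True, False, False, False, True, False, False, False, True, False, False, False] * 20,
        )
        doubled = pd.concat([base, base], ignore_index=True)
        doubled["id"] = np.arange(len(doubled))
        fit_dup = fit_weighted_logistic(doubled, include_intake=True)
        fit_w2 = fit_weighted_logistic(base, include_intake=True, weights=np.full(len(base), 2.0))
        np.testing.assert_allclose(fit_dup.coef_, fit_w2.coef_, atol=1e-7)

    def test_recovers_known_coefficients(self):
        df = generate_cohort(_recovery_params(20000, 101))
        ws = build_weight_set(df)
        fit = fit_weighted_logistic(
            df, education_coding="continuous", include_intake=True, weights=ws.truncated
        )
        se = np.sqrt(np.diag(fit.vcov_.to_numpy()))
        params = dict(zip(fit.coef_.index, fit.coef_))
        ses = dict(zip(fit.coef_.index, se))
        assert abs(params["edu_code"] - 0.39) < 3 * ses["edu_code"]
        assert abs(params["intake_100kcal"] - 0.10) < 3 * ses["intake_100kcal"]

    def test_rejects_bad_inputs(self, default_cohort_small):
        with pytest.raises(ValueError, match="positive"):
            fit_weighted_logistic(default_cohort_small, weights=np.zeros(3000))
        with pytest.raises(ValueError, match="mismatch"):
            fit_weighted_logistic(default_cohort_small, weights=np.ones(10))


class TestUnadjusted:
    def test_equal_group_rates_give_null_inequality(self):
        # 60 children per education group, identical 10% obesity everywhere
        outcomes = ([True] * 6 + [False] * 54) * 3
        educations = ["low"] * 60 + ["mid"] * 60 + ["high"] * 60
        df = toy_cohort(intakes=[1300.0] * 180, educations=educations, obese_6y=outcomes)
        report, ineq = estimate_unadjusted(df)
        assert ineq.risk_ratio == pytest.approx(1.0, abs=1e-6)
        assert ineq.risk_difference == pytest.approx(0.0, abs=1e-6)

    def test_saturated_model_reproduces_empirical_rates(self):
        # group rates 10% / 9% / 5% with 1000 children per group
        def block(rate):
            return [True] * int(1000 * rate) + [False] * (1000 - int(1000 * rate))

        df = toy_cohort(
            intakes=[1300.0] * 3000,
            educations=["low"] * 1000 + ["mid"] * 1000 + ["high"] * 1000,
            obese_6y=block(0.10) + block(0.09) + block(0.05),
        )
        report, _ = estimate_unadjusted(df)
        assert report.by_education["low"] == pytest.approx(0.10, abs=1e-9)
        assert report.by_education["mid"] == pytest.approx(0.09, abs=1e-9)
        assert report.by_education["high"] == pytest.approx(0.05, abs=1e-9)
        assert report.overall == pytest.approx(0.08, abs=1e-9)
        for lvl, (lo, hi) in report.ci.items():
            point = report.overall if lvl == "overall" else report.by_education[lvl]
            assert lo <= point <= hi

    def test_empty_education_cell_rejected(self):
        df = toy_cohort(
            intakes=[1300.0] * 40,
            educations=["low"] * 20 + ["mid"] * 20,
            obese_6y=[True, False] * 20,
        )
        with pytest.raises(Exception, match="education"):
            estimate_unadjusted(df)


class TestInequalityMetrics:
    def test_arithmetic_on_doctored_fit(self):
        # continuous fit with p(high)=0.05 and p(low)=0.10 exactly
        def logit(p):
            return math.log(p / (1 - p))

        est = MarginalStructuralLogit(education_coding="continuous", include_intake=False)
        b0 = logit(0.05)
        b1 = (logit(0.10) - logit(0.05)) / 2.0
        est.coef_ = pd.Series({"intercept": b0, "edu_code": b1})
        est.vcov_ = pd.DataFrame(np.zeros((2, 2)), index=est.coef_.index, columns=est.coef_.index)
        df = toy_cohort(intakes=[1300.0] * 10)
        from obesim.msm import _delta_inequality

        ineq = _delta_inequality(est, df)
        assert ineq.risk_ratio == pytest.approx(2.0, rel=1e-12)
        assert ineq.risk_difference == pytest.approx(5.0, rel=1e-12)

    def test_bootstrap_ci_contains_point_and_shrinks(self):
        widths = {}
        for n in (1000, 4000, 16000):
            df = generate_cohort(CohortParams(n_children=n, seed=55))
            ineq = inequality_metrics(
                df, weighted=False, ci_method="bootstrap", n_boot=60, seed=n
            )
            assert ineq.rr_ci[0] <= ineq.risk_ratio <= ineq.rr_ci[1]
            assert ineq.rd_ci[0] <= ineq.risk_difference <= ineq.rd_ci[1]
            widths[n] = ineq.rd_ci[1] - ineq.rd_ci[0]
        assert widths[1000] > widths[4000] > widths[16000]
        # ~1/sqrt(n): a 16x larger sample shrinks the CI about 4-fold
        assert 2.0 < widths[1000] / widths[16000] < 8.0


class TestCDE:
    def test_prevalences_match_unadjusted_when_intake_is_inert(self):
        params = CohortParams(
            n_children=20000,
            seed=77,
            outcome_model=OutcomeModel(
                intercept=-2.6, education_coef=0.39, intake_coef=0.0,
                ethnicity_coef=0.2,
                confounder_coefs={"tv_high": 0.2, "activity_low": 0.15},
            ),
        )
        df = generate_cohort(params)
        unadj, _ = estimate_unadjusted(df)
        cde = estimate_cde(df, ci_method="delta")
        assert cde.prevalence.overall == pytest.approx(unadj.overall, abs=0.005)
        for lvl in ("low", "mid", "high"):
            assert cde.prevalence.by_education[lvl] == pytest.approx(
                unadj.by_education[lvl], abs=0.01
            )

    def test_predict_then_average_equals_bruteforce(self, cohort_20k):
        cde = estimate_cde(cohort_20k, ci_method="delta")
        beta = cde.fit_categorical.coef_
        code = {"high": (0, 0), "mid": (1, 0), "low": (0, 1)}
        total = 0.0
        for edu, kcal in zip(cohort_20k["education"], cohort_20k["intake_kcal"]):
            mid_d, low_d = code[edu]
            eta = (
                beta["intercept"]
                + beta["edu_mid"] * mid_d
                + beta["edu_low"] * low_d
                + beta["intake_100kcal"] * (kcal - 1292.6) / 100.0
            )
            total += 1.0 / (1.0 + math.exp(-eta))
        assert cde.prevalence.overall == pytest.approx(total / len(cohort_20k), abs=1e-10)


class TestImputation:
    def test_no_missing_returns_identical_tables(self, default_cohort_small):
        out = chained_imputation(default_cohort_small, m=3, seed=1)
        assert out.m == 3
        for tbl in out.tables:
            pd.testing.assert_frame_equal(tbl, default_cohort_small)

    def test_mcar_intake_median_recovered(self):
        df = generate_cohort(CohortParams(n_children=10000, seed=91))
        truth = df["intake_kcal"].median()
        masked = impose_missingness(
            df, MissingnessSpec(column_probs={"intake_kcal": 0.2}, seed=2)
        )
        out = chained_imputation(masked, m=5, seed=3, cycles=5)
        pooled_median = np.mean([t["intake_kcal"].median() for t in out.tables])
        assert pooled_median == pytest.approx(truth, rel=0.02)
        for tbl in out.tables:
            assert not tbl["intake_kcal"].isna().any()

    def test_m50_supported(self):
        df = generate_cohort(CohortParams(n_children=400, seed=92))
        masked = impose_missingness(
            df, MissingnessSpec(column_probs={"intake_kcal": 0.1}, seed=4)
        )
        out = chained_imputation(masked, m=50, seed=5, cycles=2)
        assert out.m == 50
        assert len(set(out.seeds)) == 50

    def test_categorical_and_derived_columns(self):
        df = generate_cohort(CohortParams(n_children=4000, seed=93))
        masked = impose_missingness(
            df,
            MissingnessSpec(
                column_probs={"tv_cat": 0.2, "bmi_z_3y": 0.2, "obese_3y": 0.2}, seed=6
            ),
        )
        out = chained_imputation(masked, m=2, seed=7, cycles=3)
        for tbl in out.tables:
            assert set(tbl["tv_cat"]) <= {"low", "mid", "high"}
            from obesim.growth import OBESE_Z

            flag = tbl["obese_3y"].astype(bool).to_numpy()
            assert np.array_equal(flag, tbl["bmi_z_3y"].to_numpy() > OBESE_Z)

    def test_incomplete_outcome_rejected(self, default_cohort_small):
        bad = default_cohort_small.copy()
        bad.loc[bad.index[0], "obese_6y"] = pd.NA
        with pytest.raises(ValueError, match="exposure/outcome"):
            chained_imputation(bad, m=2)

    def test_overly_missing_column_rejected(self, default_cohort_small):
        bad = default_cohort_small.copy()
        bad["intake_kcal"] = np.nan
        with pytest.raises(ValueError, match="95%"):
            chained_imputation(bad, m=2)


class TestRubinPooling:
    def test_hand_example(self):
        # m=2, estimates {1, 3}, variances {1, 1}: Q=2, B=2, T=1+1.5*2=4
        pooled = rubin_pool([1.0, 3.0], [1.0, 1.0])
        assert pooled.estimate == pytest.approx(2.0)
        assert pooled.between_variance == pytest.approx(2.0)
        assert pooled.variance == pytest.approx(4.0)
        assert pooled.ci[0] < 2.0 < pooled.ci[1]

    def test_identical_estimates(self):
        pooled = rubin_pool([1.7, 1.7, 1.7], [0.04, 0.04, 0.04])
        assert pooled.estimate == pytest.approx(1.7)
        assert pooled.between_variance == pytest.approx(0.0)
        assert pooled.variance == pytest.approx(0.04)

    def test_single_imputation_warns(self):
        with pytest.warns(UserWarning, match="m = 1"):
            pooled = rubin_pool([2.5], [0.09])
        assert pooled.estimate == 2.5
        assert pooled.variance == pytest.approx(0.09)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rubin_pool([], [])
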