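"""Weighted logistic marginal structural model and supporting machinery.

The outcome model is a logistic regression of obesity at 6-7 years on maternal
education and (for the adjusted model) daily energy intake, fitted by IRLS
with per-child stabilized inverse-probability weights and a robust sandwich
covariance. Predicted probabilities with intake held at each child's observed
value give the controlled direct effect (CDE) of education on obesity.

Inequalities are summarised by refitting with education as a continuous
linear term on the disadvantage coding (high=0, mid=1, low=2):

    risk ratio       RR = p_hat(low) / p_hat(high)
    risk difference  RD = p_hat(low) - p_hat(high)   (percentage points)

so RR > 1 reads as disadvantage-associated excess obesity. Confidence
intervals come from a nonparametric bootstrap over children (weights
re-estimated inside each resample) or a delta-method approximation.

Missing mediator/confounder data are handled by a lightweight
chained-equations imputer with Rubin's-rules pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator
from sklearn.linear_model import LinearRegression, LogisticRegression

from .cohort import (
    EDUCATION_LEVELS,
    INTAKE_REF_KCAL,
    PROTECTED_COLUMNS,
    education_code,
)
from .growth import OBESE_Z
from .weights import build_weight_set

__all__ = [
    "MarginalStructuralLogit",
    "MSMFittingError",
    "PrevalenceReport",
    "InequalityMetrics",
    "CDEResult",
    "ImputationSet",
    "fit_weighted_logistic",
    "estimate_unadjusted",
    "estimate_cde",
    "inequality_metrics",
    "chained_imputation",
    "rubin_pool",
]

Z95 = 1.959963984540054  # standard-normal 97.5% quantile

#: disadvantage codes used for the inequality contrast
LOW_CODE, HIGH_CODE = 2.0, 0.0


class MSMFittingError(RuntimeError):
    """Weighted logistic fit failed to converge or is degenerate."""


class MarginalStructuralLogit(BaseEstimator):
    """Weighted logistic regression of obesity on education (+ intake).

    Parameters
    ----------
    education_coding : {"categorical", "continuous"}
        Dummy coding (reference = high education) or a single linear
        disadvantage term (high=0, mid=1, low=2).
    include_intake : bool
        Add daily energy intake, centred at 1292.6 kcal and scaled per
        100 kcal, as a continuous covariate.
    outcome : str
        Binary outcome column (default ``obese_6y``).

    Fitted attributes carry a trailing underscore: ``coef_`` (pandas Series),
    ``vcov_`` (robust HC1 sandwich), ``result_`` (statsmodels GLMResults),
    ``n_effective_`` (sum of weights).
    """

    def __init__(
        self,
        education_coding: str = "categorical",
        include_intake: bool = True,
        outcome: str = "obese_6y",
    ):
        self.education_coding = education_coding
        self.include_intake = include_intake
        self.outcome = outcome

    # -- design ------------------------------------------------------------
    def _design(self, cohort: pd.DataFrame, intake=None, education=None) -> pd.DataFrame:
        n = len(cohort)
        cols = {"intercept": np.ones(n)}
        code = (
            np.full(n, float(education))
            if education is not None
            else education_code(cohort["education"])
        )
        if self.education_coding == "categorical":
            cols["edu_mid"] = (code == 1.0).astype(float)
            cols["edu_low"] = (code == 2.0).astype(float)
        elif self.education_coding == "continuous":
            cols["edu_code"] = code
        else:
            raise ValueError(f"unknown education_coding {self.education_coding!r}")
        if self.include_intake:
            kcal = (
                np.asarray(intake, dtype=float)
                if intake is not None
                else cohort["intake_kcal"].to_numpy(dtype=float)
            )
            cols["intake_100kcal"] = (kcal - INTAKE_REF_KCAL) / 100.0
        return pd.DataFrame(cols, index=cohort.index)

    # -- sklearn API --------------------------------------------------------
    def fit(self, cohort: pd.DataFrame, y=None, sample_weight=None) -> "MarginalStructuralLogit":
        endog = cohort[self.outcome]
        if endog.isna().any():
            raise ValueError(f"outcome {self.outcome!r} must be complete")
        endog = endog.astype(float).to_numpy()
        X = self._design(cohort)
        if self.include_intake and cohort["intake_kcal"].isna().any():
            raise ValueError("intake_kcal must be complete (impute upstream)")
        if sample_weight is None:
            sample_weight = np.ones(len(cohort))
        w = np.asarray(sample_weight, dtype=float)
        if w.shape[0] != len(cohort):
            raise ValueError("sample_weight length mismatch")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        # empty education cells make the fit (or later contrasts) degenerate
        counts = pd.Series(education_code(cohort["education"])).value_counts()
        if self.education_coding == "categorical" and len(counts) < 3:
            raise MSMFittingError("empty maternal-education cell")
        model = sm.GLM(endog, X, family=sm.families.Binomial(), freq_weights=w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, tol=1e-8, cov_type="HC1")
        if not res.converged:
            raise MSMFittingError(f"IRLS did not converge (deviance {res.deviance:.4g})")
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
            raise MSMFittingError("separation suspected: unbounded coefficients")
        self.result_ = res
        self.coef_ = res.params
        self.vcov_ = pd.DataFrame(
            res.cov_params(), index=res.params.index, columns=res.params.index
        )
        self.n_effective_ = float(w.sum())
        self.weight_vector_ = w
        return self

    def predict_proba(self, cohort: pd.DataFrame, intake=None, education=None) -> np.ndarray:
        """Per-child predicted obesity probability; ``intake``/``education``
        override the observed values (g-computation hooks)."""
        X = self._design(cohort, intake=intake, education=education)
        return expit(X.to_numpy() @ self.coef_.to_numpy())


def fit_weighted_logistic(
    cohort: pd.DataFrame,
    education_coding: str = "categorical",
    include_intake: bool = True,
    weights=None,
    outcome: str = "obese_6y",
) -> MarginalStructuralLogit:
    """Thin functional wrapper over :class:`MarginalStructuralLogit`."""
    est = MarginalStructuralLogit(
        education_coding=education_coding, include_intake=include_intake, outcome=outcome
    )
    return est.fit(cohort, sample_weight=weights)


# ---------------------------------------------------------------------------
# reports


@dataclass
class PrevalenceReport:
    overall: float
    by_education: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    model_tag: str = ""


@dataclass
class InequalityMetrics:
    risk_ratio: float
    risk_difference: float  # percentage points, p(low) - p(high)
    rr_ci: tuple[float, float] | None = None
    rd_ci: tuple[float, float] | None = None


@dataclass
class CDEResult:
    """Reference CDE analysis: both fits, the weights, and the reports."""

    fit_categorical: MarginalStructuralLogit
    fit_continuous: MarginalStructuralLogit
    weights: np.ndarray
    prevalence: PrevalenceReport
    inequality: InequalityMetrics


def _group_masks(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    edu = cohort["education"].to_numpy()
    return {lvl: edu == lvl for lvl in EDUCATION_LEVELS}


def _prevalence_from_fit(
    fit: MarginalStructuralLogit, cohort: pd.DataFrame, model_tag: str, intake=None
) -> PrevalenceReport:
    p = fit.predict_proba(cohort, intake=intake)
    masks = _group_masks(cohort)
    by_edu = {}
    ci = {}
    X = fit._design(cohort, intake=intake).to_numpy()
    V = fit.vcov_.to_numpy()
    for lvl, mask in masks.items():
        if mask.sum() == 0:
            raise MSMFittingError(f"empty education cell {lvl!r}")
        by_edu[lvl] = float(p[mask].mean())
        grad = (p[mask] * (1 - p[mask]))[:, None] * X[mask]
        g = grad.mean(axis=0)
        se = float(np.sqrt(g @ V @ g))
        ci[lvl] = (by_edu[lvl] - Z95 * se, by_edu[lvl] + Z95 * se)
    overall = float(p.mean())
    grad_all = ((p * (1 - p))[:, None] * X).mean(axis=0)
    se_all = float(np.sqrt(grad_all @ V @ grad_all))
    ci["overall"] = (overall - Z95 * se_all, overall + Z95 * se_all)
    return PrevalenceReport(overall=overall, by_education=by_edu, ci=ci, model_tag=model_tag)


def _rr_rd_from_continuous_fit(
    fit: MarginalStructuralLogit, cohort: pd.DataFrame, intake=None
) -> tuple[float, float, np.ndarray, np.ndarray, float, float]:
    """Point estimates plus delta-method gradients of (log RR, RD)."""
    beta = fit.coef_.to_numpy()
    X_low = fit._design(cohort, intake=intake, education=LOW_CODE).to_numpy()
    X_high = fit._design(cohort, intake=intake, education=HIGH_CODE).to_numpy()
    p_low_i = expit(X_low @ beta)
    p_high_i = expit(X_high @ beta)
    p_low = float(p_low_i.mean())
    p_high = float(p_high_i.mean())
    if p_high <= 0:
        raise MSMFittingError("risk ratio undefined: p(high) = 0")
    g_low = ((p_low_i * (1 - p_low_i))[:, None] * X_low).mean(axis=0)
    g_high = ((p_high_i * (1 - p_high_i))[:, None] * X_high).mean(axis=0)
    g_logrr = g_low / p_low - g_high / p_high
    g_rd = g_low - g_high
    return p_low, p_high, g_logrr, g_rd, float(np.log(p_low / p_high)), p_low - p_high


def _delta_inequality(fit, cohort, intake=None) -> InequalityMetrics:
    p_low, p_high, g_logrr, g_rd, logrr, rd = _rr_rd_from_continuous_fit(fit, cohort, intake)
    V = fit.vcov_.to_numpy()
    se_logrr = float(np.sqrt(g_logrr @ V @ g_logrr))
    se_rd = float(np.sqrt(g_rd @ V @ g_rd))
    return InequalityMetrics(
        risk_ratio=float(np.exp(logrr)),
        risk_difference=100.0 * rd,
        rr_ci=(float(np.exp(logrr - Z95 * se_logrr)), float(np.exp(logrr + Z95 * se_logrr))),
        rd_ci=(100.0 * (rd - Z95 * se_rd), 100.0 * (rd + Z95 * se_rd)),
    )


def _point_rr_rd(cohort: pd.DataFrame, weighted: bool) -> tuple[float, float]:
    """RR/RD re-estimated from scratch (weights included) — bootstrap kernel."""
    if weighted:
        ws = build_weight_set(cohort)
        w = ws.truncated
    else:
        w = None
    fit = fit_weighted_logistic(
        cohort, education_coding="continuous", include_intake=weighted, weights=w
    )
    p_low, p_high, *_ , logrr, rd = _rr_rd_from_continuous_fit(fit, cohort)
    return float(np.exp(logrr)), 100.0 * rd


def inequality_metrics(
    cohort: pd.DataFrame,
    fit: MarginalStructuralLogit | None = None,
    weighted: bool = True,
    ci_method: str = "bootstrap",
    n_boot: int = 499,
    seed: int = 0,
) -> InequalityMetrics:
    """RR and RD (low vs high education) with 95% CIs.

    ``ci_method='bootstrap'`` resamples children and re-estimates weights in
    every replicate (percentile intervals, default 499 replicates);
    ``'delta'`` propagates the sandwich covariance of the continuous fit and
    ignores weight-estimation noise (fast approximation).
    """
    if fit is None:
        w = build_weight_set(cohort).truncated if weighted else None
        fit = fit_weighted_logistic(
            cohort, education_coding="continuous", include_intake=weighted, weights=w
        )
    point = _delta_inequality(fit, cohort)
    if ci_method == "delta":
        return point
    if ci_method != "bootstrap":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    rrs, rds = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        try:
            rr, rd = _point_rr_rd(boot, weighted=weighted)
        except (MSMFittingError, ValueError):
            continue  # rare degenerate resample
        rrs.append(rr)
        rds.append(rd)
    rr_ci = tuple(np.percentile(rrs, [2.5, 97.5]))
    rd_ci = tuple(np.percentile(rds, [2.5, 97.5]))
    return InequalityMetrics(
        risk_ratio=point.risk_ratio,
        risk_difference=point.risk_difference,
        rr_ci=(float(rr_ci[0]), float(rr_ci[1])),
        rd_ci=(float(rd_ci[0]), float(rd_ci[1])),
    )


def estimate_unadjusted(
    cohort: pd.DataFrame,
    ci_method: str = "delta",
    n_boot: int = 499,
    seed: int = 0,
) -> tuple[PrevalenceReport, InequalityMetrics]:
    """Unweighted logistic fit of obesity on education only."""
    fit_cat = fit_weighted_logistic(cohort, education_coding="categorical", include_intake=False)
    report = _prevalence_from_fit(fit_cat, cohort, model_tag="unadjusted")
    fit_cont = fit_weighted_logistic(cohort, education_coding="continuous", include_intake=False)
    ineq = inequality_metrics(
        cohort, fit=fit_cont, weighted=False, ci_method=ci_method, n_boot=n_boot, seed=seed
    )
    return report, ineq


def estimate_cde(
    cohort: pd.DataFrame,
    weights=None,
    ci_method: str = "delta",
    n_boot: int = 499,
    seed: int = 0,
) -> CDEResult:
    """Controlled-direct-effect analysis: weighted fit of obesity on education
    plus intake, prevalences with intake held at observed values."""
    if weights is None:
        weights = build_weight_set(cohort).truncated
    weights = np.asarray(weights, dtype=float)
    fit_cat = fit_weighted_logistic(
        cohort, education_coding="categorical", include_intake=True, weights=weights
    )
    fit_cont = fit_weighted_logistic(
        cohort, education_coding="continuous", include_intake=True, weights=weights
    )
    report = _prevalence_from_fit(fit_cat, cohort, model_tag="CDE")
    ineq = inequality_metrics(
        cohort, fit=fit_cont, weighted=True, ci_method=ci_method, n_boot=n_boot, seed=seed
    )
    return CDEResult(
        fit_categorical=fit_cat,
        fit_continuous=fit_cont,
        weights=weights,
        prevalence=report,
        inequality=ineq,
    )


# ---------------------------------------------------------------------------
# multiple imputation


@dataclass
class ImputationSet:
    tables: list[pd.DataFrame]
    seeds: list[int]
    diagnostics: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.tables)


_CONTINUOUS_IMPUTE = {"intake_kcal": "log", "bmi_z_3y": "identity", "imd_score": "identity"}
_CATEGORICAL_IMPUTE = ["ethnicity", "birthweight_cat", "health", "activity_cat", "tv_cat"]
_DERIVED_IMPUTE = {"obese_3y", "imd_quintile"}


def _numeric_view(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the analysis columns for the imputation models."""
    three = {"low": 0.0, "mid": 1.0, "high": 2.0}
    out = pd.DataFrame(index=df.index)
    out["edu_code"] = education_code(df["education"])
    out["male"] = (df["sex"] == "male").astype(float)
    out["nonwhite"] = (df["ethnicity"] == "non-white").astype(float)
    out["bw_code"] = df["birthweight_cat"].map(three).astype(float)
    out["health_fair"] = (df["health"] == "fair_bad").astype(float)
    out["activity_code"] = df["activity_cat"].map(three).astype(float)
    out["tv_code"] = df["tv_cat"].map(three).astype(float)
    out["log_intake"] = np.log(df["intake_kcal"].astype(float))
    out["bmi_z_3y"] = df["bmi_z_3y"].astype(float)
    out["imd_score"] = df["imd_score"].astype(float)
    out["bmi_z_6y"] = df["bmi_z_6y"].astype(float)
    out["obese_6y"] = df["obese_6y"].astype(float)
    return out


_PREDICTOR_SOURCES = {
    "intake_kcal": "log_intake",
    "bmi_z_3y": "bmi_z_3y",
    "imd_score": "imd_score",
    "ethnicity": "nonwhite",
    "birthweight_cat": "bw_code",
    "health": "health_fair",
    "activity_cat": "activity_code",
    "tv_cat": "tv_code",
}


def _impute_once(cohort: pd.DataFrame, targets: list[str], cycles: int, rng) -> pd.DataFrame:
    df = cohort.copy()
    obs_masks = {c: df[c].notna().to_numpy() for c in targets}
    # initial fill: random draws from the observed values
    for col in targets:
        obs = df.loc[obs_masks[col], col].to_numpy()
        n_miss = int((~obs_masks[col]).sum())
        df.loc[~obs_masks[col], col] = rng.choice(obs, size=n_miss, replace=True)
    for _ in range(cycles):
        for col in targets:
            miss = ~obs_masks[col]
            num = _numeric_view(df)
            pred_cols = [v for k, v in _PREDICTOR_SOURCES.items() if k != col]
            pred_cols += ["edu_code", "male", "bmi_z_6y", "obese_6y"]
            X = num[sorted(set(pred_cols))].to_numpy()
            # bootstrap the observed rows: parameter draw for proper imputation
            obs_idx = np.flatnonzero(obs_masks[col])
            boot = rng.choice(obs_idx, size=obs_idx.size, replace=True)
            if col in _CONTINUOUS_IMPUTE:
                y = df[col].astype(float).to_numpy()
                if _CONTINUOUS_IMPUTE[col] == "log":
                    y = np.log(y)
                reg = LinearRegression().fit(X[boot], y[boot])
                resid = y[boot] - reg.predict(X[boot])
                sigma = float(np.sqrt(np.mean(resid**2)))
                draw = reg.predict(X[miss]) + sigma * rng.standard_normal(int(miss.sum()))
                df.loc[miss, col] = np.exp(draw) if _CONTINUOUS_IMPUTE[col] == "log" else draw
            else:
                y = df[col].astype(str).to_numpy()
                clf = LogisticRegression(max_iter=500, C=1e4)
                clf.fit(X[boot], y[boot])
                probs = clf.predict_proba(X[miss])
                cum = np.cumsum(probs, axis=1)
                u = rng.random(probs.shape[0])
                idx = (u[:, None] > cum).sum(axis=1)
                df.loc[miss, col] = clf.classes_[idx]
    # derived columns kept consistent with their parents
    if df["obese_3y"].isna().any():
        miss = df["obese_3y"].isna()
        df.loc[miss, "obese_3y"] = df.loc[miss, "bmi_z_3y"] > OBESE_Z
    if "bmi_z_3y" in targets:
        # an imputed z must land on the side of the cut-off that an observed
        # obesity flag dictates; redraw offending values from the right tail
        z_imputed = ~obs_masks["bmi_z_3y"]
        flag = df["obese_3y"].astype(bool).to_numpy()
        z = df["bmi_z_3y"].to_numpy(dtype=float)
        bad = z_imputed & (flag != (z > OBESE_Z))
        if bad.any():
            from scipy.stats import truncnorm

            n_bad = int(bad.sum())
            redraw = np.where(
                flag[bad],
                truncnorm.rvs(OBESE_Z, np.inf, size=n_bad, random_state=rng),
                truncnorm.rvs(-np.inf, OBESE_Z, size=n_bad, random_state=rng),
            )
            df.loc[bad, "bmi_z_3y"] = redraw
    if df["imd_quintile"].isna().any():
        miss = df["imd_quintile"].isna().to_numpy()
        cuts = np.quantile(df.loc[~miss, "imd_score"], [0.2, 0.4, 0.6, 0.8])
        df.loc[miss, "imd_quintile"] = np.searchsorted(cuts, df.loc[miss, "imd_score"]) + 1
    return df


def chained_imputation(
    cohort: pd.DataFrame, m: int = 5, seed: int = 0, cycles: int = 10
) -> ImputationSet:
    """Multiple imputation by chained equations (parametric draws).

    Each of the ``m`` imputations runs ``cycles`` sweeps of conditional models
    (linear regression on the log scale for intake, multinomial logistic for
    categoricals), each fitted on a bootstrap resample of the observed rows so
    parameter uncertainty propagates into the draws. Exposure and outcome must
    be complete on entry.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    for col in ("education", "obese_6y", "bmi_z_6y"):
        if cohort[col].isna().any():
            raise ValueError(f"analysis requires complete {col!r} (exposure/outcome)")
    frac_missing = cohort.isna().mean()
    too_missing = frac_missing[frac_missing > 0.95]
    if len(too_missing):
        raise ValueError(f"columns >95% missing: {list(too_missing.index)}")
    incomplete = [c for c in cohort.columns if cohort[c].isna().any()]
    targets = [c for c in incomplete if c in set(_CONTINUOUS_IMPUTE) | set(_CATEGORICAL_IMPUTE)]
    derived = [c for c in incomplete if c in _DERIVED_IMPUTE]
    unsupported = set(incomplete) - set(targets) - set(derived)
    if unsupported:
        raise ValueError(f"no imputation model for columns: {sorted(unsupported)}")
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(m)]
    if not incomplete:
        tables = [cohort.copy() for _ in range(m)]
    else:
        tables = [
            _impute_once(cohort, targets, cycles, np.random.default_rng(s)) for s in sub
        ]
    for tbl in tables:
        tbl["obese_3y"] = tbl["obese_3y"].astype("boolean")
    diag = {
        "m": m,
        "columns": incomplete,
        "pooled_means": {
            c: float(np.mean([pd.to_numeric(t[c], errors="coerce").mean() for t in tables]))
            for c in targets
            if c in _CONTINUOUS_IMPUTE
        },
    }
    return ImputationSet(tables=tables, seeds=sub, diagnostics=diag)


@dataclass
class PooledEstimate:
    estimate: float
    variance: float
    ci: tuple[float, float]
    df: float
    between_variance: float
    within_variance: float


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool estimates across imputations by Rubin's rules.

    Total variance = W + (1 + 1/m) B with W the mean within-imputation
    variance and B the between-imputation variance; the CI uses a
    t-distribution with Rubin's degrees of freedom.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size == 0:
        raise ValueError("need at least one imputation estimate")
    if np.any(u < 0):
        raise ValueError("variances must be non-negative")
    m = q.size
    qbar = float(q.mean())
    wbar = float(u.mean())
    if m == 1:
        warnings.warn("m = 1: between-imputation variance undefined, using within only")
        se = np.sqrt(wbar)
        return PooledEstimate(qbar, wbar, (qbar - Z95 * se, qbar + Z95 * se), np.inf, np.nan, wbar)
    b = float(q.var(ddof=1))
    total = wbar + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + wbar / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = np.inf
    tq = Z95 if not np.isfinite(df) else float(t_dist.ppf(0.975, df))
    se = np.sqrt(total)
    return PooledEstimate(qbar, total, (qbar - tq * se, qbar + tq * se), df, b, wbar)
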