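"""End-to-end pipeline: generate -> (mask/impute) -> weights -> CDE -> scenarios.

A single master seed drives every stochastic stage through a fixed spawn
table (stage k always gets the k-th child of the master SeedSequence), so
adding stages never perturbs earlier streams and identical configs give
byte-identical reports.

With multiple imputations the unadjusted/CDE/scenario quantities are
estimated on every completed table and pooled by Rubin's rules (prevalences
and risk differences on their own scale, risk ratios on the log scale).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortParams,
    MissingnessSpec,
    generate_cohort,
    impose_missingness,
)
from .growth import OBESE_Z, OVERWEIGHT_Z, load_default_ears
from .interventions import ScenarioSpec, build_builtin_scenarios, simulate_impact
from .msm import chained_imputation, estimate_cde, estimate_unadjusted, rubin_pool
from .weights import build_weight_set

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "MODEL_TABLE_COLUMNS"]

MODEL_TABLE_COLUMNS = [
    "model_tag",
    "le_ear_boys",
    "le_ear_girls",
    "overall",
    "low",
    "mid",
    "high",
    "pct_change_overall",
    "pct_change_low",
    "pct_change_mid",
    "pct_change_high",
    "rr",
    "rr_lo",
    "rr_hi",
    "rd",
    "rd_lo",
    "rd_hi",
]

# fixed spawn table: stage -> index of the master SeedSequence child
_STAGES = {"generate": 0, "missingness": 1, "imputation": 2, "bootstrap": 3, "scenarios": 4}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    n_children: int = 20000
    master_seed: int = 0
    missingness: dict | None = None  # {"column_probs": {...}, "mechanism": "MCAR"}
    m_imputations: int = 1
    imputation_cycles: int = 10
    ci_method: str = "delta"
    n_boot: int = 199
    scenarios: str | list = "builtin"
    exposure_column: str = "education"
    generator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    descriptives: pd.DataFrame
    model_table: pd.DataFrame
    weight_diagnostics: pd.DataFrame
    log: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        self.model_table.to_csv(out / "model_table.csv", index=False)
        self.weight_diagnostics.to_csv(out / "weight_diagnostics.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(self.log, indent=2, sort_keys=True))


def _stage_seed(master_seed: int, stage: str, extra: int = 0) -> int:
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    ss = children[_STAGES[stage]]
    if extra:
        ss = ss.spawn(extra + 1)[extra]
    return int(ss.generate_state(1)[0] % 2**31)


def _describe(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table mirroring a cohort characteristics layout."""
    rows = []

    def pct(col, level):
        s = cohort[col].dropna()
        rows.append(
            {"variable": col, "level": str(level), "value": round(100.0 * float((s == level).mean()), 1)}
        )

    for level in ("male", "female"):
        pct("sex", level)
    for level in ("low", "mid", "high"):
        pct("education", level)
    for level in ("white", "non-white"):
        pct("ethnicity", level)
    rows.append(
        {
            "variable": "intake_kcal",
            "level": "median",
            "value": round(float(cohort["intake_kcal"].median()), 1),
        }
    )
    for col in ("birthweight_cat", "activity_cat", "tv_cat"):
        for level in ("low", "mid", "high"):
            pct(col, level)
    for level in ("good", "fair_bad"):
        pct("health", level)
    for age in ("3y", "6y"):
        z = cohort[f"bmi_z_{age}"].dropna().to_numpy()
        cats = {
            "not_overweight": float((z <= OVERWEIGHT_Z).mean()),
            "overweight": float(((z > OVERWEIGHT_Z) & (z <= OBESE_Z)).mean()),
            "obese": float((z > OBESE_Z).mean()),
        }
        for level, v in cats.items():
            rows.append(
                {"variable": f"bmi_status_{age}", "level": level, "value": round(100.0 * v, 1)}
            )
    for q in range(1, 6):
        s = cohort["imd_quintile"].dropna()
        rows.append(
            {
                "variable": "imd_quintile",
                "level": str(q),
                "value": round(100.0 * float((s == q).mean()), 1),
            }
        )
    return pd.DataFrame(rows)


def _model_row(tag, le_ear, prevalence, inequality, pct_change=None) -> dict:
    row = {
        "model_tag": tag,
        "le_ear_boys": round(100.0 * le_ear["male"], 1),
        "le_ear_girls": round(100.0 * le_ear["female"], 1),
        "overall": round(100.0 * prevalence["overall"], 1),
        "low": round(100.0 * prevalence["low"], 1),
        "mid": round(100.0 * prevalence["mid"], 1),
        "high": round(100.0 * prevalence["high"], 1),
    }
    for key in ("overall", "low", "mid", "high"):
        row[f"pct_change_{key}"] = (
            round(pct_change[key], 1) if pct_change is not None else np.nan
        )
    row["rr"] = round(inequality["rr"], 2)
    row["rr_lo"] = round(inequality["rr_lo"], 2)
    row["rr_hi"] = round(inequality["rr_hi"], 2)
    row["rd"] = round(inequality["rd"], 1)
    row["rd_lo"] = round(inequality["rd_lo"], 1)
    row["rd_hi"] = round(inequality["rd_hi"], 1)
    return row


def _ci_to_var(ci: tuple[float, float]) -> float:
    return ((ci[1] - ci[0]) / (2 * 1.959963984540054)) ** 2


def _pool(values: list[float], cis: list[tuple[float, float]], log_scale=False):
    """Rubin-pool a scalar across imputations; returns (point, lo, hi)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 1:  # single completed table: nothing to pool
        return float(vals[0]), float(cis[0][0]), float(cis[0][1])
    if log_scale:
        est = np.log(vals)
        var = [
            _ci_to_var((np.log(lo), np.log(hi))) for lo, hi in cis
        ]
    else:
        est = vals
        var = [_ci_to_var(ci) for ci in cis]
    pooled = rubin_pool(est, var)
    lo, hi = pooled.ci
    if log_scale:
        return float(np.exp(pooled.estimate)), float(np.exp(lo)), float(np.exp(hi))
    return float(pooled.estimate), float(lo), float(hi)


def _analyse_table(table, scenarios, config, ear_table):
    """Unadjusted + CDE + scenarios on one completed table."""
    unadj_prev, unadj_ineq = estimate_unadjusted(
        table, ci_method=config.ci_method, n_boot=config.n_boot,
        seed=_stage_seed(config.master_seed, "bootstrap"),
    )
    weight_set = build_weight_set(table)
    cde = estimate_cde(
        table,
        weights=weight_set.truncated,
        ci_method=config.ci_method,
        n_boot=config.n_boot,
        seed=_stage_seed(config.master_seed, "bootstrap", extra=1),
    )
    results = [simulate_impact(table, spec, cde, ear_table) for spec in scenarios]
    return unadj_prev, unadj_ineq, weight_set, cde, results


def run_pipeline(config: RunConfig, out_dir=None) -> ReportBundle:
    """Run the full analysis; identical config implies identical outputs."""
    ear_table = load_default_ears()
    params = CohortParams(
        n_children=config.n_children,
        seed=_stage_seed(config.master_seed, "generate"),
        **config.generator_overrides,
    )
    cohort = generate_cohort(params)
    if config.exposure_column != "education":
        cohort = cohort.rename(
            columns={"education": "_education_orig", config.exposure_column: "education"}
        )

    stage = "generate"
    try:
        if config.missingness:
            stage = "missingness"
            spec = MissingnessSpec(
                column_probs=config.missingness["column_probs"],
                mechanism=config.missingness.get("mechanism", "MCAR"),
                seed=_stage_seed(config.master_seed, "missingness"),
            )
            masked = impose_missingness(cohort, spec)
            stage = "imputation"
            imp = chained_imputation(
                masked,
                m=config.m_imputations,
                seed=_stage_seed(config.master_seed, "imputation"),
                cycles=config.imputation_cycles,
            )
            tables = imp.tables
        else:
            tables = [cohort] * max(config.m_imputations, 1) if config.m_imputations > 1 else [cohort]

        stage = "scenarios"
        if config.scenarios == "builtin":
            scenarios = build_builtin_scenarios(seed=_stage_seed(config.master_seed, "scenarios"))
        else:
            scenarios = [ScenarioSpec(**s) for s in config.scenarios]

        stage = "analysis"
        per_table = [_analyse_table(t, scenarios, config, ear_table) for t in tables]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    m = len(per_table)
    weight_set = per_table[0][2]  # diagnostics from the first completed table

    from .interventions import proportion_at_or_below_ear

    observed_le = [proportion_at_or_below_ear(t, ear_table) for t in tables]

    def pool_block(reports, metrics, le_props):
        """Pool one model row's ingredients across the m completed tables."""
        prev, ineq, le = {}, {}, {}
        for key in ("overall", "low", "mid", "high"):
            vals = [
                r.overall if key == "overall" else r.by_education[key] for r in reports
            ]
            cis = [r.ci[key] for r in reports]
            prev[key], *_ = _pool(vals, cis)
        ineq["rr"], ineq["rr_lo"], ineq["rr_hi"] = _pool(
            [x.risk_ratio for x in metrics], [x.rr_ci for x in metrics], log_scale=True
        )
        ineq["rd"], ineq["rd_lo"], ineq["rd_hi"] = _pool(
            [x.risk_difference for x in metrics], [x.rd_ci for x in metrics]
        )
        le["male"] = float(np.mean([x["male"] for x in le_props]))
        le["female"] = float(np.mean([x["female"] for x in le_props]))
        return prev, ineq, le

    rows = []
    # unadjusted row
    prev, ineq, le = pool_block(
        [pt[0] for pt in per_table], [pt[1] for pt in per_table], observed_le
    )
    rows.append(_model_row("unadjusted", le, prev, ineq))

    # CDE row
    prev_cde, ineq_cde, le_cde = pool_block(
        [pt[3].prevalence for pt in per_table],
        [pt[3].inequality for pt in per_table],
        observed_le,
    )
    rows.append(_model_row("CDE", le_cde, prev_cde, ineq_cde))

    # scenario rows
    for j, spec in enumerate(scenarios):
        prev_s, ineq_s, le_s = pool_block(
            [pt[4][j].prevalence for pt in per_table],
            [pt[4][j].inequality for pt in per_table],
            [pt[4][j].post_le_ear for pt in per_table],
        )
        pct = {
            key: 100.0 * (prev_s[key] - prev_cde[key]) / prev_cde[key]
            for key in ("overall", "low", "mid", "high")
        }
        rows.append(_model_row(spec.name, le_s, prev_s, ineq_s, pct_change=pct))

    model_table = pd.DataFrame(rows, columns=MODEL_TABLE_COLUMNS)
    descriptives = _describe(tables[0])
    log = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "stage_seeds": {s: _stage_seed(config.master_seed, s) for s in _STAGES},
        "n_children": config.n_children,
        "m_imputations": m,
        "obesim_version": __version__,
        "model_rows": [r["model_tag"] for r in rows],
    }
    bundle = ReportBundle(
        descriptives=descriptives,
        model_table=model_table,
        weight_diagnostics=weight_set.diagnostics_frame(),
        log=log,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
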