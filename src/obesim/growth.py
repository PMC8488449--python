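"""Growth-reference utilities: LMS BMI z-scores, centile classification, EARs.

The LMS method summarises a reference BMI distribution at each age and sex by
a Box-Cox power (L), a median (M, kg/m^2) and a coefficient of variation (S).
A measured BMI X is converted to a z-score by

    z = ((X / M)^L - 1) / (L * S)     if L != 0
    z = ln(X / M) / S                 if L == 0

Overweight and obesity are classified on the z-scale with the epidemiological
cut-offs: strictly above the 85th and 95th centiles of the reference
distribution, i.e. z > Phi^-1(0.85) and z > Phi^-1(0.95).

The bundled reference table (``data/lms_toy.tsv``) is a synthetic stand-in
covering ages 2-8 years: the licensed UK90 coefficients are not
redistributable, and nothing downstream depends on their exact values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LMSReference",
    "EARTable",
    "OVERWEIGHT_Z",
    "OBESE_Z",
    "lms_zscore",
    "lms_inverse",
    "classify_bmi_status",
    "ear_lookup",
    "load_toy_lms",
    "load_default_ears",
]

#: z-scale centile cut-offs (85th / 95th centile of the standard normal).
OVERWEIGHT_Z: float = float(norm.ppf(0.85))
OBESE_Z: float = float(norm.ppf(0.95))

SEXES = ("male", "female")


@dataclass(frozen=True)
class LMSReference:
    """Age- and sex-indexed (L, M, S) triples.

    ``table`` has columns (sex, age_years, L, M, S); ages strictly increase
    within each sex, M > 0 and S > 0.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "age_years", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"LMS reference missing columns: {sorted(missing)}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("LMS reference requires M > 0 and S > 0")
        for sex, grp in self.table.groupby("sex"):
            ages = grp["age_years"].to_numpy()
            if not np.all(np.diff(ages) > 0):
                raise ValueError(f"ages must be strictly increasing within sex {sex!r}")

    @classmethod
    def from_file(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path, sep="\t"))

    def to_file(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def lookup(self, age: float, sex: str) -> tuple[float, float, float]:
        """(L, M, S) at ``age`` for ``sex``, linearly interpolated in age."""
        grp = self.table[self.table["sex"] == sex]
        if grp.empty:
            raise KeyError(f"sex {sex!r} not in reference")
        ages = grp["age_years"].to_numpy()
        if age < ages[0] or age > ages[-1]:
            raise ValueError(
                f"age {age} outside reference range [{ages[0]}, {ages[-1]}] for {sex!r}"
            )
        out = tuple(
            float(np.interp(age, ages, grp[col].to_numpy())) for col in ("L", "M", "S")
        )
        return out


@dataclass(frozen=True)
class EARTable:
    """Estimated average requirement (kcal/day) by sex and age."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "age_years", "kcal"}
        if required - set(self.table.columns):
            raise ValueError("EAR table requires columns (sex, age_years, kcal)")
        if (self.table["kcal"] <= 0).any():
            raise ValueError("EAR values must be positive")

    @classmethod
    def from_file(cls, path) -> "EARTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_file(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def lookup(self, sex: str, age: float) -> float:
        hit = self.table[
            (self.table["sex"] == sex) & (self.table["age_years"] == age)
        ]
        if hit.empty:
            raise KeyError(f"no EAR tabulated for sex={sex!r}, age={age}")
        return float(hit["kcal"].iloc[0])

    def by_sex(self, age: float = 3.0) -> dict[str, float]:
        return {sex: self.lookup(sex, age) for sex in SEXES}


def load_toy_lms() -> LMSReference:
    """Bundled synthetic LMS reference (ages 2-8, both sexes)."""
    with importlib.resources.files("obesim.data").joinpath("lms_toy.tsv").open() as fh:
        return LMSReference(pd.read_csv(fh, sep="\t"))


def load_default_ears() -> EARTable:
    """Bundled EAR constants: 1171.0 kcal (boys) / 1076.0 kcal (girls) at 3y."""
    with importlib.resources.files("obesim.data").joinpath("ear.tsv").open() as fh:
        return EARTable(pd.read_csv(fh, sep="\t"))


def lms_zscore(bmi: float, age: float, sex: str, ref: LMSReference) -> float:
    """BMI z-score via the LMS transformation, interpolating the reference in age."""
    if not np.all(np.asarray(bmi) > 0):
        raise ValueError("bmi must be positive")
    L, M, S = ref.lookup(age, sex)
    ratio = np.asarray(bmi, dtype=float) / M
    if L == 0.0:
        z = np.log(ratio) / S
    else:
        z = (ratio**L - 1.0) / (L * S)
    return float(z) if np.isscalar(bmi) else z


def lms_inverse(z: float, age: float, sex: str, ref: LMSReference) -> float:
    """BMI corresponding to a z-score (inverse of :func:`lms_zscore`)."""
    L, M, S = ref.lookup(age, sex)
    z = np.asarray(z, dtype=float)
    if L == 0.0:
        bmi = M * np.exp(S * z)
    else:
        bmi = M * (1.0 + L * S * z) ** (1.0 / L)
    return float(bmi) if bmi.ndim == 0 else bmi


def classify_bmi_status(z) -> np.ndarray | str:
    """Classify a z-score as not_overweight / overweight / obese.

    Obese strictly above the 95th centile, overweight strictly above the 85th
    ("greater than", so a child exactly on a centile is in the lower class).
    """
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("z-scores must be finite")
    out = np.where(arr > OBESE_Z, "obese", np.where(arr > OVERWEIGHT_Z, "overweight", "not_overweight"))
    return str(out) if arr.ndim == 0 else out


def ear_lookup(sex: str, age: float, table: EARTable | None = None) -> float:
    """Tabulated estimated average requirement in kcal/day."""
    if table is None:
        table = load_default_ears()
    return table.lookup(sex, age)
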