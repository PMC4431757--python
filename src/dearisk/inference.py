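"""Correlations, the five regression model specifications, age subgroups
and efficiency-quartile summaries.

The five models all explain BMI (baseline, or yearly change) and are always
adjusted for age and sex (woman = 1, man = 0):

    M1  sex + age + expenditure + intake          (environment only)
    M2  sex + age + efficiency                    (DEA efficiency score)
    M3  sex + age + GPS                           (genetics only)
    M4  sex + age + expenditure + intake + GPS    (environment + genetics)
    M5  sex + age + GPS + efficiency              (genetics vs efficiency)

Fits use the MM-type robust estimator in :mod:`dearisk.robust` by default
(OLS available as an oracle mode); rows with any missing covariate are
dropped listwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import change_analysis_mask
from .robust import RobustLinearModel, RobustRegressionResults

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "CorrelationResult",
    "RegressionFit",
    "pearson_correlation",
    "fit_model",
    "model_comparison",
    "age_subgroup_fits",
    "quartile_summary",
]

#: design-column name -> cohort-table source
_COVARIATE_SOURCES = {
    "sex": "sex",                               # recoded woman=1
    "age": "age",
    "expenditure": "energy_expenditure_mets_h",
    "intake": "energy_intake_kcal",
    "gps": "gps",
    "efficiency": "efficiency",
}

_DEPENDENT_SOURCES = {
    "baseline_bmi": "bmi_baseline",
    "yearly_bmi_change": "yearly_bmi_change",
}


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    dependent: str
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.dependent not in _DEPENDENT_SOURCES:
            raise ValueError(f"unknown dependent {self.dependent!r}")
        unknown = [c for c in self.covariates if c not in _COVARIATE_SOURCES]
        if unknown:
            raise ValueError(f"unknown covariates {unknown}")
        if self.covariates[:2] != ("sex", "age"):
            raise ValueError("all models are adjusted for sex and age")

    def with_dependent(self, dependent: str) -> "ModelSpec":
        return ModelSpec(self.model_id, dependent, self.covariates)


def _specs(dependent: str) -> dict[str, ModelSpec]:
    lists = {
        "M1": ("sex", "age", "expenditure", "intake"),
        "M2": ("sex", "age", "efficiency"),
        "M3": ("sex", "age", "gps"),
        "M4": ("sex", "age", "expenditure", "intake", "gps"),
        "M5": ("sex", "age", "gps", "efficiency"),
    }
    return {k: ModelSpec(k, dependent, v) for k, v in lists.items()}


MODEL_SPECS: dict[str, ModelSpec] = _specs("baseline_bmi")


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    pvalue: float
    n: int


def pearson_correlation(x, y, names: tuple[str, str] = ("x", "y")
                        ) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values; drop missing rows first")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in at least one variable")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(names, float(r), float(p), len(x))


@dataclass
class RegressionFit:
    """One fitted model specification in reporting form."""

    model_id: str
    dependent: str
    results: RobustRegressionResults
    nobs: int

    @property
    def params(self) -> pd.Series:
        return self.results.params

    @property
    def bse(self) -> pd.Series:
        return self.results.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.results.pvalues

    @property
    def rsquared_adj(self) -> float:
        return self.results.rsquared_adj

    def to_frame(self) -> pd.DataFrame:
        """Rows mirroring the published layout: coefficient, SE, p."""
        out = self.results.to_frame()
        out.insert(0, "model", self.model_id)
        out.insert(1, "covariate", out.index)
        return out.reset_index(drop=True)


def _design(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    frame = cohort.copy()
    if spec.dependent == "yearly_bmi_change" and \
            "yearly_bmi_change" not in frame:
        frame["yearly_bmi_change"] = (
            (frame["bmi_followup"] - frame["bmi_baseline"])
            / frame["followup_years"])
    cols = {"__y__": frame[_DEPENDENT_SOURCES[spec.dependent]]}
    for cov in spec.covariates:
        src = frame[_COVARIATE_SOURCES[cov]]
        if cov == "sex":
            sex = src.astype(str)
            bad = ~sex.isin(["M", "F"])
            if bad.any():
                raise ValueError(f"unrecognised sex codes: "
                                 f"{sorted(sex[bad].unique())}")
            src = (sex == "F").astype(float)  # women vs. men contrast
        cols[cov] = pd.to_numeric(src)
    return pd.DataFrame(cols).dropna()


def fit_model(spec: ModelSpec, cohort: pd.DataFrame, method: str = "mm",
              seed: int = 0) -> RegressionFit:
    """Fit one model specification with listwise deletion."""
    data = _design(cohort, spec)
    model = RobustLinearModel.from_dataframe(
        data, "__y__", list(spec.covariates))
    results = model.fit(method=method, seed=seed)
    return RegressionFit(spec.model_id, spec.dependent, results, len(data))


def model_comparison(cohort: pd.DataFrame, dependent: str = "baseline_bmi",
                     method: str = "mm", seed: int = 0
                     ) -> dict[str, RegressionFit]:
    """All five model fits for one dependent variable.

    For the yearly-change outcome the normal-baseline restriction is applied
    first (idempotent if the caller already filtered).
    """
    frame = cohort
    if dependent == "yearly_bmi_change":
        frame = cohort[change_analysis_mask(cohort)].copy()
    return {
        mid: fit_model(spec, frame, method=method, seed=seed)
        for mid, spec in _specs(dependent).items()
    }


def comparison_table(fits: dict[str, RegressionFit]) -> pd.DataFrame:
    """Stack the per-model coefficient tables with adjusted R^2 rows."""
    rows = []
    for mid, fit in fits.items():
        tab = fit.to_frame()
        tab["adj_r2"] = fit.rsquared_adj
        tab["n"] = fit.nobs
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def age_subgroup_fits(cohort: pd.DataFrame, cutoff: int = 60,
                      dependent: str = "baseline_bmi", method: str = "mm",
                      seed: int = 0) -> dict[str, RegressionFit]:
    """M5 (sex + age + GPS + efficiency) fit separately below/at the cutoff."""
    spec = _specs(dependent)["M5"]
    young = cohort[cohort["age"] < cutoff]
    old = cohort[cohort["age"] >= cutoff]
    out = {}
    for label, stratum in ((f"age<{cutoff}", young), (f"age>={cutoff}", old)):
        if len(stratum) == 0:
            raise ValueError(f"empty age stratum {label!r}")
        out[label] = fit_model(spec, stratum, method=method, seed=seed)
    return out


def quartile_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean DEA inputs by efficiency-score quartile.

    Subjects are ranked by efficiency (stable subject-id tie-break) and cut
    into four nearly equal groups (sizes differ by at most one); the mean
    expenditure and mean inverse intake of each group are reported.
    """
    if "efficiency" not in cohort:
        raise ValueError("cohort lacks an 'efficiency' column")
    n = len(cohort)
    if n < 4:
        raise ValueError("need at least 4 subjects for quartiles")
    ordered = cohort.sort_values(
        ["efficiency", "subject_id"], kind="mergesort")
    groups = np.array_split(np.arange(n), 4)
    records = []
    for q, idx in enumerate(groups, start=1):
        block = ordered.iloc[idx]
        records.append({
            "quartile": f"Q{q}",
            "n": len(block),
            "mean_efficiency": block["efficiency"].mean(),
            "mean_expenditure_mets_h": block["energy_expenditure_mets_h"].mean(),
            "mean_inverse_intake": (1.0 / block["energy_intake_kcal"]).mean(),
        })
    return pd.DataFrame(records)
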