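"""Validity, condition-effect and clinical-association statistics.

Three analyses mirror a validation-study design:

* ``validity`` — Pearson correlation and absolute differences between the
  pipeline's gait metrics and matched reference values (here, simulator
  ground truth standing in for a gold-standard system).
* ``condition_anova`` — effect of walking condition (single vs dual task)
  on a gait metric, adjusted for age, sex and years of education, as an
  ANCOVA on stacked participant-condition rows.
* ``adjusted_association`` — standardized association between a gait metric
  and a clinical score (UPDRS III, MoCA, HAM-A, HAM-D), adjusted for the
  same covariates.  Outcome and metric are z-scored so the reported beta is
  a standardized coefficient; covariates enter raw.

Rows are treated as independent (no repeated-measures correction) and no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sstats

from .errors import StatsError

COVARIATES = ("age", "sex", "education")


@dataclass
class ValidityResult:
    metric: str
    condition: str
    pearson_r: float
    p_value: float
    mean_abs_diff: float
    sd_abs_diff: float
    n: int

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "condition": self.condition,
            "r": float(self.pearson_r),
            "p": float(self.p_value),
            "mean_abs_diff": float(self.mean_abs_diff),
            "sd_abs_diff": float(self.sd_abs_diff),
            "n": int(self.n),
        }


@dataclass
class ModelResult:
    outcome: str
    predictor: str
    beta_std: float
    F: float
    df1: int
    df2: int
    p_value: float
    covariates: list = field(default_factory=lambda: list(COVARIATES))
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "beta_std": float(self.beta_std),
            "F": float(self.F),
            "df1": int(self.df1),
            "df2": int(self.df2),
            "p": float(self.p_value),
            "covariates": list(self.covariates),
            "n_dropped": int(self.n_dropped),
        }


def validity(
    app_values: np.ndarray,
    ref_values: np.ndarray,
    metric: str = "",
    condition: str = "",
) -> ValidityResult:
    """Pearson r (two-sided) plus mean and SD of |app - reference|."""
    app = np.asarray(app_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if app.shape != ref.shape or app.ndim != 1:
        raise StatsError("app and reference vectors must be matched 1-D arrays")
    if len(app) < 3:
        raise StatsError("need at least 3 matched pairs")
    if np.std(app) == 0 or np.std(ref) == 0:
        raise StatsError("Pearson r undefined: zero variance in one vector")
    res = sstats.pearsonr(app, ref)
    diff = np.abs(app - ref)
    return ValidityResult(
        metric=metric,
        condition=condition,
        pearson_r=float(res.statistic),
        p_value=float(res.pvalue),
        mean_abs_diff=float(np.mean(diff)),
        sd_abs_diff=float(np.std(diff, ddof=1)),
        n=len(app),
    )


def condition_anova(long_table: pd.DataFrame, metric: str) -> ModelResult:
    """Condition effect on a metric, adjusted for age, sex and education.

    ``long_table`` has one row per participant-condition with columns
    ``condition`` plus the covariates.  Returns the F test of the condition
    term from a type-II ANOVA of the linear model
    ``metric ~ condition + age + sex + education``.
    """
    required = {metric, "condition", *COVARIATES}
    missing = required - set(long_table.columns)
    if missing:
        raise StatsError(f"long table is missing columns {sorted(missing)}")
    if long_table["condition"].nunique() < 2:
        raise StatsError("both walking conditions must be present")
    df = long_table.dropna(subset=sorted(required)).copy()
    n_dropped = len(long_table) - len(df)
    model = smf.ols(f"{metric} ~ C(condition) + age + sex + education", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(condition)"]
    # direction: positive beta means dual > single (dual sorts after single)
    beta = float(model.params.get("C(condition)[T.single_task]", np.nan))
    if not np.isnan(beta):
        beta = -beta  # re-express as dual minus single
    else:
        beta = float(model.params.get("C(condition)[T.dual_task]", np.nan))
    return ModelResult(
        outcome=metric,
        predictor="condition",
        beta_std=beta,  # raw dual-minus-single difference, metric units
        F=float(row["F"]),
        df1=int(row["df"]),
        df2=int(table.loc["Residual", "df"]),
        p_value=float(row["PR(>F)"]),
        n_dropped=n_dropped,
    )


def adjusted_association(
    cohort: pd.DataFrame,
    gait_metric: str,
    clinical_score: str,
) -> ModelResult:
    """Standardized association of a gait metric with a clinical score.

    Fits ``z(score) ~ z(metric) + age + sex + education`` on complete rows
    and reports the standardized coefficient of the metric with its partial
    F (= t^2) test.
    """
    required = {gait_metric, clinical_score, *COVARIATES}
    missing = required - set(cohort.columns)
    if missing:
        raise StatsError(f"cohort table is missing columns {sorted(missing)}")
    df = cohort.dropna(subset=sorted(required)).copy()
    n_dropped = len(cohort) - len(df)
    if len(df) < 10:
        raise StatsError("need at least 10 complete rows for the regression")
    for col in (gait_metric, clinical_score):
        if np.std(df[col]) == 0:
            raise StatsError(f"{col} is constant; standardized beta undefined")
    df["_metric_z"] = (df[gait_metric] - df[gait_metric].mean()) / df[gait_metric].std(ddof=1)
    df["_score_z"] = (df[clinical_score] - df[clinical_score].mean()) / df[clinical_score].std(ddof=1)
    model = smf.ols("_score_z ~ _metric_z + age + sex + education", data=df).fit()
    t = float(model.tvalues["_metric_z"])
    return ModelResult(
        outcome=clinical_score,
        predictor=gait_metric,
        beta_std=float(model.params["_metric_z"]),
        F=t * t,
        df1=1,
        df2=int(model.df_resid),
        p_value=float(model.pvalues["_metric_z"]),
        n_dropped=n_dropped,
    )
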