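"""Cross-sectional association models for the brain-age gap.

All models are ordinary least squares on complete cases, with
chronological age, sex, scanner (single numeric site code) and APOE
status (ordinal allele count) controlled throughout; cognition models
additionally control education.  Confidence intervals are classical
t-based 95% intervals.

Model battery:

* ANCOVA — adjusted group difference in WMBAG (healthy vs unhealthy);
* model 1a — VRS dummies (1, 2, >=3 vs 0) on WMBAG;
* model 1b — 1a plus sex x VRS-level interactions, with a delta-method
  within-level sex contrast;
* model 2a — all five risk factors simultaneously;
* models 2b-f — one sex x factor interaction at a time, added to the
  full-factor model;
* cognition regressions — WMBAG against each of four outcomes (speed,
  executive, memory, global), Bonferroni-controlled at 0.05/4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .imgio import RISK_FACTORS

__all__ = [
    "RegressionResult",
    "DEFAULT_COVARIATES",
    "COGNITION_OUTCOMES",
    "BONFERRONI_ALPHA",
    "ancova_group_difference",
    "fit_model_1a",
    "fit_model_1b",
    "fit_model_2a",
    "fit_models_2b_f",
    "vrs_level_sex_contrast",
    "cognition_regressions",
]

DEFAULT_COVARIATES = ("age", "sex", "scanner", "apoe_e4_count")
COGNITION_OUTCOMES = ("speed", "executive", "memory", "global_cognition")
#: Four cognitive outcomes per family.
BONFERRONI_ALPHA = 0.05 / len(COGNITION_OUTCOMES)


@dataclass
class RegressionResult:
    model_name: str
    terms: pd.DataFrame  # index: term; columns: beta, ci_low, ci_high, p
    n_used: int
    sm_result: object = field(default=None, repr=False)

    def beta(self, term: str) -> float:
        return float(self.terms.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.sm_result.bse[term])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


def _fit_ols(df: pd.DataFrame, outcome: str, terms: list[str], name: str) -> RegressionResult:
    cols = [outcome, *terms]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{name}: missing columns {missing_cols}")
    data = df[cols].dropna()
    if len(data) <= len(terms) + 1:
        raise ValueError(f"{name}: too few complete cases (n={len(data)})")
    for t in terms:
        if data[t].nunique() < 2:
            raise ValueError(f"{name}: term {t!r} is constant after complete-case filtering")
    X = sm.add_constant(data[terms].astype(float))
    fit = sm.OLS(data[outcome].astype(float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "beta": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    return RegressionResult(
        model_name=name, terms=table, n_used=int(fit.nobs), sm_result=fit
    )


def _with_interactions(df: pd.DataFrame, pairs: list[tuple[str, str]]) -> tuple[pd.DataFrame, list[str]]:
    out = df.copy()
    names = []
    for a, b in pairs:
        name = f"{a}_x_{b}"
        out[name] = out[a] * out[b]
        names.append(name)
    return out, names


def ancova_group_difference(
    df: pd.DataFrame,
    outcome: str = "wmbag",
    group: str = "health_status",
    covariates=DEFAULT_COVARIATES,
) -> RegressionResult:
    """Adjusted two-group mean difference via the linear-model ANCOVA.

    The group column may be two string labels or 0/1; the reported term
    ``group`` is the adjusted difference (second level minus first,
    levels sorted).  With no covariates this reduces to the two-sample
    t-test difference.
    """
    data = df.copy()
    levels = sorted(data[group].dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"ANCOVA needs exactly two groups, got {levels}")
    data["group"] = (data[group] == levels[1]).astype(float)
    data.loc[data[group].isna(), "group"] = np.nan
    complete = data[[outcome, "group", *covariates]].dropna()
    for lv in (0.0, 1.0):
        if not (complete["group"] == lv).any():
            raise ValueError(
                f"group {levels[int(lv)]!r} empty after complete-case filtering"
            )
    res = _fit_ols(data, outcome, ["group", *covariates], "ancova")
    return res


def fit_model_1a(df: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> RegressionResult:
    """Main effect of the VRS categories (dummy-coded vs 0) on WMBAG."""
    return _fit_ols(df, "wmbag", ["vrs_1", "vrs_2", "vrs_3", *covariates], "model_1a")


def fit_model_1b(df: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> RegressionResult:
    """Model 1a plus sex x VRS-level interaction terms."""
    data, inter = _with_interactions(df, [(f"vrs_{k}", "sex") for k in (1, 2, 3)])
    return _fit_ols(
        data, "wmbag", ["vrs_1", "vrs_2", "vrs_3", *covariates, *inter], "model_1b"
    )


def vrs_level_sex_contrast(result: RegressionResult, level: int) -> dict:
    """Male-female WMBAG difference at a given VRS level (delta method).

    In model 1b the difference at level k is beta_sex + beta_{vrs_k x sex};
    the standard error follows from the coefficient covariance matrix.
    """
    fit = result.sm_result
    names = list(fit.params.index)
    vec = np.zeros(len(names))
    vec[names.index("sex")] = 1.0
    if level > 0:
        vec[names.index(f"vrs_{level}_x_sex")] = 1.0
    est = float(vec @ fit.params.to_numpy())
    se = float(np.sqrt(vec @ fit.cov_params().to_numpy() @ vec))
    from scipy import stats

    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df=fit.df_resid)
    return {"level": level, "difference": est, "se": se, "t": t, "p": p}


def fit_model_2a(df: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> RegressionResult:
    """All five risk factors simultaneously: unique contributions."""
    return _fit_ols(df, "wmbag", [*RISK_FACTORS, *covariates], "model_2a")


def fit_models_2b_f(
    df: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> dict[str, RegressionResult]:
    """Sex-moderation models: one factor x sex interaction at a time.

    Each model keeps all five factors and covariates and adds the
    single interaction; a single-level sex column is unidentifiable.
    """
    if df["sex"].dropna().nunique() < 2:
        raise ValueError("sex has a single level; interactions unidentifiable")
    out = {}
    for k in RISK_FACTORS:
        data, inter = _with_interactions(df, [(k, "sex")])
        out[k] = _fit_ols(
            data, "wmbag", [*RISK_FACTORS, *covariates, *inter], f"model_2_{k}"
        )
    return out


def cognition_regressions(
    df: pd.DataFrame,
    outcomes=COGNITION_OUTCOMES,
    covariates=(*DEFAULT_COVARIATES, "education_college"),
) -> tuple[pd.DataFrame, dict[str, RegressionResult]]:
    """WMBAG-cognition regressions with Bonferroni control at 0.05/4.

    Returns a summary table (one row per outcome: WMBAG beta, CI, p,
    Bonferroni flag) and the full per-outcome results.  An outcome that
    is absent or entirely missing is skipped with a warning.
    """
    rows = []
    results = {}
    alpha = 0.05 / len(outcomes)
    for outcome in outcomes:
        if outcome not in df.columns or df[outcome].dropna().empty:
            warnings.warn(f"cognition outcome {outcome!r} unavailable; skipped", stacklevel=2)
            continue
        res = _fit_ols(df, outcome, ["wmbag", *covariates], f"cognition_{outcome}")
        results[outcome] = res
        rows.append(
            {
                "outcome": outcome,
                "beta_wmbag": res.beta("wmbag"),
                "ci_low": float(res.terms.loc["wmbag", "ci_low"]),
                "ci_high": float(res.terms.loc["wmbag", "ci_high"]),
                "p": res.p("wmbag"),
                "bonferroni_alpha": alpha,
                "significant_bonferroni": res.p("wmbag") < alpha,
                "n_used": res.n_used,
            }
        )
    return pd.DataFrame(rows), results
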