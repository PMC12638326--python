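"""Two-timepoint change analysis.

Change scores are follow-up minus baseline (gap, predicted age, and
per-domain cognition), computed only for participants present at both
timepoints; unmatched rows are excluded with a log entry.  The mean
change in gap is tested with a classical dependent (paired) t-test —
algebraically the one-sample t-test on the differences — and the
cross-sectional association and mediation machinery is reused with
change scores as mediator/outcomes.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, mediate
from .imgio import RISK_FACTORS

__all__ = [
    "change_scores",
    "paired_t",
    "percent_increased",
    "change_regressions_and_mediation",
]

log = logging.getLogger(__name__)

_COG_DOMAINS = ("speed", "memory", "executive", "global_cognition")


def change_scores(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    cognition_baseline: pd.DataFrame | None = None,
    cognition_followup: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Follow-up minus baseline deltas for matched participants.

    ``baseline``/``followup`` are prediction frames with participant_id,
    y (age), y_hat_co and wmbag; optional cognition frames carry domain
    scores.  Row order of the inputs is irrelevant.
    """
    cols = ["participant_id", "y", "y_hat_co", "wmbag"]
    merged = baseline[cols].merge(
        followup[cols], on="participant_id", suffixes=("_bl", "_fu")
    )
    unmatched = len(baseline) + len(followup) - 2 * len(merged)
    if unmatched:
        log.info("excluded %d unmatched timepoint rows from change scores", unmatched)
    out = pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "interval": merged["y_fu"] - merged["y_bl"],
            "delta_wmbag": merged["wmbag_fu"] - merged["wmbag_bl"],
            "delta_predicted_age": merged["y_hat_co_fu"] - merged["y_hat_co_bl"],
        }
    )
    if cognition_baseline is not None and cognition_followup is not None:
        cb = cognition_baseline.set_index("participant_id")
        cf = cognition_followup.set_index("participant_id")
        for d in _COG_DOMAINS:
            if d in cb.columns and d in cf.columns:
                delta = (cf[d] - cb[d]).reindex(out["participant_id"]).to_numpy()
                out[f"delta_{d}"] = delta
    return out.sort_values("participant_id").reset_index(drop=True)


class PairedT(NamedTuple):
    t: float
    df: int
    p: float
    mean_change: float


def paired_t(before, after=None) -> PairedT:
    """Dependent t-test; pass differences directly or (before, after)."""
    if after is None:
        diffs = np.asarray(before, dtype=np.float64)
    else:
        before = np.asarray(before, dtype=np.float64)
        after = np.asarray(after, dtype=np.float64)
        if before.shape != after.shape:
            raise ValueError("paired samples must have equal length")
        diffs = after - before
    if diffs.size < 2:
        raise ValueError("need at least two pairs")
    if np.var(diffs, ddof=1) == 0:
        raise ValueError("zero variance in paired differences; t undefined")
    res = stats.ttest_1samp(diffs, 0.0)
    return PairedT(
        t=float(res.statistic),
        df=int(diffs.size - 1),
        p=float(res.pvalue),
        mean_change=float(diffs.mean()),
    )


def percent_increased(delta_predicted_age) -> float:
    """Percentage of participants whose predicted age rose (reported only)."""
    d = np.asarray(delta_predicted_age, dtype=np.float64)
    return float(100.0 * np.mean(d > 0)) if d.size else np.nan


def change_regressions_and_mediation(
    baseline_records: pd.DataFrame,
    changes: pd.DataFrame,
    covariates=assoc.DEFAULT_COVARIATES,
    n_boot: int = 1000,
    seed: int = 0,
    do_mediation: bool = True,
) -> dict[str, pd.DataFrame]:
    """Factor -> delta-gap regressions, delta-gap -> delta-cognition
    regressions, and the change mediation battery.

    ``baseline_records`` supplies the factors and covariates; an empty
    longitudinal subset yields empty tables and a clean exit.  The
    follow-up interval is not used as a covariate.
    """
    if changes.empty:
        return {
            "factor_regressions": pd.DataFrame(),
            "cognition_change_regressions": pd.DataFrame(),
            "change_mediation": pd.DataFrame(),
        }
    df = baseline_records.merge(changes, on="participant_id")

    # baseline factors -> change in gap (all five factors jointly)
    res = assoc._fit_ols(
        df, "delta_wmbag", [*RISK_FACTORS, *covariates], "change_model_factors"
    )
    factor_table = res.terms.assign(n_used=res.n_used).reset_index(names="term")

    # change in gap -> change in cognition
    rows = []
    cog_deltas = [f"delta_{d}" for d in _COG_DOMAINS if f"delta_{d}" in df.columns]
    for dc in cog_deltas:
        r = assoc._fit_ols(df, dc, ["delta_wmbag", *covariates], f"change_{dc}")
        rows.append(
            {
                "outcome": dc,
                "beta_delta_wmbag": r.beta("delta_wmbag"),
                "ci_low": float(r.terms.loc["delta_wmbag", "ci_low"]),
                "ci_high": float(r.terms.loc["delta_wmbag", "ci_high"]),
                "p": r.p("delta_wmbag"),
                "n_used": r.n_used,
            }
        )
    cognition_table = pd.DataFrame(rows)

    needed = 10 * (len(covariates) + 2)
    run_med = do_mediation and cog_deltas and len(df) >= needed
    if do_mediation and cog_deltas and not run_med:
        log.warning(
            "skipping change mediation: %d pairs < %d required", len(df), needed
        )
    med = (
        mediate.mediation_battery(
            df,
            outcomes=tuple(cog_deltas),
            mediator="delta_wmbag",
            covariates=covariates,
            n_boot=n_boot,
            seed=seed,
        )
        if run_med
        else pd.DataFrame()
    )
    return {
        "factor_regressions": factor_table,
        "cognition_change_regressions": cognition_table,
        "change_mediation": med,
    }
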