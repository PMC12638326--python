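"""Vascular risk score, APOE coding, and cognition composites.

The composite vascular risk score (VRS) counts the five binary factors
(hypertension, diabetes, hypercholesterolemia, obesity, smoking) and is
categorised 0 / 1 / 2 / >=3, dummy-coded against the 0 reference level.
A participant missing any factor has a missing VRS (complete case).

APOE e4 status is three-level: non-carrier, one allele, two alleles.

Cognition: seven tests are z-scored against a reference sample with the
sign flipped for tests where a higher raw score means worse performance
(reaction time, both trail-making tests, pairs-matching errors), so
higher always means better.  Domains are available-case means of their
constituent tests — processing speed: reaction time, trail making A,
symbol digit substitution; memory: numeric memory, pairs matching;
executive function: trail making B, fluid intelligence — and global
cognition is the mean of the three domain scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgio import RISK_FACTORS
from .synth import DOMAIN_TESTS, _REVERSED_TESTS

__all__ = [
    "VRSRecord",
    "compute_vrs",
    "compute_vrs_frame",
    "encode_apoe",
    "encode_apoe_series",
    "standardise_cognition",
    "SIGN_CONVENTIONS",
    "VRS_CATEGORIES",
]

VRS_CATEGORIES = ("0", "1", "2", "3plus")

#: True where a higher raw score means worse performance (sign flipped).
SIGN_CONVENTIONS: dict[str, bool] = {
    t: (t in _REVERSED_TESTS) for d in DOMAIN_TESTS.values() for t in d
}


@dataclass
class VRSRecord:
    factor_count: float  # 0-5 or NaN
    category: str | float  # "0"/"1"/"2"/"3plus" or NaN
    dummies: tuple[float, float, float]  # (vrs_1, vrs_2, vrs_3)


def compute_vrs(risk_factors) -> VRSRecord:
    """Score one participant's five factor slots ({0, 1, NaN} each)."""
    vals = (
        [risk_factors.get(k, np.nan) for k in RISK_FACTORS]
        if isinstance(risk_factors, dict)
        else list(risk_factors)
    )
    if len(vals) != 5:
        raise ValueError("expected five risk factor slots")
    arr = np.asarray(vals, dtype=np.float64)
    if not np.all(np.isnan(arr) | np.isin(arr, (0.0, 1.0))):
        raise ValueError("risk factors must be 0, 1 or missing")
    if np.isnan(arr).any():
        return VRSRecord(np.nan, np.nan, (np.nan, np.nan, np.nan))
    count = int(arr.sum())
    cat = VRS_CATEGORIES[min(count, 3)]
    dummies = tuple(float(cat == c) for c in VRS_CATEGORIES[1:])
    return VRSRecord(float(count), cat, dummies)


def compute_vrs_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised VRS for a cohort frame carrying the five factor columns.

    Returns columns vrs_count, vrs_category, vrs_1, vrs_2, vrs_3 (all
    NaN for participants with any missing factor).
    """
    F = records[list(RISK_FACTORS)].to_numpy(dtype=np.float64)
    bad = ~(np.isnan(F) | np.isin(F, (0.0, 1.0)))
    if bad.any():
        raise ValueError("risk factors must be 0, 1 or missing")
    complete = ~np.isnan(F).any(axis=1)
    count = np.where(complete, F.sum(axis=1), np.nan)
    capped = np.minimum(count, 3)
    out = pd.DataFrame(index=records.index)
    out["vrs_count"] = count
    out["vrs_category"] = pd.Series(
        np.where(complete, capped, np.nan), index=records.index
    ).map(lambda v: VRS_CATEGORIES[int(v)] if not np.isnan(v) else np.nan)
    for level in (1, 2, 3):
        out[f"vrs_{level}"] = np.where(complete, (capped == level).astype(float), np.nan)
    return out


_APOE_LABELS = {0: "non_carrier", 1: "one_allele", 2: "two_alleles"}


def encode_apoe(e4_count) -> str | float:
    """Three-level carrier status from the e4 allele count (0/1/2)."""
    if e4_count is None or (isinstance(e4_count, float) and np.isnan(e4_count)):
        return np.nan
    c = int(e4_count)
    if c != e4_count or c not in _APOE_LABELS:
        raise ValueError(f"APOE e4 allele count must be 0, 1 or 2, got {e4_count!r}")
    return _APOE_LABELS[c]


def encode_apoe_series(counts: pd.Series) -> pd.Series:
    return counts.map(encode_apoe)


def standardise_cognition(
    raw: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Domain and global cognition z-composites from raw test scores.

    Each test is z-scored against the reference sample (default: the
    supplied sample itself, i.e. the full analysis sample at baseline),
    with the sign flipped for the reversed tests; z-scores are invariant
    to common rescaling of raw scores and reference spread.  A domain
    with all constituents missing is missing.  Returns columns speed,
    memory, executive, global_cognition (plus any id columns carried
    through).
    """
    reference = raw if reference is None else reference
    id_cols = [c for c in ("participant_id", "timepoint") if c in raw.columns]
    out = raw[id_cols].copy() if id_cols else pd.DataFrame(index=raw.index)
    domain_scores = {}
    for domain, tests in DOMAIN_TESTS.items():
        zs = []
        for t in tests:
            if t not in raw.columns:
                continue
            mu = reference[t].mean()
            sd = reference[t].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"reference sample has zero spread for test {t!r}")
            z = (raw[t] - mu) / sd
            if SIGN_CONVENTIONS[t]:
                z = -z
            zs.append(z)
        if not zs:
            domain_scores[domain] = pd.Series(np.nan, index=raw.index)
        else:
            domain_scores[domain] = pd.concat(zs, axis=1).mean(axis=1)  # available-case
    for d in ("speed", "memory", "executive"):
        out[d] = domain_scores[d]
    out["global_cognition"] = pd.concat(
        [domain_scores[d] for d in ("speed", "memory", "executive")], axis=1
    ).mean(axis=1)
    return out
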