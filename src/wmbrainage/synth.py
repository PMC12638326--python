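"""Synthetic diffusion-MRI cohort with a known planted effect structure.

The generator emulates the statistical skeleton of a large ageing cohort
(ages ~45-83, three scanner sites, five binary vascular risk factors,
APOE e4 allele counts, education, seven cognitive tests, a two-timepoint
longitudinal subset with ~2.25-year intervals) together with five
co-registered 3D "diffusion" maps per participant whose intensities
drift smoothly with an *effective age* = chronological age + planted
brain-age gap.

The planted gap is additive over active risk factors — largest for
diabetes, then hypertension, then smoking — plus a male-only obesity
interaction and Gaussian individual noise, so downstream regression,
interaction and mediation machinery can be validated by parameter
recovery against known truth.  Cognition carries a mediation structure:
risk factor -> latent gap -> cognition, plus optional direct paths.

No anatomical realism is attempted: maps are sums of a few smooth
spatial basis blobs with age-dependent amplitudes (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .imgio import COGNITION_TESTS, MAP_NAMES, RISK_FACTORS, DwiMapSet

__all__ = [
    "SynthConfig",
    "CognitionPaths",
    "ParticipantRecord",
    "LatentTruth",
    "ConfigError",
    "simulate_cohort",
    "render_maps",
    "render_cohort",
    "simulate_cognition",
    "make_longitudinal_subset",
    "make_splits",
    "latent_predictions",
]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


# ---------------------------------------------------------------------------
# Configuration

def _default_prevalences() -> dict[str, float]:
    # Cohort prevalences of the five factors in a typical mid-to-late-life
    # community sample (fractions of participants with the factor present).
    return {
        "hypertension": 0.504,
        "diabetes": 0.055,
        "hypercholesterolemia": 0.245,
        "obesity": 0.190,
        "smoking": 0.381,
    }


def _default_offsets() -> dict[str, float]:
    # Years of planted brain-age acceleration per active factor.  Diabetes
    # carries the largest offset, then hypertension, then smoking; the
    # obesity main effect is zero (its damage is male-only, see
    # sex_obesity_interaction).
    return {
        "hypertension": 0.871,
        "diabetes": 1.390,
        "hypercholesterolemia": 0.311,
        "obesity": 0.0,
        "smoking": 0.689,
    }


def _default_map_noise() -> dict[str, float]:
    return {m: 0.02 for m in MAP_NAMES}


@dataclass
class CognitionPaths:
    """Path coefficients of the planted mediation structure.

    Domain scores are generated on a z-like scale as

        L_d = -b_d * true_gap - sum_k c'_{k,d} * factor_k
              + age_beta * (age - 64) + sex_beta * male
              + edu_beta * college + N(0, domain_noise_sd)

    and each constituent test adds N(0, test_noise_sd) on top, so higher
    always means better before the per-test sign conventions are applied.
    """

    b: dict[str, float] = field(
        default_factory=lambda: {"speed": 0.025, "memory": 0.008, "executive": 0.018}
    )
    c_prime: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "obesity": {"speed": 0.103},
            "smoking": {"executive": 0.05, "memory": 0.02},
        }
    )
    age_beta: float = -0.02
    sex_beta: float = 0.0
    edu_beta: float = 0.25
    domain_noise_sd: float = 0.85
    test_noise_sd: float = 0.4


@dataclass
class SynthConfig:
    """Full description of one synthetic cohort.

    Identical config + seed reproduces the cohort, maps and splits
    byte-identically; all randomness is derived from ``seed``.
    """

    n_participants: int = 2000
    age_range: tuple[float, float] = (45.0, 83.0)
    grid_shape: tuple[int, int, int] = (24, 28, 24)

    risk_prevalences: dict[str, float] = field(default_factory=_default_prevalences)
    risk_age_offsets: dict[str, float] = field(default_factory=_default_offsets)
    sex_obesity_interaction: float = 1.0
    vrs3plus_sex_offset: float = 0.0
    # individual gap heterogeneity beyond the planted risk offsets; the
    # default puts the corrected-gap dispersion near the ~3.5 y seen in
    # large-cohort brain-age work once prediction error is added
    gap_noise_sd: float = 3.2

    male_fraction: float = 0.458
    college_fraction: float = 0.491
    apoe_probs: tuple[float, float, float] = (0.722, 0.255, 0.023)
    unhealthy_fraction: float = 0.09
    unhealthy_extra_gap: float = 0.5
    missing_rate_risk: float = 0.0
    missing_rate_apoe: float = 0.0

    noise_sd_map: dict[str, float] = field(default_factory=_default_map_noise)
    shared_noise_sd: float = 0.01
    map_age_slopes: dict[str, float] = field(
        default_factory=lambda: {"FA": -0.003, "MD": 0.004, "AxD": 0.0035, "RD": 0.0045}
    )
    mo_curvature: float = -2e-4  # per year^2; tensor-mode analogue is nonmonotone

    cognition_paths: CognitionPaths = field(default_factory=CognitionPaths)

    longitudinal_fraction: float = 0.1262
    interval_years: tuple[float, float] = (2.25, 0.12)
    followup_gap_drift: float = 0.1
    followup_gap_drift_sd: float = 0.2

    # Latent-shortcut predictor emulation (bypasses the CNN): the emulated
    # raw prediction is shrunk towards the cohort centre with this slope
    # (regression dilution) and carries additive Gaussian error.
    pred_slope: float = 0.7
    pred_noise_sd: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range low must be < high")
        if any(g < 1 for g in self.grid_shape) or len(self.grid_shape) != 3:
            raise ConfigError("grid_shape must be three positive voxel counts")
        for k in RISK_FACTORS:
            p = self.risk_prevalences.get(k)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence for {k!r} must be in [0, 1]")
            if k not in self.risk_age_offsets:
                raise ConfigError(f"missing age offset for {k!r}")
        if not 0.0 <= self.longitudinal_fraction <= 1.0:
            raise ConfigError("longitudinal_fraction must be in [0, 1]")
        for r in (self.missing_rate_risk, self.missing_rate_apoe):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("missing rates must be in [0, 1]")
        if abs(sum(self.apoe_probs) - 1.0) > 1e-9:
            raise ConfigError("apoe_probs must sum to 1")

    @property
    def age_centre(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


# ---------------------------------------------------------------------------
# Row-level views (convenience dataclasses over the frame representation)

@dataclass
class ParticipantRecord:
    participant_id: str
    timepoint: str
    chronological_age: float
    sex: int
    scanner: int
    icv: float
    risk_factors: dict[str, float]
    apoe_e4_count: float
    education_college: int
    health_status: str

    @classmethod
    def from_row(cls, row: Mapping) -> "ParticipantRecord":
        return cls(
            participant_id=row["participant_id"],
            timepoint=row["timepoint"],
            chronological_age=row["age"],
            sex=int(row["sex"]),
            scanner=int(row["scanner"]),
            icv=float(row["icv"]),
            risk_factors={k: row[k] for k in RISK_FACTORS},
            apoe_e4_count=row["apoe_e4_count"],
            education_college=int(row["education_college"]),
            health_status=row["health_status"],
        )


@dataclass
class LatentTruth:
    participant_id: str
    timepoint: str
    true_gap: float

    @classmethod
    def from_row(cls, row: Mapping) -> "LatentTruth":
        return cls(row["participant_id"], row["timepoint"], row["true_gap"])


# ---------------------------------------------------------------------------
# Cohort metadata

def _rng(config: SynthConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


def _participant_index(participant_id: str) -> int:
    return int(participant_id.lstrip("S"))


def simulate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw cohort metadata and the latent planted brain-age gaps.

    Returns ``(records, truth)``: one baseline row per participant in
    each frame, joined on ``participant_id`` x ``timepoint``.  Risk
    factors are independent Bernoulli draws at the configured
    prevalences; the planted gap is

        true_gap = sum_k factor_k * offset_k
                   + male * obesity * sex_obesity_interaction
                   + male * 1[count >= 3] * vrs3plus_sex_offset
                   + unhealthy * unhealthy_extra_gap
                   + N(0, gap_noise_sd)

    Missing-at-random masks (rates configurable, default 0) apply only
    to the *recorded* factor and APOE values, never to the truth.
    """
    n = config.n_participants
    rng = _rng(config, 1)
    lo, hi = config.age_range

    age = rng.uniform(lo, hi, n)
    sex = (rng.random(n) < config.male_fraction).astype(int)
    scanner = rng.integers(0, 3, n)
    icv = rng.normal(1500.0, 150.0, n)
    college = (rng.random(n) < config.college_fraction).astype(int)
    apoe = rng.choice([0, 1, 2], size=n, p=list(config.apoe_probs))
    unhealthy = rng.random(n) < config.unhealthy_fraction

    factors_true = {
        k: (rng.random(n) < config.risk_prevalences[k]).astype(float)
        for k in RISK_FACTORS
    }
    count = sum(factors_true.values())

    gap = np.zeros(n)
    for k in RISK_FACTORS:
        gap += factors_true[k] * config.risk_age_offsets[k]
    gap += sex * factors_true["obesity"] * config.sex_obesity_interaction
    gap += sex * (count >= 3) * config.vrs3plus_sex_offset
    gap += unhealthy * config.unhealthy_extra_gap
    gap += rng.normal(0.0, config.gap_noise_sd, n)

    records = pd.DataFrame(
        {
            "participant_id": [f"S{i:05d}" for i in range(n)],
            "timepoint": "baseline",
            "age": age,
            "sex": sex,
            "scanner": scanner,
            "icv": icv,
            "apoe_e4_count": apoe.astype(float),
            "education_college": college,
            "health_status": np.where(unhealthy, "unhealthy", "healthy"),
        }
    )
    for k in RISK_FACTORS:
        rec = factors_true[k].copy()
        if config.missing_rate_risk > 0:
            rec[rng.random(n) < config.missing_rate_risk] = np.nan
        records[k] = rec
    if config.missing_rate_apoe > 0:
        mask = rng.random(n) < config.missing_rate_apoe
        records.loc[mask, "apoe_e4_count"] = np.nan
    records = records[
        [
            "participant_id",
            "timepoint",
            "age",
            "sex",
            "scanner",
            "icv",
            *RISK_FACTORS,
            "apoe_e4_count",
            "education_college",
            "health_status",
        ]
    ]

    truth = pd.DataFrame(
        {
            "participant_id": records["participant_id"],
            "timepoint": "baseline",
            "true_gap": gap,
        }
    )
    for k in RISK_FACTORS:  # truth keeps the pre-missingness factor values
        truth[f"true_{k}"] = factors_true[k]
    return records, truth


# ---------------------------------------------------------------------------
# Map rendering

# Fixed blob geometry (fractional centres / widths) shared by all cohorts so
# that volumes are comparable across configs; per-map coupling weights give
# each map its own spatial age pattern.  The pattern components are mean-free
# so the configured slope is exactly the slope of the voxel-mean intensity.
_BLOB_CENTRES = np.array(
    [
        [0.30, 0.35, 0.40],
        [0.70, 0.30, 0.55],
        [0.45, 0.70, 0.35],
        [0.60, 0.60, 0.70],
        [0.25, 0.65, 0.70],
        [0.75, 0.75, 0.30],
    ]
)
_BLOB_WIDTHS = np.array([0.18, 0.15, 0.20, 0.16, 0.14, 0.17])
_BASE_LEVEL = {"FA": 0.45, "MD": 0.80, "AxD": 1.20, "RD": 0.65, "MO": 0.30}
_BASE_WEIGHTS = {
    "FA": [0.20, -0.10, 0.15, -0.05, 0.10, -0.08],
    "MD": [-0.12, 0.18, -0.06, 0.10, -0.05, 0.08],
    "AxD": [0.10, 0.12, -0.10, 0.06, 0.08, -0.06],
    "RD": [-0.08, -0.06, 0.12, 0.10, -0.10, 0.05],
    "MO": [0.06, -0.12, 0.08, -0.06, 0.12, 0.10],
}
_PATTERN_WEIGHTS = {
    "FA": [1.0, -0.6, 0.8, -0.4, 0.5, -0.7],
    "MD": [-0.8, 1.0, -0.5, 0.7, -0.6, 0.4],
    "AxD": [0.7, 0.5, -0.9, 0.4, -0.3, 0.6],
    "RD": [-0.5, -0.7, 0.6, 1.0, -0.4, 0.3],
    "MO": [0.9, -0.3, -0.6, 0.5, 0.7, -0.8],
}


def _blob_basis(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth Gaussian basis fields, shape (n_blobs, *grid)."""
    axes = [np.linspace(0.0, 1.0, g) for g in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    basis = []
    for (cx, cy, cz), w in zip(_BLOB_CENTRES, _BLOB_WIDTHS):
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        basis.append(np.exp(-d2 / (2.0 * w**2)))
    return np.asarray(basis)


def _map_fields(config: SynthConfig) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    basis = _blob_basis(config.grid_shape)
    centred = basis - basis.mean(axis=(1, 2, 3), keepdims=True)
    base = {
        m: _BASE_LEVEL[m] + np.tensordot(_BASE_WEIGHTS[m], basis, axes=1)
        for m in MAP_NAMES
    }
    # pattern has voxel-mean exactly 1: the age slope of the voxel-mean
    # intensity equals the configured slope.
    pattern = {
        m: 1.0 + np.tensordot(_PATTERN_WEIGHTS[m], centred, axes=1) for m in MAP_NAMES
    }
    return base, pattern, basis


def render_maps(
    record: Mapping | pd.Series,
    truth: Mapping | pd.Series,
    config: SynthConfig,
    _fields=None,
) -> DwiMapSet:
    """Render the five 3D maps for one participant-timepoint.

    Each voxel is a smooth deterministic function of the participant's
    effective age (chronological age + true gap) — FA-analogue
    decreasing, MD/AxD/RD-analogues increasing, MO-analogue nonmonotone
    — plus a participant-specific smooth field shared across the five
    maps (within-participant correlation) and i.i.d. voxel noise.
    Deterministic per (seed, participant, timepoint).
    """
    record = dict(record)
    truth = dict(truth)
    if record["participant_id"] != truth["participant_id"]:
        raise ValueError(
            "record/truth participant_id mismatch: "
            f"{record['participant_id']} vs {truth['participant_id']}"
        )
    base, pattern, basis = _fields if _fields is not None else _map_fields(config)
    tp_code = 0 if record.get("timepoint", "baseline") == "baseline" else 1
    rng = _rng(
        config, 2, _participant_index(record["participant_id"]), tp_code
    )
    a_eff = float(record["age"]) + float(truth["true_gap"])
    centre = config.age_centre

    # Smooth participant field shared across maps.
    shared = np.tensordot(rng.normal(0.0, 1.0, basis.shape[0]), basis, axes=1)

    volumes = {}
    for m in MAP_NAMES:
        if m == "MO":
            drift = config.mo_curvature * ((a_eff - centre) ** 2 - 120.0)
        else:
            drift = config.map_age_slopes[m] * (a_eff - centre)
        vol = base[m] + drift * pattern[m]
        vol = vol + config.shared_noise_sd * shared
        sd = config.noise_sd_map.get(m, 0.0)
        if sd > 0:
            vol = vol + rng.normal(0.0, sd, config.grid_shape)
        volumes[m] = vol.astype(np.float32)
    return DwiMapSet(
        participant_id=record["participant_id"],
        timepoint=record.get("timepoint", "baseline"),
        volumes=volumes,
    )


def render_cohort(
    records: pd.DataFrame, truths: pd.DataFrame, config: SynthConfig
) -> dict[str, np.ndarray]:
    """Render all rows; returns arrays of shape (n, *grid) per map name.

    Rows of ``records`` and ``truths`` are aligned on
    participant_id x timepoint before rendering.
    """
    merged = records.merge(
        truths[["participant_id", "timepoint", "true_gap"]],
        on=["participant_id", "timepoint"],
        validate="one_to_one",
    )
    fields = _map_fields(config)
    out = {m: np.empty((len(merged), *config.grid_shape), np.float32) for m in MAP_NAMES}
    for i, row in enumerate(merged.to_dict("records")):
        ms = render_maps(row, row, config, _fields=fields)
        for m in MAP_NAMES:
            out[m][i] = ms.volumes[m]
    return out


# ---------------------------------------------------------------------------
# Cognition

#: Tests whose raw scale runs opposite to performance (higher = worse).
_REVERSED_TESTS = {"reaction_time", "trail_making_a", "pairs_matching", "trail_making_b"}

#: domain -> constituent tests
DOMAIN_TESTS = {
    "speed": ("reaction_time", "trail_making_a", "symbol_digit"),
    "memory": ("numeric_memory", "pairs_matching"),
    "executive": ("trail_making_b", "fluid_intelligence"),
}

#: Raw-score location/scale per test (arbitrary but realistic units:
#: reaction time in ms, trails in s, counts otherwise).
_TEST_SCALE = {
    "reaction_time": (550.0, 100.0),
    "trail_making_a": (40.0, 15.0),
    "symbol_digit": (20.0, 5.0),
    "numeric_memory": (7.0, 1.5),
    "pairs_matching": (4.0, 2.5),
    "trail_making_b": (75.0, 30.0),
    "fluid_intelligence": (6.0, 2.0),
}


def simulate_cognition(
    records: pd.DataFrame, truths: pd.DataFrame, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the seven raw cognitive test scores.

    Returns ``(cognition, latents)``; cognition holds raw scores keyed
    by participant_id x timepoint, latents the noise-free per-domain
    linear predictors (ground truth for recovery tests).  Domain
    structure: risk factors act on cognition through the planted gap
    (path b) and through direct paths (c'), with age/sex/education
    nuisance terms; higher latent always means better performance, and
    the per-test sign conventions are applied on the raw scale.
    """
    merged = records.merge(
        truths, on=["participant_id", "timepoint"], validate="one_to_one"
    )
    n = len(merged)
    paths = config.cognition_paths
    tp_code = 0 if (n and merged["timepoint"].iloc[0] == "baseline") else 1
    rng = _rng(config, 5, tp_code)

    latents = pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "timepoint": merged["timepoint"],
        }
    )
    cognition = latents.copy()
    for d in ("speed", "memory", "executive"):
        lp = (
            -paths.b.get(d, 0.0) * merged["true_gap"].to_numpy()
            + paths.age_beta * (merged["age"].to_numpy() - 64.0)
            + paths.sex_beta * merged["sex"].to_numpy()
            + paths.edu_beta * merged["education_college"].to_numpy()
        )
        for k in RISK_FACTORS:
            c = paths.c_prime.get(k, {}).get(d, 0.0)
            if c:
                lp = lp - c * merged[f"true_{k}"].to_numpy()
        latents[f"latent_{d}"] = lp
        noisy = lp + (
            rng.normal(0.0, paths.domain_noise_sd, n) if paths.domain_noise_sd else 0.0
        )
        for t in DOMAIN_TESTS[d]:
            z = noisy + (
                rng.normal(0.0, paths.test_noise_sd, n) if paths.test_noise_sd else 0.0
            )
            mu, sdv = _TEST_SCALE[t]
            sign = -1.0 if t in _REVERSED_TESTS else 1.0
            cognition[t] = mu + sdv * sign * z
    cognition = cognition[["participant_id", "timepoint", *COGNITION_TESTS]]
    return cognition, latents


# ---------------------------------------------------------------------------
# Longitudinal subset and splits

def make_longitudinal_subset(
    records: pd.DataFrame, truths: pd.DataFrame, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw follow-up rows for a random fraction of the baseline cohort.

    Interval ~ N(interval_mean, interval_sd) truncated positive; age is
    incremented by the interval, the planted gap evolves by the
    configured drift (+noise), and risk factors are carried forward.
    """
    if not 0.0 <= config.longitudinal_fraction <= 1.0:
        raise ConfigError("longitudinal_fraction must be in [0, 1]")
    rng = _rng(config, 3)
    n = len(records)
    chosen = rng.random(n) < config.longitudinal_fraction
    fu = records.loc[chosen].reset_index(drop=True).copy()
    ft = truths.loc[chosen].reset_index(drop=True).copy()
    m = len(fu)
    mean, sd = config.interval_years
    interval = rng.normal(mean, sd, m) if sd > 0 else np.full(m, mean)
    for _ in range(100):  # truncate positive by redraw
        neg = interval <= 0
        if not neg.any():
            break
        interval[neg] = rng.normal(mean, sd, int(neg.sum()))
    interval = np.abs(interval)
    fu["timepoint"] = "followup"
    fu["age"] = fu["age"] + interval
    ft["timepoint"] = "followup"
    drift = config.followup_gap_drift + (
        rng.normal(0.0, config.followup_gap_drift_sd, m)
        if config.followup_gap_drift_sd > 0
        else 0.0
    )
    ft["true_gap"] = ft["true_gap"] + drift
    return fu, ft


def make_splits(
    records: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> pd.Series:
    """Assign train/validation/test labels to baseline participants.

    Only healthy participants are eligible for train and validation;
    every unhealthy participant is forced into the test set.  Fractions
    apply to the healthy pool and must sum to 1 (largest-remainder
    rounding gives exact counts for exact proportions).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ConfigError("need three non-negative fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {sum(fractions)!r}")
    labels = pd.Series("test", index=records.index, name="split")
    healthy_idx = records.index[records["health_status"] == "healthy"].to_numpy()
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 4])
    perm = rng.permutation(healthy_idx)
    nh = len(perm)
    counts = [math.floor(f * nh) for f in fractions]
    remainders = [f * nh - c for f, c in zip(fractions, counts)]
    while sum(counts) < nh:
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    n_tr, n_va, _ = counts
    labels.loc[perm[:n_tr]] = "train"
    labels.loc[perm[n_tr : n_tr + n_va]] = "validation"
    return labels


# ---------------------------------------------------------------------------
# Latent-shortcut predictions

def latent_predictions(
    records: pd.DataFrame,
    truths: pd.DataFrame,
    config: SynthConfig,
    slope: float | None = None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Emulate raw brain-age predictions directly from the latent truth.

    Bypasses the CNN: the participant's latent brain age
    (age + true_gap) is shrunk towards the cohort centre with the
    configured slope — mimicking the regression dilution a real
    regressor exhibits — and perturbed with Gaussian prediction error:

        y_hat = centre + slope * (age + true_gap - centre) + N(0, sd)

    Used by the statistical layers (bias correction onwards) where the
    imaging stage is not under test.  Deterministic under the config
    seed; follow-up rows use an independent noise stream.
    """
    slope = config.pred_slope if slope is None else slope
    noise_sd = config.pred_noise_sd if noise_sd is None else noise_sd
    merged = records.merge(
        truths[["participant_id", "timepoint", "true_gap"]],
        on=["participant_id", "timepoint"],
        validate="one_to_one",
    )
    tp_code = 0 if (len(merged) and merged["timepoint"].iloc[0] == "baseline") else 1
    rng = _rng(config, 6, tp_code)
    centre = config.age_centre
    brain_age = merged["age"].to_numpy() + merged["true_gap"].to_numpy()
    y_hat = centre + slope * (brain_age - centre)
    if noise_sd > 0:
        y_hat = y_hat + rng.normal(0.0, noise_sd, len(merged))
    return pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "timepoint": merged["timepoint"],
            "y": merged["age"],
            "y_hat": y_hat,
        }
    )
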