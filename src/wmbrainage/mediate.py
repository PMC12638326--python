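"""Product-of-coefficients mediation with a nonparametric bootstrap.

For exposure X, mediator M (the brain-age gap) and outcome Y
(cognition), two linear regressions on complete cases give

    M = a X + covariates + e1
    Y = c' X + b M + covariates + e2

and the decomposition ACME = a*b (indirect, on the scale of Y),
ADE = c' (direct), total = ACME + ADE — an identity in this linear,
no-interaction model.  Uncertainty comes from case-resampling
bootstrap (default 5000 samples) with percentile confidence intervals;
bootstrap p-values are twice the smaller tail proportion of the
bootstrap distribution relative to zero.  Fully deterministic under
the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgio import RISK_FACTORS

__all__ = ["MediationResult", "mediate", "mediation_battery"]

log = logging.getLogger(__name__)


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    ci_acme: tuple[float, float]
    ci_ade: tuple[float, float]
    ci_total: tuple[float, float]
    p_acme: float
    p_ade: float
    p_total: float
    a: float
    b: float
    n_used: int
    n_boot: int
    seed: int


def _solve(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)


def _boot_solve(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Batched normal-equations solve: Xb (B, n, p), yb (B, n) -> (B, p)."""
    G = np.einsum("bni,bnj->bij", Xb, Xb)
    h = np.einsum("bni,bn->bi", Xb, yb)
    return np.linalg.solve(G, h[..., None])[..., 0]


def _tail_p(draws: np.ndarray) -> float:
    lo = float(np.mean(draws <= 0.0))
    hi = float(np.mean(draws >= 0.0))
    return min(1.0, 2.0 * min(lo, hi))


def mediate(
    x,
    m,
    y,
    covariates=None,
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Estimate indirect/direct/total effects of x on y through m."""
    x = np.asarray(x, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, m, y, C = x[keep], m[keep], y[keep], C[keep]
    n = len(x)
    n_cov = C.shape[1]
    if n < 10 * (n_cov + 2):
        raise ValueError(
            f"too few complete cases (n={n}) for {n_cov} covariates; need >= {10 * (n_cov + 2)}"
        )
    if np.var(x) == 0 or np.var(m) == 0:
        raise ValueError("zero variance in exposure or mediator")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    ones = np.ones((n, 1))
    X1 = np.column_stack([ones, x, C])  # mediator model
    X2 = np.column_stack([ones, x, m, C])  # outcome model
    coef1 = _solve(X1, m)
    coef2 = _solve(X2, y)
    a, c_prime, b = coef1[1], coef2[1], coef2[2]
    acme = a * b
    ade = c_prime
    total = acme + ade

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    draws_acme = np.empty(n_boot)
    draws_ade = np.empty(n_boot)
    chunk = max(1, min(n_boot, 50_000_000 // (n * (n_cov + 3))))
    done = 0
    while done < n_boot:
        bsz = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(bsz, n))
        # redraw resamples in which the exposure is constant
        for _ in range(100):
            xb = x[idx]
            degenerate = xb.var(axis=1) == 0
            if not degenerate.any():
                break
            log.info("redrawing %d bootstrap resamples with constant exposure", int(degenerate.sum()))
            idx[degenerate] = rng.integers(0, n, size=(int(degenerate.sum()), n))
        c1 = _boot_solve(X1[idx], m[idx])
        c2 = _boot_solve(X2[idx], y[idx])
        draws_acme[done : done + bsz] = c1[:, 1] * c2[:, 2]
        draws_ade[done : done + bsz] = c2[:, 1]
        done += bsz
    draws_total = draws_acme + draws_ade

    q = (0.5 * (1 - ci_level) * 100, (1 - 0.5 * (1 - ci_level)) * 100)
    ci = lambda d: tuple(float(v) for v in np.percentile(d, q))
    return MediationResult(
        acme=float(acme),
        ade=float(ade),
        total=float(total),
        ci_acme=ci(draws_acme),
        ci_ade=ci(draws_ade),
        ci_total=ci(draws_total),
        p_acme=_tail_p(draws_acme),
        p_ade=_tail_p(draws_ade),
        p_total=_tail_p(draws_total),
        a=float(a),
        b=float(b),
        n_used=int(n),
        n_boot=int(n_boot),
        seed=int(seed),
    )


def mediation_battery(
    df: pd.DataFrame,
    factors=RISK_FACTORS,
    outcomes=("speed", "executive", "memory", "global_cognition"),
    mediator: str = "wmbag",
    covariates=("age", "sex", "scanner", "apoe_e4_count", "education_college"),
    n_boot: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """One mediation model per (factor, outcome) pair, in deterministic order.

    Returns a long-format table with ACME/ADE/total point estimates,
    percentile CIs, bootstrap p-values and a Bonferroni flag at 0.05/4
    within each outcome family.
    """
    alpha = 0.05 / len(outcomes)
    rows = []
    for fi, factor in enumerate(sorted(factors)):
        for oi, outcome in enumerate(sorted(outcomes)):
            res = mediate(
                df[factor].to_numpy(),
                df[mediator].to_numpy(),
                df[outcome].to_numpy(),
                covariates=df[list(covariates)].to_numpy(),
                n_boot=n_boot,
                seed=(int(seed) * 1000 + fi * 10 + oi) & 0x7FFFFFFF,
            )
            rows.append(
                {
                    "factor": factor,
                    "outcome": outcome,
                    "acme": res.acme,
                    "acme_ci_low": res.ci_acme[0],
                    "acme_ci_high": res.ci_acme[1],
                    "p_acme": res.p_acme,
                    "ade": res.ade,
                    "ade_ci_low": res.ci_ade[0],
                    "ade_ci_high": res.ci_ade[1],
                    "p_ade": res.p_ade,
                    "total": res.total,
                    "p_total": res.p_total,
                    "n_used": res.n_used,
                    "acme_significant_bonferroni": res.p_acme < alpha,
                }
            )
    return pd.DataFrame(rows)
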