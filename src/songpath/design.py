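"""Design analysis: power, Type S and Type M errors for a planned study.

Given a hypothesized true effect A (here the log-odds of a preference
ratio) and the standard error s the design is expected to achieve, the
Gelman-Carlin design analysis asks three questions about a two-sided
test at level alpha:

- power: the probability the estimate reaches significance;
- Type S (sign) error: among significant estimates, the probability the
  sign is wrong;
- Type M (magnitude) error: the factor by which a significant estimate
  is expected to exaggerate |A| (the "exaggeration ratio").

With lambda = A / s and z* the critical value, the estimate's
standardized distribution is Normal(lambda, 1) (or shifted t when a
finite df is supplied) and all three quantities have closed or
one-dimensional-integral forms; a seeded Monte-Carlo mode is provided
as an independent cross-check.

The module also simulates the sampling distribution of the standard
error itself for a hierarchical binomial design (birds x trials with
bird-level intercept and session-level slope variation), the quantity
the design analysis conditions on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "EffectSpec",
    "RetrodesignResult",
    "pr_to_logodds",
    "logodds_to_pr",
    "retrodesign",
    "retrodesign_mc",
    "se_distribution",
]


def pr_to_logodds(pr: float) -> float:
    """Log-odds A = ln(pr / (1 - pr)) of a preference ratio in (0, 1)."""
    if not 0 < pr < 1:
        raise ValueError(f"preference ratio must be in (0, 1), got {pr}")
    return math.log(pr / (1 - pr))


def logodds_to_pr(a: float) -> float:
    """Inverse of :func:`pr_to_logodds`."""
    return 1.0 / (1.0 + math.exp(-a))


@dataclass(frozen=True)
class EffectSpec:
    """Hypothesized effect for the design analysis.

    ``pr`` is the hypothetical preference ratio, ``A`` its log-odds
    (derived), ``s`` the anticipated standard error on the log-odds
    scale, ``alpha`` the two-sided test level, and ``df`` an optional
    t-reference degrees of freedom (None = normal reference).
    """

    pr: float
    s: float
    alpha: float = 0.05
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.pr < 1:
            raise ValueError(f"pr must be in (0, 1), got {self.pr}")
        if self.s <= 0:
            raise ValueError(f"standard error must be > 0, got {self.s}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def A(self) -> float:
        return pr_to_logodds(self.pr)


@dataclass(frozen=True)
class RetrodesignResult:
    """power, Type S and Type M for one effect spec.

    ``type_m`` is None when the true effect is exactly zero (the
    exaggeration ratio divides by |A|).
    """

    power: float
    type_s: float
    type_m: float | None


def _dist(df: float | None):
    return stats.norm if df is None else stats.t(df)


def retrodesign(spec: EffectSpec) -> RetrodesignResult:
    """Closed-form / quadrature design analysis for one effect spec.

    With lambda = A/s and critical value z*: power = P(lambda + Z > z*)
    + P(lambda + Z < -z*); Type S is the lower-tail share of that
    probability; Type M is E[|lambda + Z| given significance] / lambda.
    Under the normal reference the Type M numerator has a truncated
    normal closed form; under a t reference it is evaluated by
    quadrature.  At A = 0: power = alpha, Type S = 1/2, Type M
    undefined (None).
    """
    d = _dist(spec.df)
    lam = spec.A / spec.s
    zstar = d.ppf(1 - spec.alpha / 2)

    p_hi = d.sf(zstar - lam)  # significant and positive
    p_lo = d.cdf(-zstar - lam)  # significant and negative
    power = p_hi + p_lo
    type_s = (p_lo if lam >= 0 else p_hi) / power

    if lam == 0:
        return RetrodesignResult(power=power, type_s=type_s, type_m=None)

    if spec.df is None:
        # E[|X| ; |X| > z*] for X ~ N(lam, 1), via truncated-normal moments
        phi = stats.norm.pdf
        num = (
            lam * p_hi
            + phi(zstar - lam)
            - lam * p_lo
            + phi(zstar + lam)
        )
    else:
        num = sum(
            integrate.quad(lambda x: abs(x) * d.pdf(x - lam), a, b, limit=200)[0]
            for a, b in ((-np.inf, -zstar), (zstar, np.inf))
        )
    type_m = num / (power * abs(lam))
    return RetrodesignResult(power=power, type_s=type_s, type_m=type_m)


def retrodesign_mc(
    spec: EffectSpec, n: int = 1_000_000, seed: int = 0
) -> RetrodesignResult:
    """Monte-Carlo design analysis; independent oracle for retrodesign.

    Draws n replicate estimates A + s*Z, applies the two-sided test,
    and tabulates the three quantities empirically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    d = _dist(spec.df)
    zstar = d.ppf(1 - spec.alpha / 2)
    noise = (
        rng.standard_normal(n) if spec.df is None else rng.standard_t(spec.df, n)
    )
    est = spec.A + spec.s * noise
    sig = np.abs(est) > zstar * spec.s
    power = sig.mean()
    if not np.any(sig):
        return RetrodesignResult(power=0.0, type_s=float("nan"), type_m=None)
    wrong_sign = sig & (np.sign(est) != np.sign(spec.A))
    type_s = wrong_sign.sum() / sig.sum()
    type_m = (
        float(np.abs(est[sig]).mean() / abs(spec.A)) if spec.A != 0 else None
    )
    return RetrodesignResult(power=float(power), type_s=float(type_s), type_m=type_m)


def _cluster_robust_logit_se(successes: np.ndarray, totals: np.ndarray) -> float:
    """SE of an intercept-only logistic MLE with cluster-robust variance.

    One row per cluster (bird-session).  The MLE is the pooled logit
    p_hat = sum(successes) / sum(totals); the observed information is
    N * p_hat * (1 - p_hat); the sandwich variance replaces the middle
    with the sum of squared per-cluster scores sum_i (y_i - n_i p_hat)^2.
    """
    N = totals.sum()
    p = successes.sum() / N
    if p <= 0 or p >= 1:
        raise ValueError("degenerate simulated data: all one outcome")
    info = N * p * (1 - p)
    scores = successes - totals * p
    return float(np.sqrt((scores**2).sum()) / info)


def se_distribution(
    n_birds: int = 22,
    n_trials: int = 120,
    sigma_bird: float = 0.5,
    sigma_slope: float = 0.25,
    mu: float = 0.0,
    n_scenarios: int = 1000,
    n_sessions: int = 2,
    seed: int = 0,
) -> dict:
    """Sampling distribution of the population-effect standard error.

    Each scenario simulates ``n_birds`` birds whose choice log-odds are
    mu + b_i (+ s_ij per session), with b_i ~ N(0, sigma_bird) and
    s_ij ~ N(0, sigma_slope); each bird contributes ``n_trials``
    Bernoulli responses split across ``n_sessions`` sessions.  The SE of
    the population log-odds is estimated by an intercept-only logistic
    fit with a cluster-robust (per-bird) variance — a fast stand-in for
    refitting the full hierarchical model per scenario.  Returns min,
    mean and max SE over scenarios plus the raw values.
    """
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    if n_trials < 2 or n_birds < 2:
        raise ValueError(
            "degenerate design: need >= 2 birds and >= 2 trials per bird"
        )
    rng = np.random.default_rng(seed)
    per_session = np.full(n_sessions, n_trials // n_sessions)
    per_session[: n_trials % n_sessions] += 1

    ses = np.empty(n_scenarios)
    for sc in range(n_scenarios):
        b = rng.normal(0.0, sigma_bird, n_birds)
        s = rng.normal(0.0, sigma_slope, (n_birds, n_sessions))
        logits = mu + b[:, None] + s
        p = 1.0 / (1.0 + np.exp(-logits))
        succ_cells = rng.binomial(per_session[None, :], p)
        # cluster = bird: sum sessions within bird
        successes = succ_cells.sum(axis=1).astype(float)
        totals = np.full(n_birds, n_trials, dtype=float)
        ses[sc] = _cluster_robust_logit_se(successes, totals)
    return {
        "min": float(ses.min()),
        "mean": float(ses.mean()),
        "max": float(ses.max()),
        "se_values": ses,
    }
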