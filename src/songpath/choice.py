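"""Operant two-choice preference sessions: simulation, screening, analysis.

A session places a bird in a cage with two trigger perches; landing on a
perch for a dwell period plays a song from that perch's stimulus
category (long- vs short-path-length synthetic motifs), so perch
triggers index preference.  A session runs baseline (no audio), playback
and post-playback phases; left/right assignment of the long-path
category is counterbalanced across sessions.

This module simulates such sessions from a hierarchical Bernoulli model
(population log-odds mu plus per-bird intercepts), round-trips session
logs through CSV, screens baselines for side bias, computes preference
ratios, and fits a Bayesian hierarchical logistic model
(choice ~ (1 | bird), optionally with phase / experiment / session-order
fixed effects and a stimulus random effect) by ensemble MCMC, with LOO
model comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "SessionLog",
    "BirdEffect",
    "PreferenceEstimate",
    "TimingConfig",
    "ModelSpec",
    "SamplerConfig",
    "simulate_session",
    "simulate_experiment",
    "preference_ratio",
    "baseline_bias_screen",
    "logs_to_frame",
    "logs_to_csv",
    "logs_from_csv",
    "fit_choice_glmm",
    "compare_models",
]

PHASES = ("baseline", "playback", "post")
LOG_COLUMNS = [
    "bird_id",
    "session_order",
    "experiment",
    "side_assignment",
    "phase",
    "t_start_s",
    "perch",
    "stimulus_category",
    "stimulus_id",
    "interrupted",
]


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class TrialRecord:
    """One perch trigger: when, which perch, what played (if anything)."""

    t_start: float
    perch: str  # "left" | "right"
    stimulus_category: str  # "long" | "short" | "none" (baseline/post)
    stimulus_id: str
    interrupted: bool
    phase: str  # "baseline" | "playback" | "post"


@dataclass(frozen=True)
class SessionLog:
    """All trigger events of one bird's session, plus its design cell."""

    bird_id: str
    session_order: str  # "first" | "second"
    experiment: str  # "replication" | "extension"
    side_assignment: str  # perch carrying long-path songs: "left" | "right"
    records: tuple[TrialRecord, ...]

    def __post_init__(self) -> None:
        if self.side_assignment not in ("left", "right"):
            raise ValueError("side_assignment must be 'left' or 'right'")
        times = [r.t_start for r in self.records]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("records must be non-decreasing in time")

    def phase_records(self, phase: str) -> list[TrialRecord]:
        return [r for r in self.records if r.phase == phase]


@dataclass(frozen=True)
class BirdEffect:
    """A bird's log-odds deviation from the population preference."""

    bird_id: str
    intercept_logit: float
    slope_logit: float = 0.0


@dataclass(frozen=True)
class PreferenceEstimate:
    """Posterior summary of the population preference log-odds."""

    posterior_mean_logit: float
    ci95_low: float
    ci95_high: float
    pr_mean: float  # inverse-logit of the posterior mean
    model_label: str
    loo_score: float
    sigma_bird_mean: float
    rhat_max: float
    converged: bool
    n_obs: int
    idata: object = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class TimingConfig:
    """Trial timing: dwell to trigger, stimulus length, inter-trial gap.

    Defaults follow the operant design: 2 s perch dwell triggers
    playback, ~1 s motif, 5 s inter-trial interval, 30 min playback
    phase flanked by 10 min silent baseline and post phases.
    """

    dwell_s: float = 2.0
    stimulus_s: float = 1.0
    iti_s: float = 5.0
    playback_duration_s: float = 1800.0
    baseline_duration_s: float = 600.0
    post_duration_s: float = 600.0

    @property
    def trial_spacing_s(self) -> float:
        return self.dwell_s + self.stimulus_s + self.iti_s


def simulate_session(
    mu: float,
    sigma_bird: float,
    n_trials: int,
    seed: int = 0,
    bird: BirdEffect | None = None,
    bird_id: str | None = None,
    side_assignment: str = "left",
    session_order: str = "first",
    experiment: str = "replication",
    side_bias_logit: float = 0.0,
    p_interrupt: float = 0.2,
    n_baseline: int = 20,
    n_post: int = 15,
    timing: TimingConfig = TimingConfig(),
    n_stimuli_per_category: int = 1,
) -> SessionLog:
    """Simulate one operant session from the hierarchical choice model.

    The bird's playback-phase log-odds of choosing the long-path perch
    is ``mu + b`` where ``b`` is either the supplied :class:`BirdEffect`
    intercept or a fresh Normal(0, sigma_bird) draw.  Baseline and post
    phases have no audio; their perch choices follow ``side_bias_logit``
    (log-odds of landing on the long-assigned side, default unbiased),
    so a phase effect can be simulated by offsetting ``mu`` against it.
    Trial times honor dwell + stimulus + inter-trial spacing.
    Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if sigma_bird < 0:
        raise ValueError("sigma_bird must be >= 0")
    max_trials = int(timing.playback_duration_s // timing.trial_spacing_s)
    if n_trials > max_trials:
        raise ValueError(
            f"{n_trials} trials cannot fit in {timing.playback_duration_s:.0f} s "
            f"at {timing.trial_spacing_s:.1f} s spacing (max {max_trials})"
        )

    rng = np.random.default_rng(seed)
    if bird is not None:
        b = bird.intercept_logit
        bird_id = bird_id or bird.bird_id
    else:
        b = float(rng.normal(0.0, sigma_bird))
        bird_id = bird_id or f"bird{seed:03d}"

    p_long = float(_expit(mu + b))
    p_side = float(_expit(side_bias_logit))
    other = "right" if side_assignment == "left" else "left"

    records: list[TrialRecord] = []

    def _silent_phase(phase: str, n: int, t0: float, duration: float) -> float:
        spacing = duration / max(n, 1)
        for i in range(n):
            on_long_side = rng.random() < p_side
            records.append(
                TrialRecord(
                    t_start=t0 + i * spacing,
                    perch=side_assignment if on_long_side else other,
                    stimulus_category="none",
                    stimulus_id="none",
                    interrupted=False,
                    phase=phase,
                )
            )
        return t0 + duration

    t = _silent_phase("baseline", n_baseline, 0.0, timing.baseline_duration_s)
    for i in range(n_trials):
        chose_long = (p_long >= 1.0) or (rng.random() < p_long)
        cat = "long" if chose_long else "short"
        stim_idx = int(rng.integers(n_stimuli_per_category))
        records.append(
            TrialRecord(
                t_start=t + i * timing.trial_spacing_s,
                perch=side_assignment if chose_long else other,
                stimulus_category=cat,
                stimulus_id=f"{cat}{stim_idx:02d}",
                interrupted=bool(rng.random() < p_interrupt),
                phase="playback",
            )
        )
    t += timing.playback_duration_s
    _silent_phase("post", n_post, t, timing.post_duration_s)

    return SessionLog(
        bird_id=bird_id,
        session_order=session_order,
        experiment=experiment,
        side_assignment=side_assignment,
        records=tuple(records),
    )


def simulate_experiment(
    n_birds: int = 22,
    n_trials: int = 120,
    mu: float = 0.847,
    sigma_bird: float = 0.5,
    seed: int = 0,
    both_sessions: bool = False,
    phase_effect: float | None = None,
    **session_kwargs,
) -> list[SessionLog]:
    """Simulate a full counterbalanced experiment (one log per session).

    Bird intercepts are drawn once per bird and shared across that
    bird's sessions; side assignment and session order are
    counterbalanced across birds.  ``phase_effect`` (log-odds) offsets
    the playback-phase preference above the silent-phase side bias,
    which is then centred at ``mu - phase_effect``.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_bird, n_birds)
    side_bias = 0.0 if phase_effect is None else mu - phase_effect
    logs = []
    for i in range(n_birds):
        eff = BirdEffect(bird_id=f"bird{i:03d}", intercept_logit=float(b[i]))
        sessions = (
            [("first", "replication"), ("second", "extension")]
            if both_sessions
            else [("first", "replication")]
        )
        if both_sessions and i % 2:
            sessions = [("first", "extension"), ("second", "replication")]
        for s_i, (order, exp) in enumerate(sessions):
            logs.append(
                simulate_session(
                    mu=mu,
                    sigma_bird=sigma_bird,
                    n_trials=n_trials,
                    seed=int(rng.integers(2**31)),
                    bird=eff,
                    side_assignment="left" if (i + s_i) % 2 == 0 else "right",
                    session_order=order,
                    experiment=exp,
                    side_bias_logit=side_bias,
                    **session_kwargs,
                )
            )
    return logs


def preference_ratio(long_count: float, short_count: float) -> float:
    """long / (long + short); accepts counts or time proportions."""
    if long_count < 0 or short_count < 0:
        raise ValueError("counts must be non-negative")
    total = long_count + short_count
    if total == 0:
        raise ValueError("preference ratio undefined: both counts are zero")
    return long_count / total


def _side_ratio(counts: tuple[float, float]) -> tuple[float, int]:
    """(max-side ratio, biased side index) for a (left, right) pair."""
    total = counts[0] + counts[1]
    if total <= 0:
        raise ValueError("baseline with zero triggers")
    side = int(counts[1] > counts[0])
    return max(counts) / total, side


def baseline_bias_screen(
    baseline1: tuple[float, float],
    baseline2: tuple[float, float] | None = None,
    retest: tuple[float, float] | None = None,
    threshold: float = 0.80,
) -> str:
    """Screen a bird's silent baselines for side bias.

    Inputs are (left, right) trigger counts.  Decision states:

    - ``pass``: no bias (max-side ratio < threshold), or the bias did
      not persist on the same side at the next stage;
    - ``rerun_baseline``: first baseline biased (ratio >= threshold,
      equality included) and no second baseline supplied yet;
    - ``retest_later``: both baselines biased to the same side, no
      retest supplied yet;
    - ``exclude``: bias persisted on the same side through the retest.
    """
    r1, s1 = _side_ratio(baseline1)
    if r1 < threshold:
        return "pass"
    if baseline2 is None:
        return "rerun_baseline"
    r2, s2 = _side_ratio(baseline2)
    if r2 < threshold or s2 != s1:
        return "pass"
    if retest is None:
        return "retest_later"
    r3, s3 = _side_ratio(retest)
    if r3 >= threshold and s3 == s1:
        return "exclude"
    return "pass"


# ---------------------------------------------------------------------------
# session-log CSV round trip


def logs_to_frame(logs: Sequence[SessionLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for r in log.records:
            rows.append(
                {
                    "bird_id": log.bird_id,
                    "session_order": log.session_order,
                    "experiment": log.experiment,
                    "side_assignment": log.side_assignment,
                    "phase": r.phase,
                    "t_start_s": r.t_start,
                    "perch": r.perch,
                    "stimulus_category": r.stimulus_category,
                    "stimulus_id": r.stimulus_id,
                    "interrupted": r.interrupted,
                }
            )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def logs_to_csv(logs: Sequence[SessionLog], path) -> None:
    logs_to_frame(logs).to_csv(path, index=False)


def logs_from_csv(path) -> list[SessionLog]:
    df = pd.read_csv(path)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing session-log columns {sorted(missing)}")
    logs = []
    keys = ["bird_id", "session_order", "experiment", "side_assignment"]
    for vals, grp in df.groupby(keys, sort=False):
        records = tuple(
            TrialRecord(
                t_start=float(row.t_start_s),
                perch=str(row.perch),
                stimulus_category=str(row.stimulus_category),
                stimulus_id=str(row.stimulus_id),
                interrupted=bool(row.interrupted),
                phase=str(row.phase),
            )
            for row in grp.itertuples()
        )
        logs.append(
            SessionLog(
                bird_id=str(vals[0]),
                session_order=str(vals[1]),
                experiment=str(vals[2]),
                side_assignment=str(vals[3]),
                records=records,
            )
        )
    return logs


# ---------------------------------------------------------------------------
# Bayesian hierarchical logistic model (ensemble MCMC + LOO)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the hierarchical logistic model.

    The base model is ``choice ~ (1 | bird)``.  Fixed effects may be
    drawn from {"phase", "experiment", "session_order"}; a stimulus-ID
    random effect supports the extension stimulus set.
    """

    label: str = "base"
    fixed_effects: tuple[str, ...] = ()
    stimulus_re: bool = False

    _ALLOWED = ("phase", "experiment", "session_order")

    def __post_init__(self) -> None:
        bad = set(self.fixed_effects) - set(self._ALLOWED)
        if bad:
            raise ValueError(f"unknown fixed effects {sorted(bad)}")


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-MCMC settings (walkers, steps, priors, diagnostics)."""

    n_walkers: int = 48
    n_steps: int = 20000
    n_burn: int = 5000
    thin: int = 5
    seed: int = 1234
    prior_scale: float = 1.5  # Normal SD on population logit / fixed effects
    sigma_prior_scale: float = 1.0  # half-Normal SD on random-effect SDs
    rhat_threshold: float = 1.01
    loglik_draws: int = 1000  # thinned draws kept for pointwise LOO


def _choice_frame(
    logs: Sequence[SessionLog],
    phases: tuple[str, ...],
    include_interrupted: bool,
) -> pd.DataFrame:
    """Flatten logs to one row per analyzable trigger.

    ``choice`` is 1 when the trigger was on the session's long-path side
    (in silent phases this codes perch side against that assignment, per
    the design's phase-effect convention).
    """
    df = logs_to_frame(logs)
    df = df[df["phase"].isin(phases)].copy()
    if not include_interrupted:
        df = df[~df["interrupted"]]
    if df.empty:
        raise ValueError(f"no triggers in phases {phases}")
    df["choice"] = (df["perch"] == df["side_assignment"]).astype(int)
    return df.reset_index(drop=True)


def _design(df: pd.DataFrame, spec: ModelSpec):
    """Cell-aggregated design: bird index, dummy columns, binomial counts."""
    birds = sorted(df["bird_id"].unique())
    if len(birds) < 2:
        raise ValueError("hierarchical model needs >= 2 birds")
    bird_idx = df["bird_id"].map({b: i for i, b in enumerate(birds)}).to_numpy()

    dummy_cols: list[str] = []
    X_parts = []
    for fe in spec.fixed_effects:
        levels = sorted(df[fe].unique())
        if len(levels) < 2:
            raise ValueError(
                f"fixed effect {fe!r} has a single level in these data"
            )
        for lev in levels[1:]:  # first level is the reference
            dummy_cols.append(f"{fe}[{lev}]")
            X_parts.append((df[fe] == lev).astype(float).to_numpy())
    X = np.column_stack(X_parts) if X_parts else np.zeros((len(df), 0))

    if spec.stimulus_re:
        stims = sorted(df["stimulus_id"].unique())
        stim_idx = df["stimulus_id"].map({s: i for i, s in enumerate(stims)}).to_numpy()
    else:
        stims, stim_idx = [], np.zeros(len(df), dtype=int)

    # aggregate per (bird, dummies, stimulus) cell
    key = pd.DataFrame({"bird": bird_idx, "stim": stim_idx})
    for j, c in enumerate(dummy_cols):
        key[c] = X[:, j]
    key["choice"] = df["choice"].to_numpy()
    grouped = key.groupby(["bird", "stim"] + dummy_cols, sort=True)["choice"].agg(
        ["sum", "count"]
    )
    cells = grouped.reset_index()
    return {
        "birds": birds,
        "stims": stims,
        "dummy_cols": dummy_cols,
        "cell_bird": cells["bird"].to_numpy(int),
        "cell_stim": cells["stim"].to_numpy(int),
        "cell_X": cells[dummy_cols].to_numpy(float)
        if dummy_cols
        else np.zeros((len(cells), 0)),
        "cell_succ": cells["sum"].to_numpy(float),
        "cell_n": cells["count"].to_numpy(float),
        "trial_bird": bird_idx,
        "trial_stim": stim_idx,
        "trial_X": X,
        "trial_y": df["choice"].to_numpy(float),
    }


def _log_prob_factory(d: dict, spec: ModelSpec, cfg: SamplerConfig):
    """Vectorized log-posterior over walker parameter matrices.

    Parameterization (non-centered): mu, betas, log sigma_bird, bird z's
    [, log sigma_stim, stimulus z's].  Half-normal priors on SDs include
    the log-SD Jacobian.
    """
    n_birds = len(d["birds"])
    n_beta = d["cell_X"].shape[1]
    n_stim = len(d["stims"]) if spec.stimulus_re else 0
    ndim = 1 + n_beta + 1 + n_birds + (1 + n_stim if spec.stimulus_re else 0)

    succ, n_cell = d["cell_succ"], d["cell_n"]
    bird_of_cell, stim_of_cell, Xc = d["cell_bird"], d["cell_stim"], d["cell_X"]

    def log_prob(theta: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(theta)
        i = 0
        mu = th[:, i]
        i += 1
        beta = th[:, i : i + n_beta]
        i += n_beta
        log_sb = th[:, i]
        i += 1
        zb = th[:, i : i + n_birds]
        i += n_birds
        sb = np.exp(log_sb)
        eta = mu[:, None] + zb * sb[:, None]
        lin = eta[:, bird_of_cell]
        if n_beta:
            lin = lin + beta @ Xc.T
        if spec.stimulus_re:
            log_ss = th[:, i]
            i += 1
            zs = th[:, i : i + n_stim]
            ss = np.exp(log_ss)
            lin = lin + (zs * ss[:, None])[:, stim_of_cell]

        # binomial log-likelihood per cell (constants dropped)
        ll = succ * lin - n_cell * np.logaddexp(0.0, lin)
        lp = ll.sum(axis=1)
        # priors
        lp -= 0.5 * (mu / cfg.prior_scale) ** 2
        if n_beta:
            lp -= 0.5 * ((beta / cfg.prior_scale) ** 2).sum(axis=1)
        lp -= 0.5 * (zb**2).sum(axis=1)
        lp += -0.5 * (sb / cfg.sigma_prior_scale) ** 2 + log_sb  # half-N + Jacobian
        if spec.stimulus_re:
            lp -= 0.5 * (zs**2).sum(axis=1)
            lp += -0.5 * (ss / cfg.sigma_prior_scale) ** 2 + log_ss
        return lp

    return log_prob, ndim, n_beta, n_birds, n_stim


def _pointwise_loglik(th: np.ndarray, d: dict, spec: ModelSpec):
    """Per-trial Bernoulli log-likelihood for a draw matrix (draws, ndim)."""
    n_birds = len(d["birds"])
    n_beta = d["trial_X"].shape[1]
    n_stim = len(d["stims"]) if spec.stimulus_re else 0
    i = 0
    mu = th[:, i]
    i += 1
    beta = th[:, i : i + n_beta]
    i += n_beta
    sb = np.exp(th[:, i])
    i += 1
    zb = th[:, i : i + n_birds]
    i += n_birds
    eta = mu[:, None] + zb * sb[:, None]
    lin = eta[:, d["trial_bird"]]
    if n_beta:
        lin = lin + beta @ d["trial_X"].T
    if spec.stimulus_re:
        ss = np.exp(th[:, i])
        i += 1
        zs = th[:, i : i + n_stim]
        lin = lin + (zs * ss[:, None])[:, d["trial_stim"]]
    y = d["trial_y"]
    return y * lin - np.logaddexp(0.0, lin)


def fit_choice_glmm(
    logs: Sequence[SessionLog],
    spec: ModelSpec = ModelSpec(),
    phases: tuple[str, ...] = ("playback",),
    include_interrupted: bool = True,
    sampler: SamplerConfig = SamplerConfig(),
) -> PreferenceEstimate:
    """Fit the Bayesian hierarchical logistic choice model.

    choice (1 = long-path side) ~ mu + fixed effects + bird intercepts
    [+ stimulus intercepts], with Normal(0, 1.5) priors on mu and fixed
    effects and half-Normal(1) priors on random-effect SDs.  Posterior
    sampling uses the affine-invariant ensemble sampler (emcee) on an
    aggregated binomial likelihood; convergence is assessed by split-Rhat
    over walker chains (threshold 1.01, flagged — never silently
    discarded) and LOO is computed from per-trial pointwise
    log-likelihoods via arviz (Pareto-smoothed importance sampling).
    Interrupted trials count as choices by default (the perch trigger is
    the choice); pass ``include_interrupted=False`` to drop them.
    """
    import arviz as az
    import emcee

    df = _choice_frame(logs, phases, include_interrupted)
    if "playback" in phases and not (df["phase"] == "playback").any():
        raise ValueError("no playback-phase choices present")
    d = _design(df, spec)
    log_prob, ndim, n_beta, n_birds, n_stim = _log_prob_factory(d, spec, sampler)

    rng = np.random.default_rng(sampler.seed)
    nw = max(sampler.n_walkers, 2 * ndim + 2)
    # initialize near the pooled empirical logit; bird/stimulus z's near 0
    pooled = d["cell_succ"].sum() / d["cell_n"].sum()
    pooled = min(max(pooled, 1e-3), 1 - 1e-3)
    p0 = 0.2 * rng.standard_normal((nw, ndim))
    p0[:, 0] += math.log(pooled / (1 - pooled))
    p0[:, 1 + n_beta] = np.log(0.5) + 0.2 * rng.standard_normal(nw)  # log sigma_bird

    # differential-evolution moves mix far better than the default stretch
    # move in the ~25-dimensional hierarchical posterior
    es = emcee.EnsembleSampler(
        nw,
        ndim,
        log_prob,
        vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    es.random_state = np.random.RandomState(sampler.seed).get_state()
    es.run_mcmc(p0, sampler.n_steps, progress=False)
    chain = es.get_chain(discard=sampler.n_burn, thin=sampler.thin)
    # (steps, walkers, ndim)
    chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)

    def _scalar_posterior(ch: np.ndarray) -> dict[str, np.ndarray]:
        post = {"mu": ch[:, :, 0], "sigma_bird": np.exp(ch[:, :, 1 + n_beta])}
        for j, c in enumerate(d["dummy_cols"]):
            post[c] = ch[:, :, 1 + j]
        return post

    scalar_vars = ["mu", "sigma_bird"] + d["dummy_cols"]
    idata_full = az.from_dict(posterior=_scalar_posterior(chain))
    rhats = az.rhat(idata_full, var_names=scalar_vars)
    rhat_max = float(max(float(rhats[v].values) for v in scalar_vars))
    converged = rhat_max <= sampler.rhat_threshold
    if not converged:
        warnings.warn(
            f"chains not converged: max split-Rhat {rhat_max:.4f} > "
            f"{sampler.rhat_threshold}",
            RuntimeWarning,
            stacklevel=2,
        )

    # thinned draws, reshaped to 4 pseudo-chains, with matching per-trial
    # log-likelihood so the LOO InferenceData is internally consistent
    flat = chain.reshape(-1, ndim)
    n_keep = min(sampler.loglik_draws, len(flat)) // 4 * 4
    take = np.linspace(0, len(flat) - 1, n_keep).astype(int)
    thin = flat[take]
    ll = _pointwise_loglik(thin, d, spec)  # (draws, n_trials)
    thin_chains = thin.reshape(4, n_keep // 4, ndim)
    idata = az.from_dict(posterior=_scalar_posterior(thin_chains))
    idata.add_groups(
        log_likelihood={"choice": ll.reshape(4, n_keep // 4, -1)}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo = az.loo(idata, pointwise=False)

    mu_draws = chain[:, :, 0].ravel()
    mean_logit = float(mu_draws.mean())
    lo, hi = np.percentile(mu_draws, [2.5, 97.5])
    return PreferenceEstimate(
        posterior_mean_logit=mean_logit,
        ci95_low=float(lo),
        ci95_high=float(hi),
        pr_mean=float(_expit(mean_logit)),
        model_label=spec.label,
        loo_score=float(loo.elpd_loo),
        sigma_bird_mean=float(np.exp(chain[:, :, 1 + n_beta]).mean()),
        rhat_max=rhat_max,
        converged=converged,
        n_obs=len(df),
        idata=idata,
    )


def compare_models(
    logs: Sequence[SessionLog],
    specs: Sequence[ModelSpec],
    phases: tuple[str, ...] = ("playback",),
    include_interrupted: bool = True,
    sampler: SamplerConfig = SamplerConfig(),
) -> pd.DataFrame:
    """LOO ranking of candidate models fit on identical data.

    All models are fit on the same trial rows (same phases and
    interruption handling), so their pointwise LOO scores are
    comparable.  Returns a table ranked by expected log predictive
    density with the standard error of each pairwise difference from
    the best model; models within one SE of the best are flagged as
    statistically indistinguishable ties.
    """
    import arviz as az

    if len(specs) < 2:
        raise ValueError("compare_models needs >= 2 model specs")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        labels = [f"{s.label}#{i}" for i, s in enumerate(specs)]
    fits = {
        lab: fit_choice_glmm(
            logs, spec, phases=phases, include_interrupted=include_interrupted,
            sampler=sampler,
        )
        for lab, spec in zip(labels, specs)
    }
    n_obs = {f.n_obs for f in fits.values()}
    if len(n_obs) != 1:
        raise ValueError("models were fit on differing row subsets")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp = az.compare({lab: f.idata for lab, f in fits.items()}, ic="loo")
    out = cmp[["rank", "elpd_loo", "elpd_diff", "dse"]].copy()
    out["tie_with_best"] = out["elpd_diff"] <= out["dse"].where(out["dse"] > 0, np.inf)
    out.loc[out["rank"] == 0, "tie_with_best"] = True
    return out
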