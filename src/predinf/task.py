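"""Generative task model and synthetic participants.

The predictive-inference task: on every trial a particle lands on the edge
of a circle at an angle drawn from a Gaussian around a hidden generative
mean (SD 12 degrees by default). With a fixed hazard rate (0.125) the mean
is re-drawn uniformly from the circle's 360 integer points — a change-point
(CP). The player places a bucket on the edge to catch the particle, rates
confidence on a 1-100 scale initialised at a random anchor (25 or 75), and
wins/loses 10 points per catch/miss. 200 trials, four blocks of 50.

Synthetic participants ("agents") replace human data for testing the whole
pipeline. Each agent owns latent traits held stable across the two sessions
(plus small session drift); the noisy-normative policy mixes the reduced
Bayesian learner's learning rate with a fixed one and adds motor noise, and
reports confidence as a noisy monotone function of the learner's certainty.
Trait variance between agents is what the downstream reliability machinery
is supposed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .circular import circ_diff, wrap360
from .learner import cpp_step, ru_step

__all__ = [
    "TaskConfig",
    "EnvironmentTrace",
    "AgentTraits",
    "TraitPopulation",
    "DEFAULT_POPULATION",
    "POLICIES",
    "generate_environment",
    "simulate_agent",
    "simulate_cohort",
]

RECORD_COLUMNS = [
    "participant_id",
    "session",
    "trial",
    "block",
    "gen_mean",
    "is_cp",
    "outcome",
    "bucket",
    "confidence",
    "anchor",
    "hit",
    "score",
]

POLICIES = ("noisy_normative", "always_update", "never_update", "random", "anchor_sticky")


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the task environment.

    ``bucket_halfwidth`` (degrees, half the bucket arc) governs hit
    probability; the task description leaves the arc size open, so it is a
    configurable with default 20.
    """

    n_trials: int = 200
    block_size: int = 50
    hazard: float = 0.125
    outcome_sd: float = 12.0
    circle_size: int = 360
    bucket_halfwidth: float = 20.0
    confidence_anchors: tuple = (25, 75)
    points_win: int = 10
    points_loss: int = -10

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError(f"n_trials must be positive, got {self.n_trials}")
        if not (0.0 <= self.hazard < 1.0):
            raise ValueError(f"hazard must be in [0, 1), got {self.hazard}")
        if self.outcome_sd < 0:
            raise ValueError(f"outcome_sd must be non-negative, got {self.outcome_sd}")
        if self.block_size <= 0 or self.n_trials % self.block_size:
            raise ValueError(
                f"block_size must divide n_trials, got block_size={self.block_size} "
                f"for n_trials={self.n_trials}"
            )
        if self.circle_size <= 0:
            raise ValueError(f"circle_size must be positive, got {self.circle_size}")
        if self.bucket_halfwidth <= 0:
            raise ValueError(f"bucket_halfwidth must be positive, got {self.bucket_halfwidth}")
        for a in self.confidence_anchors:
            if not (1 <= a <= 100):
                raise ValueError(f"confidence_anchors must lie in [1, 100], got {a}")


@dataclass
class EnvironmentTrace:
    """One session's hidden generative sequence and observed outcomes."""

    gen_mean: np.ndarray  # mu_t, integer degrees in [0, 360)
    is_cp: np.ndarray  # bool; trial 1 starts a run and is never a CP
    outcome: np.ndarray  # X_t, integer degrees in [0, 360)


# trait name -> (hard lower, hard upper) used when clipping population draws
_TRAIT_BOUNDS = {
    "norm_weight": (0.0, 1.0),
    "base_lr": (0.0, 1.0),
    "motor_noise_sd": (0.0, None),
    "conf_intercept": (1.0, 150.0),
    "conf_uncertainty_slope": (0.0, None),
    "conf_noise_sd": (0.0, None),
    "anchor_stick_prob": (0.0, 1.0),
}


@dataclass
class AgentTraits:
    """Latent parameters of one synthetic participant.

    norm_weight
        Mixing weight lambda in [0, 1] between the normative learning rate
        and a fixed one: effective LR = lambda*alpha_t + (1-lambda)*base_lr.
    base_lr
        The fixed (trait-like) learning rate in [0, 1].
    motor_noise_sd
        SD (degrees) of Gaussian noise on each bucket placement.
    conf_intercept, conf_uncertainty_slope, conf_noise_sd
        Confidence = intercept - slope * uncertainty + noise, clipped to
        [1, 100]; uncertainty is 100*(1 - (1-tau_t)*(1-Omega_{t-1})), a
        monotone transform of the learner's certainty heading into the trial.
    anchor_stick_prob
        Probability of leaving the confidence slider at its random anchor.
    """

    norm_weight: float = 0.8
    base_lr: float = 0.4
    motor_noise_sd: float = 8.0
    conf_intercept: float = 95.0
    conf_uncertainty_slope: float = 0.75
    conf_noise_sd: float = 8.0
    anchor_stick_prob: float = 0.05

    def __post_init__(self):
        for name in ("norm_weight", "base_lr", "anchor_stick_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("motor_noise_sd", "conf_noise_sd", "conf_uncertainty_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")


@dataclass(frozen=True)
class TraitPopulation:
    """Population distribution the cohort's traits are drawn from.

    ``means``/``sds`` give an independent Gaussian per trait, truncated by
    clipping to each trait's valid range. ``session_drift_frac`` scales the
    per-session perturbation: session trait = base + N(0, drift_frac * sd),
    re-clipped, so drift vanishes for traits the population holds fixed.
    """

    means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    session_drift_frac: float = 0.3

    def draw(self, rng: np.random.Generator) -> AgentTraits:
        vals = {}
        for name in _TRAIT_BOUNDS:
            v = rng.normal(self.means[name], self.sds[name])
            vals[name] = _clip_trait(name, v)
        return AgentTraits(**vals)

    def drift(self, base: AgentTraits, rng: np.random.Generator) -> AgentTraits:
        vals = {}
        for name in _TRAIT_BOUNDS:
            v = getattr(base, name) + rng.normal(0.0, self.session_drift_frac * self.sds[name])
            vals[name] = _clip_trait(name, v)
        return AgentTraits(**vals)


_DEFAULT_MEANS = {
    "norm_weight": 0.8,
    "base_lr": 0.4,
    "motor_noise_sd": 8.0,
    "conf_intercept": 95.0,
    "conf_uncertainty_slope": 0.75,
    "conf_noise_sd": 8.0,
    "anchor_stick_prob": 0.05,
}
_DEFAULT_SDS = {
    "norm_weight": 0.15,
    "base_lr": 0.20,
    "motor_noise_sd": 4.0,
    "conf_intercept": 8.0,
    "conf_uncertainty_slope": 0.20,
    "conf_noise_sd": 4.0,
    "anchor_stick_prob": 0.05,
}

DEFAULT_POPULATION = TraitPopulation()


def _clip_trait(name, value):
    lo, hi = _TRAIT_BOUNDS[name]
    if lo is not None:
        value = max(lo, value)
    if hi is not None:
        value = min(hi, value)
    return float(value)


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_environment(config: TaskConfig, seed) -> EnvironmentTrace:
    """Draw one session's change-point sequence and particle outcomes.

    Trial 1 initialises a run (never a CP); from trial 2 onward a CP occurs
    with probability ``config.hazard`` and the mean is re-drawn uniformly
    from the circle's integer points. Outcomes are Gaussian around the
    current mean (continuous draw, rounded to the nearest integer degree —
    the display resolution) and wrapped to [0, 360).
    """
    rng = _as_rng(seed)
    n = config.n_trials
    is_cp = np.zeros(n, dtype=bool)
    # U(1..circle_size) mapped onto [0, 360) via mod
    mu0 = rng.integers(1, config.circle_size + 1) % config.circle_size
    cp_draws = rng.random(n)
    redraws = rng.integers(1, config.circle_size + 1, size=n) % config.circle_size
    is_cp[1:] = cp_draws[1:] < config.hazard
    redraws[0] = mu0
    # each trial inherits the mean drawn at the most recent run start
    last_reset = np.maximum.accumulate(np.where(is_cp, np.arange(n), 0))
    mu = redraws[last_reset]
    outcome = rng.normal(mu, config.outcome_sd)
    outcome = np.rint(outcome).astype(int) % config.circle_size
    return EnvironmentTrace(gen_mean=mu, is_cp=is_cp, outcome=outcome.astype(float))


def simulate_agent(env, traits, config, policy="noisy_normative", seed=None):
    """Play one session of the task with a synthetic participant.

    Policies
    --------
    noisy_normative
        Runs the reduced Bayesian learner online on the agent's own
        prediction errors; the bucket moves by a traits-weighted mixture of
        the normative and fixed learning rates plus motor noise, and
        confidence tracks the learner's certainty (see AgentTraits).
    always_update
        Next bucket is placed exactly at the latest outcome (LR = 1).
    never_update
        The bucket never moves (LR = 0).
    random
        Bucket placed uniformly at random each trial.
    anchor_sticky
        Bucket as noisy_normative but the confidence slider is always left
        at its anchor (a planted defect for exclusion-rule tests).

    Returns a DataFrame of trial records (without participant/session ids).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy: {policy!r}; expected one of {POLICIES}")
    rng = _as_rng(seed)
    n = config.n_trials
    x = env.outcome
    sigma = config.outcome_sd
    anchors = np.asarray(config.confidence_anchors)

    bucket = np.empty(n)
    confidence = np.empty(n, dtype=int)
    anchor = anchors[rng.integers(0, anchors.size, size=n)]
    hit = np.empty(n, dtype=int)
    score = np.empty(n, dtype=int)

    bucket[0] = rng.uniform(0.0, 360.0)
    tau = 0.5
    omega_prev = 0.0  # no surprise carried into the first trial
    total = 0
    for t in range(n):
        # confidence is reported after placing the bucket, before the outcome
        if policy == "anchor_sticky":
            confidence[t] = anchor[t]
        else:
            certainty = 100.0 * (1.0 - tau) * (1.0 - omega_prev)
            uncertainty = 100.0 - certainty
            if rng.random() < traits.anchor_stick_prob:
                confidence[t] = anchor[t]
            else:
                c = (
                    traits.conf_intercept
                    - traits.conf_uncertainty_slope * uncertainty
                    + rng.normal(0.0, traits.conf_noise_sd)
                )
                confidence[t] = int(np.clip(np.rint(c), 1, 100))

        pe = circ_diff(x[t], bucket[t])
        hit[t] = int(abs(pe) <= config.bucket_halfwidth)
        total += config.points_win if hit[t] else config.points_loss
        score[t] = total

        # learner state advances on the agent's own error
        omega = cpp_step(pe, tau, sigma, config.hazard, config.circle_size)
        alpha = omega + (1.0 - omega) * tau
        tau = ru_step(omega, tau, pe, sigma)
        omega_prev = omega

        if t + 1 < n:
            if policy == "always_update":
                bucket[t + 1] = x[t]
            elif policy == "never_update":
                bucket[t + 1] = bucket[t]
            elif policy == "random":
                bucket[t + 1] = rng.uniform(0.0, 360.0)
            else:  # noisy_normative / anchor_sticky
                lr = traits.norm_weight * alpha + (1.0 - traits.norm_weight) * traits.base_lr
                step = lr * pe
                if traits.motor_noise_sd > 0:
                    step += rng.normal(0.0, traits.motor_noise_sd)
                bucket[t + 1] = float(wrap360(bucket[t] + step))

    trials = np.arange(1, n + 1)
    return pd.DataFrame(
        {
            "trial": trials,
            "block": (trials - 1) // config.block_size + 1,
            "gen_mean": env.gen_mean.astype(float),
            "is_cp": env.is_cp.astype(int),
            "outcome": x,
            "bucket": bucket,
            "confidence": confidence,
            "anchor": anchor,
            "hit": hit,
            "score": score,
        }
    )


def simulate_cohort(
    n_participants,
    config: TaskConfig | None = None,
    population: TraitPopulation | None = None,
    seed=None,
    n_sessions=2,
    policy="noisy_normative",
):
    """Simulate a multi-session cohort with participant-stable traits.

    Each participant's traits are drawn once from ``population`` and then
    perturbed independently per session (session drift); every
    participant x session gets a fresh task environment. Returns
    ``(records, traits)``: the long-format trial table (RECORD_COLUMNS) and
    the per participant x session ground-truth trait table.
    """
    if n_participants < 2:
        raise ValueError(
            f"n_participants must be >= 2 for downstream psychometrics, got {n_participants}"
        )
    config = config or TaskConfig()
    population = population or DEFAULT_POPULATION
    root = np.random.SeedSequence(seed)
    frames = []
    trait_rows = []
    for pid_seq in root.spawn(n_participants):
        streams = pid_seq.spawn(2 * n_sessions + 1)
        pid = int(pid_seq.spawn_key[-1]) + 1
        base = population.draw(np.random.default_rng(streams[0]))
        for s in range(1, n_sessions + 1):
            traits = population.drift(base, np.random.default_rng(streams[2 * s - 1]))
            sess_rng = np.random.default_rng(streams[2 * s])
            env = generate_environment(config, sess_rng)
            rec = simulate_agent(env, traits, config, policy=policy, seed=sess_rng)
            rec.insert(0, "session", s)
            rec.insert(0, "participant_id", pid)
            frames.append(rec)
            row = {"participant_id": pid, "session": s}
            row.update({f.name: getattr(traits, f.name) for f in fields(traits)})
            trait_rows.append(row)
    records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    traits = pd.DataFrame(trait_rows)
    return records, traits
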