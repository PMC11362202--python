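"""Reduced quasi-optimal Bayesian learner for change-point environments.

The learner tracks a point belief about the generative mean of a circular
outcome process that is occasionally re-drawn (with hazard rate ``H``) from
a uniform distribution over the circle. Two latent quantities summarise its
state on every trial:

* change-point probability (CPP, ``omega``): the posterior probability that
  the latest outcome came from a freshly drawn mean rather than the current
  one, obtained by comparing a uniform outcome density against a Gaussian
  predictive density centred on the belief;
* relative uncertainty (RU, ``tau``): the model's estimation uncertainty
  about the mean, expressed as a fraction of total predictive variance.

From these the per-trial normative learning rate is
``alpha = omega + (1 - omega) * tau`` and the belief moves by
``alpha * delta`` where ``delta`` is the prediction error.

The recursion can be driven either by the model's own prediction errors
("normative" mode) or by the errors a participant actually experienced at
their bucket position ("conditioned_on_participant" mode), which is how the
trial-wise CPP/RU regressors for behavioural analyses are obtained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import circ_diff, wrap360

__all__ = ["NormativeSeries", "cpp_step", "ru_step", "run_reduced_bayes"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class NormativeSeries:
    """Trial-wise learner quantities, aligned with the input trials.

    Attributes
    ----------
    cpp : change-point probability Omega_t in [0, 1].
    ru : relative uncertainty tau_t in (0, 1), the value *used* on trial t
        (i.e. before observing the trial-t outcome).
    model_lr : normative learning rate alpha_t = Omega_t + (1-Omega_t)*tau_t.
    belief : the learner's predicted mean B_t (degrees) heading into trial t.
    pred_sd : total predictive SD sigma/sqrt(1-tau_t) in degrees.
    model_pe : the error delta_t (degrees, signed) that drove trial t.
    """

    cpp: np.ndarray
    ru: np.ndarray
    model_lr: np.ndarray
    belief: np.ndarray
    pred_sd: np.ndarray
    model_pe: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cpp": self.cpp,
                "ru": self.ru,
                "model_lr": self.model_lr,
                "belief": self.belief,
                "pred_sd": self.pred_sd,
                "model_pe": self.model_pe,
            }
        )


def cpp_step(delta, tau, sigma, hazard, circle_size=360):
    """Change-point probability for a signed circular error ``delta``.

    Posterior odds of "new mean" vs "same mean" combine the hazard prior
    with a uniform outcome density U = 1/circle_size against a Gaussian
    predictive density N(delta; 0, sigma^2/(1-tau)). Computed with log
    densities so large |delta|/small sigma cannot underflow.
    """
    if not (0.0 < hazard < 1.0):
        raise ValueError(f"hazard must be in (0, 1), got {hazard}")
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    pred_var = sigma**2 / (1.0 - tau)
    log_u = -np.log(circle_size)
    log_n = -_LOG_SQRT_2PI - 0.5 * np.log(pred_var) - 0.5 * delta**2 / pred_var
    # omega = H*U / (H*U + (1-H)*N) via a numerically safe logistic
    log_odds = np.log(hazard) + log_u - np.log1p(-hazard) - log_n
    return float(1.0 / (1.0 + np.exp(-log_odds)))


def ru_step(omega, tau, delta, sigma):
    """One update of relative uncertainty after observing error ``delta``.

    The posterior variance about the mean mixes the change and no-change
    branches plus the between-branch disagreement:

        s^2 = omega*sigma^2 + (1-omega)*tau*sigma^2
              + omega*(1-omega) * (delta*(1-tau))^2

    and the next relative uncertainty is s^2 / (s^2 + sigma^2). Closed
    forms: omega=0 gives tau/(tau+1); omega=1 gives 1/2.
    """
    s2 = (
        omega * sigma**2
        + (1.0 - omega) * tau * sigma**2
        + omega * (1.0 - omega) * (delta * (1.0 - tau)) ** 2
    )
    return float(s2 / (s2 + sigma**2))


def run_reduced_bayes(outcomes, config, mode="normative", buckets=None):
    """Run the learner over one session's outcome sequence.

    Parameters
    ----------
    outcomes : array of landing angles X_t in degrees, trial order.
    config : TaskConfig (uses hazard, outcome_sd, circle_size).
    mode : "normative" drives the recursion with the model's own error
        delta_t = X_t - B_t; "conditioned_on_participant" uses the
        participant's error delta_t = X_t - b_t at their bucket, so CPP/RU
        reflect the surprise and uncertainty the participant experienced.
    buckets : bucket positions b_t, required in conditioned mode.

    Returns
    -------
    NormativeSeries with one entry per trial. Initialisation: tau_1 = 0.5
    (a single outcome pins the mean no better than half the predictive
    variance) and B_1 anchored at the first observation (first outcome in
    normative mode, first bucket in conditioned mode), so delta_1 = 0 in
    normative mode.
    """
    x = np.asarray(outcomes, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty outcome series")
    conditioned = mode == "conditioned_on_participant"
    if conditioned:
        if buckets is None:
            raise ValueError("conditioned_on_participant mode requires buckets")
        b = np.asarray(buckets, dtype=float)
        if b.size != n:
            raise ValueError("buckets and outcomes must have equal length")
    elif mode != "normative":
        raise ValueError(f"unknown mode: {mode!r}")

    sigma = config.outcome_sd
    hazard = config.hazard
    circle = config.circle_size

    cpp = np.empty(n)
    ru = np.empty(n)
    alpha = np.empty(n)
    belief = np.empty(n)
    pred_sd = np.empty(n)
    model_pe = np.empty(n)

    tau = 0.5
    bel = x[0] if not conditioned else b[0]
    for t in range(n):
        belief[t] = bel
        ru[t] = tau
        pred_sd[t] = sigma / np.sqrt(1.0 - tau)
        delta = circ_diff(x[t], b[t]) if conditioned else circ_diff(x[t], bel)
        model_pe[t] = delta
        omega = cpp_step(delta, tau, sigma, hazard, circle)
        cpp[t] = omega
        alpha[t] = omega + (1.0 - omega) * tau
        bel = float(wrap360(bel + alpha[t] * delta))
        tau = ru_step(omega, tau, delta, sigma)

    return NormativeSeries(cpp, ru, alpha, belief, pred_sd, model_pe)
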