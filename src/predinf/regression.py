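"""Per-participant regression models and group-level tests.

Three model families, each fit separately per participant x session:

* the circular action-update model — a Von Mises regression of the signed
  bucket update on the prediction error and its interactions with the
  normative regressors (CPP, RU) and accuracy (Hit), estimated by maximum
  a posteriori with weak zero-centred Gaussian priors (SD 5) on each
  coefficient and a jointly estimated concentration kappa;
* linear confidence models — OLS of the (z-scored) confidence rating on
  the previous trial's z-scored |PE|, CPP, RU and binary Hit, in variants
  that separate |PE| from CPP because the two are strongly collinear;
* the action-confidence coupling — OLS of confidence on the magnitude of
  the action-update that produced the current bucket position.

Group-level inference is a one-sample two-sided t test of the
per-participant coefficients against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "RegressionFit",
    "GroupTestResult",
    "zscore",
    "circular_log_posterior",
    "fit_circular_update_model",
    "fit_confidence_model",
    "fit_action_confidence",
    "group_level_test",
    "CONFIDENCE_VARIANTS",
]

DEG = np.pi / 180.0

CIRC_COEF_NAMES = ("PE", "PExCPP", "PExRU", "PExHit")
CONFIDENCE_VARIANTS = {
    "pe_model": ("abs_pe", "ru", "hit"),
    "cpp_model": ("cpp", "ru", "hit"),
    "combined": ("abs_pe", "cpp", "ru", "hit"),
}
_CONF_COEF_NAMES = {"abs_pe": "|PE|", "cpp": "CPP", "ru": "RU", "hit": "Hit"}


@dataclass
class RegressionFit:
    """One participant's fitted model."""

    model: str
    coefficients: dict
    se: dict
    kappa: float | None  # circular model only
    resid_sd: float | None  # linear models only
    log_posterior: float
    converged: bool
    n_trials_used: int
    extra: dict = field(default_factory=dict)


@dataclass
class GroupTestResult:
    coefficient: str
    mean: float
    se: float
    t: float
    df: int
    p: float


def zscore(x, ddof: int = 1):
    """Standardise to zero mean, unit SD; constant input raises."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=ddof)
    if sd == 0 or np.isnan(sd):
        raise ValueError("cannot z-score a constant series")
    return (x - np.mean(x)) / sd


def _log_i0(kappa):
    # log I0 via the exponentially scaled Bessel function, stable for large kappa
    return np.log(special.i0e(kappa)) + kappa


def circular_log_posterior(beta, kappa, X, y, prior_width=5.0):
    """Log posterior of the circular update model at (beta, kappa).

    ``X`` is the (n, p) design in degrees, ``y`` the observed updates in
    degrees. Likelihood: y_i ~ VonMises(mu_i = X_i beta, kappa) with angles
    converted to radians; prior: independent N(0, prior_width^2) on each
    beta and flat on log kappa. ``prior_width=None`` drops the prior
    (maximum likelihood).
    """
    mu = X @ np.asarray(beta, dtype=float)
    resid = (np.asarray(y, dtype=float) - mu) * DEG
    ll = np.sum(kappa * np.cos(resid)) - y.size * (np.log(2 * np.pi) + _log_i0(kappa))
    if prior_width is None:
        return float(ll)
    lp = np.sum(stats.norm.logpdf(beta, 0.0, prior_width))
    return float(ll + lp)


def _numerical_hessian(f, x, h=1e-4):
    """Central-difference Hessian of scalar f at x."""
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def _centre(v):
    return v - np.mean(v)


def fit_circular_update_model(
    data,
    prior_width: float = 5.0,
    n_starts: int = 3,
    seed=None,
    tol: float = 1e-6,
) -> RegressionFit:
    """MAP fit of the Von Mises action-update model for one participant.

    ``data`` needs columns ``update``, ``pe``, ``cpp``, ``ru``, ``hit``,
    already restricted to valid learning-rate trials. The linear predictor
    (degrees) is

        mu_t = b_PE*PE_t + b_CPP*PE_t*CPP_c + b_RU*PE_t*RU_c + b_Hit*PE_t*Hit_c

    with CPP, RU and Hit mean-centred within the participant (so b_PE is
    the error-driven update weight at the participant's average trial, a
    learning-rate-like quantity in [0, 1] for sensible behaviour). No
    intercept: updates are error-driven. The optimiser runs from
    ``n_starts`` starting points (an OLS warm start, zeros, and random
    perturbations) and keeps the best optimum; standard errors come from
    the numerical Hessian of the negative log posterior.
    """
    rows = data.dropna(subset=["update", "pe", "cpp", "ru", "hit"])
    pe = rows["pe"].to_numpy(dtype=float)
    y = rows["update"].to_numpy(dtype=float)
    n = y.size
    if n < 6:
        raise ValueError(f"need at least 6 valid trials, got {n}")
    X = np.column_stack(
        [
            pe,
            pe * _centre(rows["cpp"].to_numpy(dtype=float)),
            pe * _centre(rows["ru"].to_numpy(dtype=float)),
            pe * _centre(rows["hit"].to_numpy(dtype=float)),
        ]
    )

    def neg_obj(theta):
        beta, log_kappa = theta[:-1], theta[-1]
        return -circular_log_posterior(beta, np.exp(log_kappa), X, y, prior_width)

    # OLS warm start; crude kappa from the circular residual variance
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = (y - X @ beta_ols) * DEG
    r_bar = float(np.clip(np.mean(np.cos(resid)), 1e-3, 1 - 1e-6))
    kappa0 = r_bar * (2 - r_bar**2) / (1 - r_bar**2)  # standard approximation
    rng = np.random.default_rng(seed)
    starts = [np.append(beta_ols, np.log(kappa0)), np.append(np.zeros(4), 0.0)]
    while len(starts) < n_starts:
        starts.append(starts[0] + rng.normal(0.0, 0.2, size=5))

    best = None
    any_ok = False
    for x0 in starts:
        nm = optimize.minimize(
            neg_obj, x0, method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-6, "maxiter": 4000},
        )
        res = optimize.minimize(neg_obj, nm.x, method="BFGS", options={"gtol": 1e-8})
        if not np.isfinite(res.fun) or res.fun > nm.fun:
            res = nm
        # BFGS can stop on precision loss at an already-polished optimum;
        # count the start as converged if either stage reports success
        any_ok = any_ok or ((nm.success or res.success) and np.isfinite(res.fun))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("all optimiser starts diverged")

    theta = best.x
    H = _numerical_hessian(neg_obj, theta)
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(theta.size, np.nan)
    coef = dict(zip(CIRC_COEF_NAMES, theta[:-1]))
    se = dict(zip(CIRC_COEF_NAMES, ses[:-1]))
    return RegressionFit(
        model="circular_update",
        coefficients=coef,
        se=se,
        kappa=float(np.exp(theta[-1])),
        resid_sd=None,
        log_posterior=float(-best.fun),
        converged=bool(any_ok),
        n_trials_used=n,
        extra={"prior_width": prior_width},
    )


def _ols(X, y, names):
    """Plain OLS with classical standard errors."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    dof = n - p
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    ses = np.sqrt(np.clip(s2 * np.diag(XtX_inv), 0.0, None))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    ll = -0.5 * n * (np.log(2 * np.pi * max(s2, 1e-300)) + 1.0)
    return dict(zip(names, beta)), dict(zip(names, ses)), np.sqrt(s2), ll, r2


def fit_confidence_model(data, variant: str = "pe_model") -> RegressionFit:
    """OLS confidence model for one participant x session.

    Confidence on trial t is regressed on regressors from trial t-1:
    z-scored |PE|, CPP and RU (continuous, standardised within the
    participant x session) and binary Hit. Variants: ``pe_model``
    (|PE|, RU, Hit), ``cpp_model`` (CPP, RU, Hit) — separated because |PE|
    and CPP are strongly collinear — and ``combined`` (all four, as a
    control; its design condition number is reported).
    """
    if variant not in CONFIDENCE_VARIANTS:
        raise ValueError(f"unknown variant: {variant!r}")
    cols = CONFIDENCE_VARIANTS[variant]
    d = data.sort_values("trial")
    y_raw = d["confidence"].to_numpy(dtype=float)[1:]  # confidence at t
    lagged = {c: d[c].to_numpy(dtype=float)[:-1] for c in cols}  # regressors at t-1
    ok = ~np.any([np.isnan(v) for v in lagged.values()], axis=0)
    y_raw = y_raw[ok]
    lagged = {c: v[ok] for c, v in lagged.items()}

    y = zscore(y_raw)
    names = ["intercept"]
    columns = [np.ones(y.size)]
    dropped = []
    for c in cols:
        v = lagged[c]
        if np.std(v) == 0:
            dropped.append(c)
            warnings.warn(f"zero-variance regressor {c!r} dropped", stacklevel=2)
            continue
        columns.append(v if c == "hit" else zscore(v))
        names.append(_CONF_COEF_NAMES[c])
    X = np.column_stack(columns)
    coef, se, resid_sd, ll, r2 = _ols(X, y, names)
    extra = {"r2": r2, "dropped": dropped}
    extra["condition_number"] = float(np.linalg.cond(X))
    return RegressionFit(
        model=f"confidence_{variant}",
        coefficients=coef,
        se=se,
        kappa=None,
        resid_sd=resid_sd,
        log_posterior=ll,
        converged=True,
        n_trials_used=int(y.size),
        extra=extra,
    )


def fit_action_confidence(data) -> RegressionFit:
    """Action-confidence coupling for one participant x session.

    The confidence reported at trial t follows the bucket placement
    produced by the update u_{t-1} = b_t - b_{t-1}; confidence is regressed
    on |u_{t-1}|. Three scalings are returned: ``abs_update`` is the
    primary slope (raw confidence per SD of |update|, i.e. the predictor is
    standardised), ``abs_update_raw`` is per degree, and ``abs_update_zz``
    standardises both variables.
    """
    d = data.sort_values("trial")
    conf = d["confidence"].to_numpy(dtype=float)[1:]
    upd = np.abs(d["update"].to_numpy(dtype=float))[:-1]
    ok = ~np.isnan(upd)
    conf, upd = conf[ok], upd[ok]
    if np.std(conf) == 0:
        raise ValueError("constant confidence: coupling undefined")
    if np.std(upd) == 0:
        raise ValueError("constant |update|: coupling undefined")

    X = np.column_stack([np.ones(conf.size), zscore(upd)])
    coef, se, resid_sd, ll, r2 = _ols(X, conf, ["intercept", "abs_update"])
    raw_coef, raw_se, *_ = _ols(
        np.column_stack([np.ones(conf.size), upd]), conf, ["intercept", "abs_update_raw"]
    )
    zz_coef, zz_se, *_ = _ols(X, zscore(conf), ["intercept", "abs_update_zz"])
    coef["abs_update_raw"] = raw_coef["abs_update_raw"]
    se["abs_update_raw"] = raw_se["abs_update_raw"]
    coef["abs_update_zz"] = zz_coef["abs_update_zz"]
    se["abs_update_zz"] = zz_se["abs_update_zz"]
    return RegressionFit(
        model="action_confidence",
        coefficients=coef,
        se=se,
        kappa=None,
        resid_sd=resid_sd,
        log_posterior=ll,
        converged=True,
        n_trials_used=int(conf.size),
        extra={"r2": r2},
    )


def group_level_test(fits, coefficient: str) -> GroupTestResult:
    """Two-sided one-sample t test of per-participant coefficients vs zero."""
    vals = np.array(
        [f.coefficients[coefficient] for f in fits if f.converged], dtype=float
    )
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 converged fits")
    if np.std(vals, ddof=1) == 0:
        if vals.mean() != 0.0:
            raise ValueError("zero variance across participants")
        return GroupTestResult(coefficient=coefficient, mean=0.0, se=0.0, t=0.0,
                               df=int(vals.size - 1), p=1.0)
    res = stats.ttest_1samp(vals, 0.0)
    return GroupTestResult(
        coefficient=coefficient,
        mean=float(vals.mean()),
        se=float(vals.std(ddof=1) / np.sqrt(vals.size)),
        t=float(res.statistic),
        df=int(vals.size - 1),
        p=float(res.pvalue),
    )
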