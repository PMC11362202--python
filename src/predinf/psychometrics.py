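"""Reliability machinery: split-half internal consistency, test-retest ICC,
category labels, change-point subsampling curves, and correlation power.

Internal consistency splits one session's data into two halves — either by
alternating change-point segments (a CP trial and everything up to the next
CP), which keeps the CP-relative structure intact in both halves, or by
trial parity for regression measures — computes the measure per half and
participant, correlates the halves across participants, and extrapolates to
full length with the Spearman-Brown formula r_SB = 2r / (1 + r).

Test-retest reliability is the intraclass correlation between sessions.
ICC(2,1) (two-way random effects, absolute agreement, single measure)
treats session as a random effect so systematic between-session shifts
count against reliability; ICC(3,1) treats it as fixed. Both come from the
two-way ANOVA mean squares, alongside the participant/session/error
variance decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "spearman_brown",
    "categorize",
    "SplitHalfResult",
    "ICCResult",
    "add_cp_segments",
    "split_cp_segments",
    "split_half",
    "split_half_scores",
    "icc",
    "reliability_vs_ncps",
    "required_n_correlation",
]

_KEY = ["participant_id", "session"]


def spearman_brown(r: float) -> float:
    """Step up a half-test correlation to full length: 2r / (1 + r)."""
    if r == -1.0:
        return -np.inf
    return 2.0 * r / (1.0 + r)


def categorize(value: float, kind: str) -> str:
    """Conventional reliability labels.

    Internal consistency: below 0.5 'low', 0.5-0.7 'moderate', above 0.7
    'good'. ICC: below 0.5 'low', 0.5-0.75 'moderate', above 0.75 'good'.
    Boundary values take the lower interval's label (0.5 is 'moderate').
    """
    if kind == "consistency":
        hi = 0.7
    elif kind == "icc":
        hi = 0.75
    else:
        raise ValueError(f"unknown kind: {kind!r}")
    if not np.isfinite(value):
        raise ValueError(f"cannot categorise non-finite value {value}")
    if value < 0.5:
        return "low"
    if value <= hi:
        return "moderate"
    return "good"


@dataclass
class SplitHalfResult:
    r: float
    r_sb: float
    ci95: tuple
    n: int
    category: str
    mode: str


@dataclass
class ICCResult:
    icc21: float
    icc31: float
    ci95_21: tuple
    ci95_31: tuple
    variance_components: dict  # percentages: participant, time, error
    n: int
    k: int
    category: str  # for ICC(2,1), the primary estimate


def add_cp_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``cp_segment`` column: 0 before the first CP, then one
    segment per CP (the CP trial through the trial before the next CP),
    counted within each participant x session."""
    out = df.sort_values(_KEY + ["trial"], kind="stable").copy()
    out["cp_segment"] = out.groupby(_KEY, sort=False)["is_cp"].cumsum().astype(int)
    return out


def split_cp_segments(df: pd.DataFrame):
    """Partition a session table into two halves by alternating CP segments.

    Segments (including the leading pre-first-CP segment 0) are assigned to
    halves by parity of their index, so each half keeps whole CP-relative
    windows and the per-half CP counts differ by at most one. Requires at
    least 4 segments in every participant x session.
    """
    seg = add_cp_segments(df)
    n_segs = seg.groupby(_KEY)["cp_segment"].max() + 1
    if (n_segs < 4).any():
        bad = n_segs[n_segs < 4].index.tolist()
        raise ValueError(f"fewer than 4 CP segments in {bad}; refusing to split")
    even = seg[seg["cp_segment"] % 2 == 0].drop(columns="cp_segment")
    odd = seg[seg["cp_segment"] % 2 == 1].drop(columns="cp_segment")
    return even, odd


def _split_odd_even_trials(df: pd.DataFrame):
    odd = df[df["trial"] % 2 == 1]
    even = df[df["trial"] % 2 == 0]
    return odd, even


def _fisher_ci(r, n, level=0.95):
    if n < 4:
        return (np.nan, np.nan)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def split_half(extractor, df: pd.DataFrame, mode: str = "cp_segments") -> SplitHalfResult:
    """Split-half internal consistency of a per-participant measure.

    ``extractor(half) -> Series`` maps a (half-)dataset to one value per
    participant (indexed by participant_id). The halves' measures are
    correlated across participants (Pearson), stepped up with
    Spearman-Brown, and a 95% CI is built on the Fisher-z scale for r with
    the endpoints Spearman-Brown transformed. Negative corrected values are
    reported as computed, with a warning.
    """
    if mode == "cp_segments":
        half_a, half_b = split_cp_segments(df)
    elif mode == "odd_even_trials":
        half_a, half_b = _split_odd_even_trials(df)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return split_half_scores(extractor(half_a), extractor(half_b), mode=mode)


def split_half_scores(ma: pd.Series, mb: pd.Series, mode: str = "paired") -> SplitHalfResult:
    """Spearman-Brown corrected correlation between two per-participant
    half-measures (aligned on their index)."""
    paired = pd.concat([ma.rename("a"), mb.rename("b")], axis=1).dropna()
    n = len(paired)
    if n < 3:
        raise ValueError(f"only {n} participants with both half-measures")
    if n < 10:
        warnings.warn(f"only {n} participants; the CI is unstable", stacklevel=2)
    r = float(stats.pearsonr(paired["a"], paired["b"])[0])
    r_sb = spearman_brown(r)
    if r_sb < 0:
        warnings.warn(f"negative corrected reliability ({r_sb:.3f})", stacklevel=2)
    lo, hi = _fisher_ci(r, n)
    return SplitHalfResult(
        r=r,
        r_sb=float(r_sb),
        ci95=(float(spearman_brown(lo)), float(spearman_brown(hi))),
        n=n,
        category=categorize(r_sb, "consistency") if np.isfinite(r_sb) else "low",
        mode=mode,
    )


def icc(scores_t1, scores_t2, level: float = 0.95) -> ICCResult:
    """Intraclass correlations between two sessions of paired scores.

    Input series must be paired by participant (aligned positionally or on
    a shared index); pairs with a missing value are dropped. Mean squares
    from the two-way layout (rows = participants, columns = sessions):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

    Variance components (participant, time, error) are the corresponding
    expected-mean-square solutions, clipped at zero and expressed as
    percentages of their total. CIs use the standard F-based intervals
    (exact for ICC(3,1), the Satterthwaite-style approximation for
    ICC(2,1)).
    """
    a = pd.Series(scores_t1)
    b = pd.Series(scores_t2)
    if isinstance(scores_t1, pd.Series) and isinstance(scores_t2, pd.Series):
        m = pd.concat([a.rename("t1"), b.rename("t2")], axis=1).dropna().to_numpy()
    else:
        m = np.column_stack([a.to_numpy(), b.to_numpy()])
        m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc31 = (msr - mse) / (msr + (k - 1) * mse)

    var_p = max((msr - mse) / k, 0.0)
    var_t = max((msc - mse) / n, 0.0)
    var_e = max(mse, 0.0)
    total = var_p + var_t + var_e
    comps = {
        "participant": 100.0 * var_p / total,
        "time": 100.0 * var_t / total,
        "error": 100.0 * var_e / total,
    }

    alpha = 1.0 - level
    with np.errstate(divide="ignore", invalid="ignore"):
        # ICC(3,1): exact F interval
        f31 = msr / mse if mse > 0 else np.inf
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f31 / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f31 * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci31 = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))

        # ICC(2,1): McGraw & Wong approximation
        fj = msc / mse if mse > 0 else np.inf
        r = icc21
        a_ = (k * r) / (n * (1 - r)) if r < 1 else np.inf
        b_ = 1 + (k * r * (n - 1)) / (n * (1 - r)) if r < 1 else np.inf
        v_num = (a_ * fj + b_) ** 2
        v_den = (a_**2 * fj**2) / (k - 1) + (b_**2) / ((n - 1) * (k - 1))
        v = v_num / v_den
        f_star_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_star_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower21 = (n * (msr - f_star_l * mse)) / (
            f_star_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper21 = (n * (f_star_u * msr - mse)) / (
            k * msc + (k * n - k - n) * mse + n * f_star_u * msr
        )
    # degenerate layouts (zero error variance) collapse the intervals
    if not np.isfinite(lower21):
        lower21 = icc21
    if not np.isfinite(upper21):
        upper21 = icc21
    ci31 = tuple(c if np.isfinite(c) else icc31 for c in ci31)
    return ICCResult(
        icc21=float(icc21),
        icc31=float(icc31),
        ci95_21=(float(lower21), float(upper21)),
        ci95_31=(float(ci31[0]), float(ci31[1])),
        variance_components=comps,
        n=n,
        k=k,
        category=categorize(icc21, "icc") if np.isfinite(icc21) else "low",
    )


def reliability_vs_ncps(df: pd.DataFrame, estimate_fn, cp_range=range(6, 25)) -> pd.DataFrame:
    """Reliability as a function of the number of change-points used.

    For each m in ``cp_range``, every participant x session is restricted
    to its chronologically first m CP segments (the leading pre-CP segment
    is always kept; sessions with fewer than m CPs contribute all their
    trials), and ``estimate_fn(sub_dataset)`` — returning a
    SplitHalfResult or ICCResult — is recomputed on the restriction.
    """
    if min(cp_range) < 6:
        raise ValueError("fewer than 6 change-points gives unstable splits")
    seg = add_cp_segments(df)
    rows = []
    for m in cp_range:
        sub = seg[seg["cp_segment"] <= m].drop(columns="cp_segment")
        res = estimate_fn(sub)
        if isinstance(res, SplitHalfResult):
            est, (lo, hi) = res.r_sb, res.ci95
        elif isinstance(res, ICCResult):
            est, (lo, hi) = res.icc21, res.ci95_21
        else:
            raise TypeError(f"estimate_fn returned {type(res).__name__}")
        rows.append(
            {
                "n_cps": m,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "n": res.n,
                "category": res.category,
            }
        )
    return pd.DataFrame(rows)


def _log_r_density(r, n, rho):
    """Log density of the sample correlation under bivariate normality."""
    return (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + 0.5 * (n - 1) * np.log1p(-(rho**2))
        + 0.5 * (n - 4) * np.log1p(-(r**2))
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        + (1.5 - n) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2))
    )


def _exact_power(n, rho, alpha, tail):
    """Power of the test of rho = 0 at sample size n (bivariate normal)."""
    df = n - 2
    a = alpha if tail == "one" else alpha / 2
    t_crit = stats.t.ppf(1 - a, df)
    r_crit = t_crit / np.sqrt(df + t_crit**2)
    dens = lambda r: np.exp(_log_r_density(r, n, rho))
    upper, _ = integrate.quad(dens, r_crit, 1.0, limit=200)
    if tail == "one":
        return upper
    lower, _ = integrate.quad(dens, -1.0, -r_crit, limit=200)
    return upper + lower


def _nct_power(n, rho, alpha, tail):
    """Noncentral-t approximation used by common power software.

    Treats the correlation test as a t test with noncentrality
    delta = rho * sqrt(n) / sqrt(1 - rho^2) (the point-biserial model).
    """
    df = n - 2
    a = alpha if tail == "one" else alpha / 2
    t_crit = stats.t.ppf(1 - a, df)
    delta = rho * np.sqrt(n) / np.sqrt(1 - rho**2)
    power = 1 - stats.nct.cdf(t_crit, df, delta)
    if tail == "two":
        power += stats.nct.cdf(-t_crit, df, delta)
    return power


def required_n_correlation(
    rho: float,
    alpha: float = 0.01,
    power: float = 0.90,
    tail: str = "two",
    method: str = "exact",
) -> int:
    """Smallest N detecting a correlation ``rho`` with the given power.

    Methods
    -------
    exact
        Integrates the exact sampling density of the Pearson correlation
        under a bivariate normal with true correlation ``rho`` against the
        critical region of the usual t test of rho = 0.
    nct
        The noncentral-t (point-biserial) approximation that common power
        software applies to correlation tests; slightly anti-conservative
        relative to the exact computation.
    fisher_z
        The closed-form normal approximation
        N = ((z_{1-a} + z_{power}) / atanh(rho))^2 + 3.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    if tail not in ("two", "one"):
        raise ValueError(f"tail must be 'two' or 'one', got {tail!r}")
    if method == "fisher_z":
        a = alpha if tail == "one" else alpha / 2
        za = stats.norm.ppf(1 - a)
        zb = stats.norm.ppf(power)
        return int(np.ceil(((za + zb) / np.arctanh(rho)) ** 2 + 3))
    if method == "exact":
        power_fn = _exact_power
    elif method == "nct":
        power_fn = _nct_power
    else:
        raise ValueError(f"unknown method: {method!r}")

    lo, hi = 4, 8
    while power_fn(hi, rho, alpha, tail) < power:
        lo, hi = hi, hi * 2
        if hi > 1_000_000:
            raise RuntimeError("sample size search did not converge")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_fn(mid, rho, alpha, tail) >= power:
            hi = mid
        else:
            lo = mid
    return hi
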