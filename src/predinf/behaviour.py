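"""Raw behavioural measures, validity filters, and change-point alignment.

From the trial log this module derives, per participant x session:

* the prediction error ``pe`` — signed circular distance from the bucket
  centre to the particle's landing angle, PE_t = X_t - b_t;
* the action-update ``update`` — signed circular bucket move u_t =
  b_{t+1} - b_t (undefined on the last trial);
* the human learning rate ``lr`` = update / pe, 1 meaning a full move to
  the latest outcome and 0 no move (undefined where pe = 0).

It also implements the data-quality screens applied to the confidence
scale, the pooled 99th-percentile learning-rate trim used before any
analysis involving the normative regressors, and the alignment of any
trial-wise measure to change-points at offsets -4..+4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import circ_diff

__all__ = [
    "derive_series",
    "lr_validity_mask",
    "apply_confidence_exclusions",
    "align_to_cps",
    "cp_effect_test",
    "ExclusionReport",
    "GroupTest",
]

OFFSETS = tuple(range(-4, 5))

_KEY = ["participant_id", "session"]


def derive_series(records: pd.DataFrame, mode: str = "circular") -> pd.DataFrame:
    """Add pe, update, lr, abs_pe and hit_prev columns to a trial log.

    ``mode='circular'`` (default) uses signed circular distances on
    (-180, 180]. ``mode='linear'`` is the robustness variant using unsigned
    shortest distances for both numerator and denominator, so lr >= 0.

    Rows must carry consecutive unique trial indices within each
    participant x session.
    """
    if mode not in ("circular", "linear"):
        raise ValueError(f"unknown mode: {mode!r}")
    out = records.sort_values(_KEY + ["trial"], kind="stable").reset_index(drop=True)

    def _per_session(g: pd.DataFrame) -> pd.DataFrame:
        trials = g["trial"].to_numpy()
        if len(np.unique(trials)) != len(trials):
            raise ValueError("duplicate trial indices in a participant x session block")
        if not np.array_equal(trials, np.arange(trials[0], trials[0] + len(trials))):
            raise ValueError("missing trial indices in a participant x session block")
        pe = circ_diff(g["outcome"].to_numpy(), g["bucket"].to_numpy())
        b = g["bucket"].to_numpy()
        upd = np.full(len(g), np.nan)
        upd[:-1] = circ_diff(b[1:], b[:-1])
        if mode == "linear":
            pe = np.abs(pe)
            upd = np.abs(upd)
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.where(pe != 0, upd / pe, np.nan)
        g = g.copy()
        g["pe"] = pe
        g["abs_pe"] = np.abs(pe)
        g["update"] = upd
        g["lr"] = lr
        g["hit_prev"] = g["hit"].shift(1)
        return g

    parts = [_per_session(g) for _, g in out.groupby(_KEY, sort=False)]
    return pd.concat(parts, ignore_index=True)


def lr_validity_mask(derived: pd.DataFrame, percentile: float = 99.0) -> pd.Series:
    """Trials usable for analyses involving the normative regressors.

    Pooled over all participants within the given table (call it per
    session), a trial is invalid if PE = 0, the learning rate is undefined
    (last trial), or the learning rate exceeds the pooled ``percentile``-th
    percentile — an upper-tail trim of extreme updates unrelated to
    error-driven learning. With fewer than 100 pooled valid learning rates
    the percentile is unstable, so only the PE = 0 / undefined rules apply.
    """
    lr = derived["lr"]
    pe = derived["pe"]
    valid = pe.ne(0) & lr.notna()
    pool = lr[valid]
    if pool.size < 100:
        warnings.warn(
            f"only {pool.size} pooled learning rates; skipping the percentile trim",
            stacklevel=2,
        )
        return valid
    cut = np.percentile(pool, percentile)
    return valid & lr.le(cut)


@dataclass
class ExclusionReport:
    """Confidence-scale quality screens for one cohort.

    ``table`` holds one row per participant x session with the computed
    statistics and flags; ``dropped`` lists (participant_id, session) pairs
    failing any dropping criterion.
    """

    table: pd.DataFrame

    @property
    def dropped(self):
        bad = self.table[self.table["drop"]]
        return list(bad[_KEY].itertuples(index=False, name=None))

    def filter(self, records: pd.DataFrame) -> pd.DataFrame:
        keep = self.table.loc[~self.table["drop"], _KEY]
        return records.merge(keep, on=_KEY)


def apply_confidence_exclusions(records: pd.DataFrame, alpha: float = 0.05) -> ExclusionReport:
    """Screen each participant x session's confidence usage.

    Four criteria, mirroring standard practice for this task:

    1. *reset flag* (informational, never drops): the slider was left at its
       anchor on more than 70% of the first 50 trials — during live data
       collection this restarted the task.
    2. *anchor-stay*: left at the anchor on more than 60% of all trials.
    3. *anchor correlation*: Pearson correlation between the trial's random
       anchor (25/75) and the logged confidence exceeds 0.5 — ratings that
       track the slider's random start rather than the task. An undefined
       correlation (constant confidence) fires this flag by convention.
    4. *inverted confidence*: mean confidence after hits significantly
       lower than after misses (one-sided Welch t at ``alpha``).

    A session is dropped iff any of criteria 2-4 fires.
    """
    rows = []
    for (pid, sess), g in records.groupby(_KEY, sort=True):
        g = g.sort_values("trial")
        conf = g["confidence"].to_numpy(dtype=float)
        anch = g["anchor"].to_numpy(dtype=float)
        at_anchor = conf == anch
        first50 = at_anchor[:50]
        default_rate = float(first50.mean()) if first50.size else 0.0
        stay_rate = float(at_anchor.mean())

        if np.std(conf) == 0 or np.std(anch) == 0:
            anchor_corr = np.nan
            corr_flag = np.std(conf) == 0  # constant confidence: anchored by convention
        else:
            anchor_corr = float(stats.pearsonr(anch, conf)[0])
            corr_flag = anchor_corr > 0.5

        hit_prev = g["hit"].shift(1).to_numpy(dtype=float)
        conf_after_hit = conf[hit_prev == 1]
        conf_after_miss = conf[hit_prev == 0]
        if conf_after_hit.size >= 2 and conf_after_miss.size >= 2:
            t, p = stats.ttest_ind(
                conf_after_hit, conf_after_miss, equal_var=False, alternative="less"
            )
            inverted = bool(p < alpha)
            inv_p = float(p)
        else:
            inverted, inv_p = False, np.nan

        rows.append(
            {
                "participant_id": pid,
                "session": sess,
                "anchor_default_rate": default_rate,
                "reset_flag": default_rate > 0.70,
                "anchor_stay_rate": stay_rate,
                "anchor_over_60pct": stay_rate > 0.60,
                "anchor_corr": anchor_corr,
                "anchor_corr_over_0.5": bool(corr_flag),
                "confidence_inversion_p": inv_p,
                "confidence_inverted": inverted,
            }
        )
    table = pd.DataFrame(rows)
    table["drop"] = (
        table["anchor_over_60pct"] | table["anchor_corr_over_0.5"] | table["confidence_inverted"]
    )
    return ExclusionReport(table)


def _cp_offset_index(is_cp: np.ndarray) -> pd.DataFrame:
    """Map trials to (cp index, offset) pairs, truncating at adjacent CPs.

    For each change-point at position c, trials c-4..c+4 contribute at their
    offset unless another CP lies between them and c — no trial is ever
    attributed to a CP across another CP. Offset 0 is the CP trial itself.
    """
    n = is_cp.size
    cps = np.flatnonzero(is_cp)
    rows = []
    for k, c in enumerate(cps):
        prev_cp = cps[k - 1] if k > 0 else -1
        next_cp = cps[k + 1] if k + 1 < cps.size else n
        for off in OFFSETS:
            t = c + off
            if t < 0 or t >= n:
                continue
            if off < 0 and t <= prev_cp:
                continue
            if off > 0 and t >= next_cp:
                continue
            rows.append((k, off, t))
    return pd.DataFrame(rows, columns=["cp_index", "offset", "pos"])


def align_to_cps(
    derived: pd.DataFrame,
    measure: str,
    stat: str = "median",
    min_cps: int = 2,
    cp_half: str | None = None,
) -> pd.DataFrame:
    """Per-participant summaries of ``measure`` at CP-relative offsets.

    For every change-point, the measure's values at offsets -4..+4
    (truncated at neighbouring CPs) are collected; ``stat`` ('median' or
    'mean'; 'mean_bounded' restricts learning rates to [0, 1] first) is
    applied across CPs separately per offset. Derived columns:

    * ``stable_avg`` — mean of the offset -2 and -1 summaries (the stable
      phase just before a change);
    * ``unstable_avg`` — mean of offsets +1 and +2 (just after);
    * ``cp_adaptation`` — the offset-0 summary minus the mean of offsets
      +1..+4, the CP-driven adaptation difference score.

    ``cp_half`` supports change-point-level split halves: 'even' keeps only
    CPs whose segment (the CP trial up to the next CP; the pre-first-CP run
    is segment 0) has an even index, 'odd' the others. Offset windows are
    still taken from the full trial sequence, so pre-CP offsets reach into
    the neighbouring segment — the split is over CPs, not trials.

    Participant x sessions with fewer than ``min_cps`` usable CPs are
    excluded with a warning. Returns a wide table, one row per
    participant x session, columns ``off_-4``..``off_+4`` plus the derived
    scores.
    """
    if stat not in ("median", "mean", "mean_bounded"):
        raise ValueError(f"unknown stat: {stat!r}")
    if cp_half not in (None, "even", "odd"):
        raise ValueError(f"cp_half must be None, 'even' or 'odd', got {cp_half!r}")
    rows = []
    skipped = []
    for (pid, sess), g in derived.groupby(_KEY, sort=True):
        g = g.sort_values("trial")
        idx = _cp_offset_index(g["is_cp"].to_numpy(dtype=bool))
        if cp_half is not None:
            # CP k sits in segment k+1; keep by segment parity
            want = 0 if cp_half == "even" else 1
            idx = idx[(idx["cp_index"] + 1) % 2 == want]
        n_cps = idx["cp_index"].nunique()
        if n_cps < min_cps:
            skipped.append((pid, sess))
            continue
        vals = g[measure].to_numpy(dtype=float)
        row = {"participant_id": pid, "session": sess, "n_cps": n_cps}
        for off in OFFSETS:
            v = vals[idx.loc[idx["offset"] == off, "pos"].to_numpy()]
            if stat == "mean_bounded":
                v = v[(v >= 0) & (v <= 1)]
            v = v[~np.isnan(v)]
            if v.size == 0:
                row[_off_col(off)] = np.nan
                continue
            row[_off_col(off)] = float(np.median(v) if stat == "median" else np.mean(v))
        row["stable_avg"] = np.nanmean([row[_off_col(-2)], row[_off_col(-1)]])
        row["unstable_avg"] = np.nanmean([row[_off_col(1)], row[_off_col(2)]])
        post = [row[_off_col(o)] for o in (1, 2, 3, 4)]
        row["cp_adaptation"] = row[_off_col(0)] - np.nanmean(post)
        rows.append(row)
    if skipped:
        warnings.warn(
            f"{len(skipped)} participant x session blocks had fewer than {min_cps} "
            f"usable change-points and were excluded from CP alignment",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def _off_col(off: int) -> str:
    return f"off_{off:+d}" if off else "off_0"


@dataclass
class GroupTest:
    """A group-level t test result."""

    name: str
    mean: float
    se: float
    t: float
    df: float
    p: float


def cp_effect_test(aligned: pd.DataFrame, measure_name: str = "lr") -> GroupTest:
    """Across-participant test of the CP-driven adaptation.

    Welch two-sample t test comparing, across participants, the offset-0
    summaries against the mean of the offset +1..+4 summaries (degrees of
    freedom by Welch-Satterthwaite). A positive effect means the measure is
    elevated at the change-point itself relative to the trials that follow.
    """
    at_cp = aligned[_off_col(0)].to_numpy(dtype=float)
    post = aligned[[_off_col(o) for o in (1, 2, 3, 4)]].to_numpy(dtype=float)
    post_avg = np.nanmean(post, axis=1)
    ok = ~(np.isnan(at_cp) | np.isnan(post_avg))
    at_cp, post_avg = at_cp[ok], post_avg[ok]
    if at_cp.size < 2:
        raise ValueError("need at least 2 participants with usable CP summaries")
    if np.var(at_cp) == 0 and np.var(post_avg) == 0:
        if at_cp.mean() != post_avg.mean():
            raise ValueError("zero variance in both groups with unequal means")
        res_t, res_df, res_p = 0.0, float(2 * at_cp.size - 2), 1.0
        diff = at_cp - post_avg
        return GroupTest(
            name=f"{measure_name}: CP vs post-CP",
            mean=float(np.mean(diff)),
            se=0.0,
            t=res_t,
            df=res_df,
            p=res_p,
        )
    res = stats.ttest_ind(at_cp, post_avg, equal_var=False)
    diff = at_cp - post_avg
    return GroupTest(
        name=f"{measure_name}: CP vs post-CP",
        mean=float(np.mean(diff)),
        se=float(np.std(diff, ddof=1) / np.sqrt(diff.size)),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )
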