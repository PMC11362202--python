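"""End-to-end pipeline stages: simulate -> derive -> normative -> fit ->
psychometrics -> report.

Each stage reads the CSV/JSON artefacts of the previous one from a working
directory, writes its own, and records provenance (seed, config hash, row
counts). The numbered scripts under ``analysis/`` and the ``predinf`` CLI
are thin wrappers over these functions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour, io, psychometrics, regression
from .learner import run_reduced_bayes
from .task import DEFAULT_POPULATION, TaskConfig, simulate_cohort

log = logging.getLogger("predinf")

_KEY = ["participant_id", "session"]

ARTEFACTS = {
    "simulate": ["config.yaml", "records.csv", "traits.csv"],
    "derive": ["derived.csv", "exclusions.json", "ledger.csv"],
    "normative": ["normative.csv"],
    "fit": ["fits.csv", "group_tests.json"],
    "psychometrics": ["psychometrics.csv", "psychometrics_summary.json"],
    "report": ["report.md"],
}
_PRODUCER = {a: stage for stage, arts in ARTEFACTS.items() for a in arts}


def _require(out_dir, name) -> Path:
    p = Path(out_dir) / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing artefact {name}; run the '{_PRODUCER[name]}' stage first"
        )
    return p


def _load_config(out_dir) -> TaskConfig:
    return io.load_config(_require(out_dir, "config.yaml"))


def stage_simulate(
    out_dir,
    config: TaskConfig | None = None,
    n_participants: int = 50,
    seed: int = 1,
    population=None,
    policy: str = "noisy_normative",
):
    """Simulate a two-session cohort and write the trial log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or TaskConfig()
    records, traits = simulate_cohort(
        n_participants, config=config, population=population or DEFAULT_POPULATION,
        seed=seed, policy=policy,
    )
    io.save_config(config, out_dir / "config.yaml")
    io.write_table(records, out_dir / "records.csv")
    io.write_table(traits, out_dir / "traits.csv")
    io.write_meta(out_dir / "simulate_meta.json", seed=seed, config=config,
                  n_rows=len(records), n_participants=n_participants, policy=policy)
    log.info("simulate: %d participants, %d rows, config %s",
             n_participants, len(records), io.config_hash(config))
    return records


def stage_derive(out_dir, lr_percentile: float = 99.0):
    """Apply confidence-quality exclusions, derive PE/update/LR series and
    the pooled learning-rate validity mask; write the exclusion ledger."""
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    records = io.read_table(_require(out_dir, "records.csv"))

    report = behaviour.apply_confidence_exclusions(records)
    kept = report.filter(records)
    derived = behaviour.derive_series(kept)
    derived["lr_valid"] = False
    for sess, g in derived.groupby("session"):
        derived.loc[g.index, "lr_valid"] = behaviour.lr_validity_mask(g, lr_percentile)

    counts = {}
    for sess in sorted(records["session"].unique()):
        entering = records.loc[records["session"] == sess, "participant_id"].nunique()
        dropped = sum(1 for (_, s) in report.dropped if s == sess)
        counts[f"S{sess}"] = {
            "entering": entering,
            "exclusions": [("confidence-quality criteria", dropped)],
        }
    ledger = io.exclusion_ledger(counts)

    io.write_table(derived, out_dir / "derived.csv")
    (out_dir / "exclusions.json").write_text(
        json.dumps(
            {
                "table": report.table.to_dict(orient="records"),
                "dropped": [list(x) for x in report.dropped],
            },
            indent=2,
            default=float,
        )
    )
    io.write_table(ledger.to_frame(), out_dir / "ledger.csv")
    io.write_meta(out_dir / "derive_meta.json", seed=None, config=config,
                  n_rows=len(derived), n_dropped=len(report.dropped))
    io.check_config_consistency(out_dir / "simulate_meta.json", out_dir / "derive_meta.json")
    log.info("derive: %d rows kept, %d participant-sessions dropped",
             len(derived), len(report.dropped))
    return derived


def stage_normative(out_dir, mode: str = "conditioned_on_participant"):
    """Run the reduced Bayesian learner per participant x session and merge
    its trial-wise CPP/RU/learning-rate columns into the derived series."""
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    derived = io.read_table(_require(out_dir, "derived.csv"))
    parts = []
    for _, g in derived.groupby(_KEY, sort=False):
        g = g.sort_values("trial")
        series = run_reduced_bayes(
            g["outcome"].to_numpy(), config, mode=mode, buckets=g["bucket"].to_numpy()
        )
        parts.append(pd.concat([g.reset_index(drop=True), series.to_frame()], axis=1))
    normative = pd.concat(parts, ignore_index=True)
    io.write_table(normative, out_dir / "normative.csv")
    io.write_meta(out_dir / "normative_meta.json", seed=None, config=config,
                  n_rows=len(normative), mode=mode)
    io.check_config_consistency(out_dir / "simulate_meta.json", out_dir / "normative_meta.json")
    log.info("normative: %d rows in %s mode", len(normative), mode)
    return normative


def _tidy_fit(pid, sess, fit):
    rows = []
    for name, est in fit.coefficients.items():
        rows.append(
            {
                "participant_id": pid,
                "session": sess,
                "model": fit.model,
                "coefficient": name,
                "estimate": est,
                "se": fit.se.get(name, np.nan),
                "converged": fit.converged,
                "n_trials_used": fit.n_trials_used,
            }
        )
    return rows


def fit_participant_models(normative: pd.DataFrame, seed: int = 0,
                           circular: bool = True) -> pd.DataFrame:
    """Fit all per-participant models on a normative-series table.

    Returns the tidy coefficient table (one row per participant x session x
    model x coefficient). The circular MAP model uses only learning-rate-
    valid trials; the linear models use all trials with defined regressors.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for (pid, sess), g in normative.groupby(_KEY, sort=True):
        g = g.sort_values("trial")
        if circular:
            valid = g[g["lr_valid"].astype(bool)]
            try:
                fit = regression.fit_circular_update_model(
                    valid, seed=rng.integers(2**31)
                )
                rows += _tidy_fit(pid, sess, fit)
            except ValueError as e:
                log.warning("circular fit skipped for %s/%s: %s", pid, sess, e)
        for variant in regression.CONFIDENCE_VARIANTS:
            try:
                fit = regression.fit_confidence_model(g, variant=variant)
                rows += _tidy_fit(pid, sess, fit)
            except ValueError as e:
                log.warning("%s fit skipped for %s/%s: %s", variant, pid, sess, e)
        try:
            fit = regression.fit_action_confidence(g)
            rows += _tidy_fit(pid, sess, fit)
        except ValueError as e:
            log.warning("action-confidence fit skipped for %s/%s: %s", pid, sess, e)
    return pd.DataFrame(rows)


def group_tests_from_tidy(fits: pd.DataFrame) -> list[dict]:
    """One-sample group test per session x model x coefficient."""
    out = []
    for (sess, model, coefficient), g in fits.groupby(["session", "model", "coefficient"]):
        vals = g.loc[g["converged"], "estimate"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2 or np.std(vals, ddof=1) == 0:
            continue
        from scipy import stats as sps

        res = sps.ttest_1samp(vals, 0.0)
        out.append(
            {
                "session": int(sess),
                "model": model,
                "coefficient": coefficient,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                "t": float(res.statistic),
                "df": int(vals.size - 1),
                "p": float(res.pvalue),
            }
        )
    return out


def stage_fit(out_dir, seed: int = 0):
    """Fit the circular update, confidence and coupling models for every
    participant x session; write tidy coefficients and group tests."""
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    normative = io.read_table(_require(out_dir, "normative.csv"))
    fits = fit_participant_models(normative, seed=seed)
    io.write_table(fits, out_dir / "fits.csv")
    tests = group_tests_from_tidy(fits)
    (out_dir / "group_tests.json").write_text(json.dumps(tests, indent=2))
    io.write_meta(out_dir / "fit_meta.json", seed=seed, config=config, n_rows=len(fits))
    io.check_config_consistency(out_dir / "simulate_meta.json", out_dir / "fit_meta.json")
    log.info("fit: %d coefficient rows", len(fits))
    return fits


# ---------------------------------------------------------------------------
# psychometrics over the pipeline's measures


def cp_measure_table(normative, measure, stat="median", cp_half=None):
    """Per-participant CP-aligned summaries for each session separately."""
    out = {}
    for sess, g in normative.groupby("session"):
        out[sess] = behaviour.align_to_cps(
            g, measure, stat=stat, cp_half=cp_half
        ).set_index("participant_id")
    return out


_PHASE_COLS = [behaviour._off_col(o) for o in behaviour.OFFSETS] + [
    "stable_avg",
    "unstable_avg",
    "cp_adaptation",
]


def cp_measure_psychometrics(normative: pd.DataFrame, measure: str,
                             stat: str = "median") -> pd.DataFrame:
    """Internal consistency and test-retest reliability of a CP-aligned
    measure at every offset and derived phase score.

    Internal consistency splits at the CP level (alternating CP segments;
    windows drawn from the full trial sequence); test-retest is the
    ICC(2,1) between the two sessions' full-data summaries.
    """
    full = cp_measure_table(normative, measure, stat=stat)
    even = cp_measure_table(normative, measure, stat=stat, cp_half="even")
    odd = cp_measure_table(normative, measure, stat=stat, cp_half="odd")
    rows = []
    for sess in sorted(full):
        for col in _PHASE_COLS:
            res = psychometrics.split_half_scores(
                even[sess][col], odd[sess][col], mode="cp_segments"
            )
            rows.append(
                {
                    "measure": measure,
                    "statistic": stat,
                    "phase": col,
                    "session": sess,
                    "estimator": "split_half_sb",
                    "estimate": res.r_sb,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "n": res.n,
                    "category": res.category,
                }
            )
    if {1, 2} <= set(full):
        for col in _PHASE_COLS:
            res = psychometrics.icc(full[1][col], full[2][col])
            rows.append(
                {
                    "measure": measure,
                    "statistic": stat,
                    "phase": col,
                    "session": 0,  # across sessions
                    "estimator": "icc21",
                    "estimate": res.icc21,
                    "ci_low": res.ci95_21[0],
                    "ci_high": res.ci95_21[1],
                    "n": res.n,
                    "category": res.category,
                }
            )
    return pd.DataFrame(rows)


def coefficient_psychometrics(normative: pd.DataFrame, fits: pd.DataFrame,
                              seed: int = 0, circular: bool = True) -> pd.DataFrame:
    """Internal consistency (odd/even-trial refits) and ICC of regression
    coefficients."""
    rows = []
    odd = normative[normative["trial"] % 2 == 1]
    even = normative[normative["trial"] % 2 == 0]
    fits_odd = fit_participant_models(odd, seed=seed + 1, circular=circular)
    fits_even = fit_participant_models(even, seed=seed + 2, circular=circular)

    def _pivot(f):
        return f[f["converged"]].set_index(_KEY + ["model", "coefficient"])["estimate"]

    po, pe_, pf = _pivot(fits_odd), _pivot(fits_even), _pivot(fits)
    for (model, coefficient), _ in fits.groupby(["model", "coefficient"]):
        if coefficient == "intercept":
            continue
        for sess in sorted(normative["session"].unique()):
            try:
                a = po.xs((sess, model, coefficient), level=(1, 2, 3))
                b = pe_.xs((sess, model, coefficient), level=(1, 2, 3))
                res = psychometrics.split_half_scores(a, b, mode="odd_even_trials")
            except (KeyError, ValueError):
                continue
            rows.append(
                {
                    "measure": f"{model}:{coefficient}",
                    "statistic": "beta",
                    "phase": "all",
                    "session": sess,
                    "estimator": "split_half_sb",
                    "estimate": res.r_sb,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "n": res.n,
                    "category": res.category,
                }
            )
        try:
            a = pf.xs((1, model, coefficient), level=(1, 2, 3))
            b = pf.xs((2, model, coefficient), level=(1, 2, 3))
            res = psychometrics.icc(a, b)
        except (KeyError, ValueError):
            continue
        rows.append(
            {
                "measure": f"{model}:{coefficient}",
                "statistic": "beta",
                "phase": "all",
                "session": 0,
                "estimator": "icc21",
                "estimate": res.icc21,
                "ci_low": res.ci95_21[0],
                "ci_high": res.ci95_21[1],
                "n": res.n,
                "category": res.category,
            }
        )
    return pd.DataFrame(rows)


def stage_psychometrics(out_dir, seed: int = 0, coefficients: bool = True):
    """Reliability of the CP-aligned raw measures and (optionally) of the
    per-participant regression coefficients."""
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    normative = io.read_table(_require(out_dir, "normative.csv"))
    tables = [
        cp_measure_psychometrics(normative, "lr", stat="median"),
        cp_measure_psychometrics(normative, "confidence", stat="median"),
    ]
    if coefficients:
        fits = io.read_table(_require(out_dir, "fits.csv"))
        tables.append(coefficient_psychometrics(normative, fits, seed=seed))
    table = pd.concat(tables, ignore_index=True)
    io.write_table(table, out_dir / "psychometrics.csv")
    summary = {
        "n_measures": int(table["measure"].nunique()),
        "categories": table.groupby("estimator")["category"]
        .value_counts()
        .unstack(fill_value=0)
        .to_dict(),
    }
    (out_dir / "psychometrics_summary.json").write_text(
        json.dumps(summary, indent=2, default=int)
    )
    io.write_meta(out_dir / "psychometrics_meta.json", seed=seed, config=config,
                  n_rows=len(table))
    io.check_config_consistency(out_dir / "simulate_meta.json",
                                out_dir / "psychometrics_meta.json")
    log.info("psychometrics: %d estimates", len(table))
    return table


def stage_report(out_dir):
    """Render a plain-text summary of the pipeline's main tables."""
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    psych = io.read_table(_require(out_dir, "psychometrics.csv"))
    ledger = io.read_table(_require(out_dir, "ledger.csv"))
    tests = json.loads(_require(out_dir, "group_tests.json").read_text())
    aligned_lr = psych[(psych["measure"] == "lr") & (psych["estimator"] == "split_half_sb")]
    aligned_conf = psych[
        (psych["measure"] == "confidence") & (psych["estimator"] == "split_half_sb")
    ]
    icc_rows = psych[psych["estimator"] == "icc21"]

    lines = [
        "# Pipeline report",
        "",
        f"Config hash: {io.config_hash(config)}",
        "",
        "## Exclusion ledger",
        ledger.to_string(index=False),
        "",
        "## Internal consistency of CP-aligned median learning rate",
        aligned_lr.to_string(index=False),
        "",
        "## Internal consistency of CP-aligned median confidence",
        aligned_conf.to_string(index=False),
        "",
        "## Test-retest reliability (ICC(2,1))",
        icc_rows.to_string(index=False),
        "",
        "## Group-level regression tests",
        pd.DataFrame(tests).to_string(index=False),
        "",
    ]
    text = "\n".join(lines)
    (out_dir / "report.md").write_text(text)
    log.info("report: written to %s", out_dir / "report.md")
    return text


def run_all(out_dir, config=None, n_participants=50, seed=1, population=None,
            mode="conditioned_on_participant", coefficients: bool = True):
    """Run every stage in order."""
    stage_simulate(out_dir, config=config, n_participants=n_participants,
                   seed=seed, population=population)
    stage_derive(out_dir)
    stage_normative(out_dir, mode=mode)
    stage_fit(out_dir, seed=seed)
    stage_psychometrics(out_dir, seed=seed, coefficients=coefficients)
    return stage_report(out_dir)
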