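import pandas as pd
import pytest

from predinf import behaviour
from predinf.learner import run_reduced_bayes
from predinf.task import TaskConfig, simulate_cohort


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def cohort():
    """A small two-session noisy-normative cohort with known traits."""
    records, traits = simulate_cohort(20, seed=11)
    return records, traits


@pytest.fixture(scope="session")
def derived(cohort):
    records, _ = cohort
    d = behaviour.derive_series(records)
    d["lr_valid"] = False
    for _, g in d.groupby("session"):
        d.loc[g.index, "lr_valid"] = behaviour.lr_validity_mask(g)
    return d


def attach_normative(derived, config, mode="conditioned_on_participant"):
    """Merge the learner's trial-wise columns into a derived table."""
    parts = []
    for _, g in derived.groupby(["participant_id", "session"], sort=False):
        g = g.sort_values("trial")
        ns = run_reduced_bayes(
            g["outcome"].to_numpy(), config, mode=mode, buckets=g["bucket"].to_numpy()
        )
        parts.append(pd.concat([g.reset_index(drop=True), ns.to_frame()], axis=1))
    return pd.concat(parts, ignore_index=True)


@pytest.fixture(scope="session")
def normative(derived, config):
    return attach_normative(derived, config)
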