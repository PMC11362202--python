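"""File formats, run configuration, and the participant-exclusion ledger.

All tabular artefacts are UTF-8 CSV with a header, '.' decimal separator
and no index column; nested results are JSON; configuration is YAML or
JSON. Angles are stored in degrees everywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .task import TaskConfig

__all__ = [
    "load_config",
    "save_config",
    "config_hash",
    "write_table",
    "read_table",
    "write_meta",
    "read_meta",
    "check_config_consistency",
    "ExclusionLedger",
    "exclusion_ledger",
]


def load_config(path) -> TaskConfig:
    """Read a TaskConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    known = {f.name for f in dataclasses.fields(TaskConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "confidence_anchors" in data:
        data["confidence_anchors"] = tuple(data["confidence_anchors"])
    return TaskConfig(**data)


def save_config(config: TaskConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["confidence_anchors"] = list(data["confidence_anchors"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(config: TaskConfig) -> str:
    """Stable short hash identifying a task configuration."""
    data = dataclasses.asdict(config)
    data["confidence_anchors"] = list(data["confidence_anchors"])
    blob = json.dumps(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_meta(path, *, seed, config: TaskConfig, n_rows: int, **extra) -> None:
    """Record provenance next to an artefact: seed, config hash, row count."""
    meta = {"seed": seed, "config_hash": config_hash(config), "n_rows": int(n_rows)}
    meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, default=float))


def read_meta(path) -> dict:
    return json.loads(Path(path).read_text())


def check_config_consistency(*meta_paths) -> str:
    """Refuse to combine artefacts produced under different configs."""
    hashes = {}
    for p in meta_paths:
        hashes[str(p)] = read_meta(p)["config_hash"]
    if len(set(hashes.values())) > 1:
        raise ValueError(f"mixed-config artefacts: {hashes}")
    return next(iter(hashes.values()))


@dataclass
class LedgerStage:
    name: str
    entering: int
    excluded: int

    @property
    def remaining(self) -> int:
        return self.entering - self.excluded


@dataclass
class ExclusionLedger:
    """Chained exclusion accounting across sessions.

    ``stages`` maps a session label to its ordered stage list; within a
    session each stage's remaining count is the next stage's entering
    count. ``retention`` is the percentage of the first session's final
    sample that came back to start the second session.
    """

    stages: dict

    def __post_init__(self):
        for label, chain in self.stages.items():
            for st in chain:
                if st.entering < 0 or st.excluded < 0 or st.remaining < 0:
                    raise ValueError(
                        f"inconsistent counts at {label}/{st.name}: "
                        f"{st.entering} entering, {st.excluded} excluded"
                    )
            for a, b in zip(chain, chain[1:]):
                if a.remaining != b.entering:
                    raise ValueError(
                        f"broken chain at {label}: {a.name} leaves {a.remaining} "
                        f"but {b.name} enters {b.entering}"
                    )

    def final(self, label) -> int:
        return self.stages[label][-1].remaining

    @property
    def retention(self) -> int:
        labels = list(self.stages)
        if len(labels) < 2:
            raise ValueError("retention needs two sessions")
        t1_final = self.final(labels[0])
        t2_enter = self.stages[labels[1]][0].entering
        return round(100.0 * t2_enter / t1_final)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "session": label,
                "stage": st.name,
                "entering": st.entering,
                "excluded": st.excluded,
                "remaining": st.remaining,
            }
            for label, chain in self.stages.items()
            for st in chain
        ]
        return pd.DataFrame(rows)

    def render(self) -> str:
        return self.to_frame().to_string(index=False)


def exclusion_ledger(counts: dict) -> ExclusionLedger:
    """Build a ledger from per-session stage counts.

    ``counts`` maps session label -> {"entering": int,
    "exclusions": [(stage name, n excluded), ...]}; stages chain within a
    session.

    >>> led = exclusion_ledger({
    ...     "T1": {"entering": 401,
    ...            "exclusions": [("attention checks", 19), ("task criteria", 52)]},
    ...     "T2": {"entering": 260,
    ...            "exclusions": [("attention checks", 14), ("task criteria", 27)]},
    ... })
    >>> led.final("T1"), led.final("T2"), led.retention
    (330, 219, 79)
    """
    stages = {}
    for label, spec in counts.items():
        entering = spec["entering"]
        chain = []
        for name, excl in spec["exclusions"]:
            chain.append(LedgerStage(name, entering, excl))
            entering -= excl
        if not chain:
            chain.append(LedgerStage("all", entering, 0))
        stages[label] = chain
    return ExclusionLedger(stages)
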