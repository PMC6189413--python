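"""Trial-log CSV dialect, run configuration, and result serialization.

The trial log is UTF-8 CSV with header::

    pair_id,agent_id,condition,design,block,trial_index,stimulus_side,
    stimulus_color,required_responder,response_side,rt_ms,accuracy

one row per trial per perspective agent, 1-based block/trial indices, missing
RT as an empty field.  Round-trips are lossless and unknown extra columns are
preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coordination import CorrConfig
from .simulate import CONDITIONS, Session, SimConfig

DIALECT_COLUMNS = [
    "pair_id",
    "agent_id",
    "condition",
    "design",
    "block",
    "trial_index",
    "stimulus_side",
    "stimulus_color",
    "required_responder",
    "response_side",
    "rt_ms",
    "accuracy",
]

_ENUMS = {
    "condition": set(CONDITIONS),
    "stimulus_side": {"left", "right"},
    "response_side": {"left", "right", "none"},
    "accuracy": {"correct", "error", "miss"},
}


class TrialLogError(ValueError):
    """Raised for malformed or invariant-violating trial logs."""


@dataclass
class RunConfig:
    """Analysis + simulation parameters with paper-anchored defaults."""

    sim: SimConfig = field(default_factory=SimConfig)
    corr: CorrConfig = field(default_factory=CorrConfig)
    n_bins: int = 4
    tukey_k: float = 1.5
    n_pairs: int = 10
    design: str = "cooperative"
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        corr_fields = {f.name for f in dataclasses.fields(CorrConfig)}
        top_fields = {f.name for f in dataclasses.fields(cls)} - {"sim", "corr"}
        sim_kw = {k: v for k, v in raw.items() if k in sim_fields}
        corr_kw = {k: v for k, v in raw.items() if k in corr_fields}
        top_kw = {k: v for k, v in raw.items() if k in top_fields}
        unknown = set(raw) - sim_fields - corr_fields - top_fields
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "seed" in top_kw:
            sim_kw.setdefault("seed", top_kw["seed"])
        return cls(sim=SimConfig(**sim_kw), corr=CorrConfig(**corr_kw), **top_kw)


def load_config(path: str | Path) -> RunConfig:
    """Read a flat YAML key-value file mirroring the config field names."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_mapping(raw or {})


def write_trial_log(frame_or_sessions, path: str | Path) -> None:
    """Write sessions (or a concatenated frame) in the trial-log dialect."""
    if isinstance(frame_or_sessions, pd.DataFrame):
        frame = frame_or_sessions
    else:
        frame = pd.concat(
            [s.trials for s in frame_or_sessions], ignore_index=True
        )
    cols = DIALECT_COLUMNS + [c for c in frame.columns if c not in DIALECT_COLUMNS]
    frame.to_csv(path, index=False, columns=cols)


def read_trial_log(path: str | Path) -> list[Session]:
    """Read and validate a trial log, grouped into per-agent sessions.

    Structural violations (bad enum values, RT present on miss / no-go rows,
    RT absent on responded rows, non-increasing trial indices) are reported
    with 1-based data row numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"pair_id": str, "agent_id": str})
    if frame.empty:
        raise TrialLogError(f"{path}: empty trial log")
    missing = [c for c in DIALECT_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialLogError(f"{path}: missing columns {missing}")

    problems: list[str] = []
    rownum = frame.index.to_numpy() + 1
    for col, allowed in _ENUMS.items():
        bad = ~frame[col].isin(allowed)
        for r in rownum[bad.to_numpy()][:10]:
            problems.append(f"row {r}: invalid {col} {frame.at[r - 1, col]!r}")
    has_rt = frame["rt_ms"].notna()
    responded = frame["response_side"] != "none"
    for r in rownum[(has_rt & ~responded).to_numpy()][:10]:
        problems.append(f"row {r}: rt_ms present without a response")
    for r in rownum[(~has_rt & responded).to_numpy()][:10]:
        problems.append(f"row {r}: response recorded but rt_ms missing")
    miss_with_resp = (frame["accuracy"] == "miss") & responded
    for r in rownum[miss_with_resp.to_numpy()][:10]:
        problems.append(f"row {r}: miss row has a response")
    if problems:
        raise TrialLogError(f"{path}: malformed rows:\n  " + "\n  ".join(problems))

    sessions = []
    for (pair_id, condition, agent_id), grp in frame.groupby(
        ["pair_id", "condition", "agent_id"], sort=True
    ):
        idx = grp["trial_index"].to_numpy()
        if not np.all(np.diff(idx) > 0):
            raise TrialLogError(
                f"{path}: non-increasing trial_index in session "
                f"({pair_id}, {condition}, {agent_id})"
            )
        design = str(grp["design"].iloc[0])
        sessions.append(
            Session(
                pair_id=str(pair_id),
                agent_id=str(agent_id),
                condition=str(condition),
                trials=grp.reset_index(drop=True),
                design=design,
            )
        )
    return sessions
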