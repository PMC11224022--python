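"""Readers/writers and configuration for the CSV/JSON interchange format.

Trial tables travel as flat CSV with the canonical columns
(session_id, start, target, v_a, v_p, t_go, t_on, t_off, n_attempts,
rewarded); spike times as a long CSV (neuron_id, group, spike_time).
Configuration round-trips through YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import TRIAL_COLUMNS, NeuronSession

__all__ = ["RunConfig", "read_trials", "write_trials", "read_spikes",
           "write_spikes", "load_session", "save_session"]


@dataclass
class RunConfig:
    """Task constants, generator sizes and analysis knobs for a pipeline run."""

    n_landmarks: int = 6
    t_o: float = 0.65
    reward_rule: str = "relative_fixed_0.08"
    kernel_sd: float = 0.1
    acg_bin: float = 0.001
    warp_bin: float = 0.04
    n_trials: int = 200
    n_neurons: int = 20
    n_null: int = 200
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing column(s): {', '.join(missing)}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing column(s): {', '.join(missing)}")
    df["rewarded"] = df["rewarded"].astype(bool)
    return df


def write_spikes(sessions: list[NeuronSession], path) -> None:
    rows = []
    for s in sessions:
        rows.append(pd.DataFrame({
            "neuron_id": s.neuron_id, "group": s.group,
            "spike_time": s.spike_times,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_spikes(path, trials: pd.DataFrame, iti_segments=None) -> list[NeuronSession]:
    df = pd.read_csv(path)
    out = []
    for (nid, grp), sub in df.groupby(["neuron_id", "group"], sort=True):
        out.append(NeuronSession(str(nid), sub["spike_time"].to_numpy(float),
                                 trials, group=str(grp),
                                 iti_segments=list(iti_segments or [])))
    return out


def save_session(trials: pd.DataFrame, sessions: list[NeuronSession], directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_trials(trials, d / "trials.csv")
    write_spikes(sessions, d / "spikes.csv")
    itis = sessions[0].iti_segments if sessions else []
    with open(d / "iti_segments.json", "w") as fh:
        json.dump([[float(a), float(b)] for a, b in itis], fh)


def load_session(directory) -> tuple[pd.DataFrame, list[NeuronSession]]:
    """Load a session saved by :func:`save_session` (CSV interchange)."""
    d = Path(directory)
    trials = read_trials(d / "trials.csv")
    itis = []
    p = d / "iti_segments.json"
    if p.exists():
        with open(p) as fh:
            itis = [tuple(x) for x in json.load(fh)]
    sessions = read_spikes(d / "spikes.csv", trials, itis)
    return trials, sessions
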