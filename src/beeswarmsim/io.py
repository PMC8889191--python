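"""Flat-file I/O: stimulus sets, trajectories, trial logs, cohort tables.

All tables are comma-separated UTF-8 with a header row; stochastic outputs
carry their seed either in a JSON sidecar/manifest or in a ``# key=value``
comment line at the top of the CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .scoring import BlockSummary
from .stimulus import (
    EvidenceRule,
    EvidenceTrajectory,
    Trial,
    TrialSpec,
    latency_to_array_index,
    optimal_array_index,
)

__all__ = [
    "write_stimulus_set",
    "read_stimulus_set",
    "write_trajectories",
    "write_cohort",
    "read_cohort",
    "read_trial_log",
    "write_block_summaries",
    "load_config",
    "write_manifest",
]


def write_stimulus_set(trials: Sequence[Trial], out_dir: str | Path, seed=None) -> Path:
    """Write trials as long CSV plus a JSON sidecar with the generative spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in trials:
        for group, values in (("pink", t.pink), ("blue", t.blue)):
            for pos, v in enumerate(values, start=1):
                rows.append(
                    {
                        "trial_id": t.trial_id,
                        "truth": "true" if t.truth else "null",
                        "group": group,
                        "position": pos,
                        "value": v,
                    }
                )
    pd.DataFrame(rows).to_csv(out_dir / "stimuli.csv", index=False)
    spec = trials[0].spec
    sidecar = {
        "delta": spec.delta,
        "array_sizes": list(spec.array_sizes),
        "n_trials": len(trials),
        "seed": seed,
    }
    (out_dir / "stimuli.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir / "stimuli.csv"


def read_stimulus_set(out_dir: str | Path) -> list[Trial]:
    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / "stimuli.json").read_text())
    # keep the truth labels as raw strings ("null" is a valid label, not NaN)
    df = pd.read_csv(
        out_dir / "stimuli.csv", dtype={"truth": str}, keep_default_na=False, na_values=[]
    )
    trials = []
    for tid, grp in df.groupby("trial_id", sort=True):
        truth = grp["truth"].iloc[0] == "true"
        pink = grp[grp["group"] == "pink"].sort_values("position")["value"].to_numpy()
        blue = grp[grp["group"] == "blue"].sort_values("position")["value"].to_numpy()
        spec = TrialSpec(
            delta=sidecar["delta"] if truth else 0.0,
            array_sizes=tuple(sidecar["array_sizes"]),
        )
        trials.append(Trial(spec=spec, pink=pink, blue=blue, truth=truth, trial_id=int(tid)))
    return trials


def write_trajectories(
    trials: Sequence[Trial], path: str | Path, rule: EvidenceRule | None = None
) -> Path:
    """Evidence-trajectory CSV: one row per trial x array index."""
    rule = rule or EvidenceRule()
    rows = []
    for t in trials:
        traj = EvidenceTrajectory.from_trial(t, rule)
        opt = optimal_array_index(traj, rule)
        for k in range(len(traj)):
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "array_index": k + 1,
                    "n": int(traj.n[k]),
                    "observed_d": traj.observed_d[k],
                    "llr": traj.llr[k],
                    "optimal_index": opt,
                }
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_cohort(df: pd.DataFrame, path: str | Path, seed=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read a trial log (participant_id, block, trial_id, truth, choice and
    latency_s or array_index); latencies are converted to array indices."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    required = {"participant_id", "block", "trial_id", "truth", "choice"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial log lacks columns: {sorted(missing)}")
    if "array_index" not in df.columns:
        if "latency_s" not in df.columns:
            raise ValueError("trial log needs either array_index or latency_s")
        df["array_index"] = [latency_to_array_index(x) for x in df["latency_s"]]
    return df


def write_block_summaries(summaries: Sequence[BlockSummary], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(s) for s in summaries]).to_csv(path, index=False)
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    # fall back: YAML parses JSON too
    return yaml.safe_load(text)


def write_manifest(out_dir: str | Path, **fields) -> Path:
    """Record seed, package version and parameters of a run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"package": "beeswarmsim", "version": __version__, **fields}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
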