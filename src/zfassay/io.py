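"""Dataset directory persistence.

A dataset directory holds one CSV per fish (``traces/<fish>.csv`` with
time_s,intensity and/or ``trajectories/<fish>.csv`` with
time_s,x_mm,y_mm), a ``ground_truth.csv`` (fish_id, group, true
baselines, event times) and a ``manifest.json`` describing groups,
treatments, seed and sampling.  Everything is plain text so runs diff
cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import Trajectory
from .signals import IntensityTrace
from .synthetic import (
    AssayDataset,
    CohortDesign,
    DRUG_MODELS,
    FishParams,
    FishRecord,
    GroupSpec,
    TreatmentSpec,
)

__all__ = ["load_dataset", "save_dataset"]


def save_dataset(dataset: AssayDataset, path) -> None:
    dataset.to_dir(path)


def load_dataset(path, kind: str = "respiratory") -> AssayDataset:
    """Load a dataset directory written by :meth:`AssayDataset.to_dir`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    truth = pd.read_csv(path / "ground_truth.csv").set_index("fish_id")
    groups = []
    treatments = {}
    for g in manifest["groups"]:
        spec = TreatmentSpec(**g["treatment"])
        treatments[g["label"]] = spec
        groups.append(GroupSpec(label=g["label"], treatment=spec, n=g["n"]))
    design = CohortDesign(
        groups=tuple(groups),
        duration=manifest["duration_s"],
        sample_rate=manifest["sample_rate_hz"],
        seed=manifest.get("seed", 0),
        assay=manifest.get("assay", kind),
    )
    records = []
    for fish_id, row in truth.iterrows():
        group = row["group"]
        rec = FishRecord(
            fish_id=str(fish_id),
            group=group,
            treatment=treatments[group],
            params=FishParams(),
            true_baseline_rate=float(row.get("true_baseline_rate", np.nan)),
            true_baseline_speed=float(row.get("true_baseline_speed", np.nan)),
        )
        trace_path = path / "traces" / f"{fish_id}.csv"
        if trace_path.exists():
            rec.trace = IntensityTrace.from_csv(trace_path)
        traj_path = path / "trajectories" / f"{fish_id}.csv"
        if traj_path.exists():
            rec.trajectory = Trajectory.from_csv(traj_path)
        ev = row.get("event_times", "")
        if isinstance(ev, str) and ev.strip():
            rec.event_times = np.array([float(x) for x in ev.split()])
        records.append(rec)
    return AssayDataset(design=design, records=records, models=dict(DRUG_MODELS))
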