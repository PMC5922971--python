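"""Reading and writing trial traces and generated datasets.

Each trial is one CSV (columns ``time_ms, force_N, orientation_deg``) plus
a JSON sidecar with the metadata; a dataset directory holds a manifest
listing its trials and, for synthetic data, a ground-truth CSV.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_trials import GroundTruth
from .trial_pipeline import TrialMeta, TrialRecord

__all__ = [
    "save_trial",
    "load_trial",
    "save_dataset",
    "load_dataset",
    "ground_truth_frame",
]


def _meta_dict(meta: TrialMeta) -> dict:
    return {
        "go_time_ms": meta.go_time_ms,
        "shutter_open_ms": meta.shutter_open_ms,
        "initial_orientation": meta.initial_orientation,
        "edge_length": "inf" if math.isinf(meta.edge_length) else meta.edge_length,
        "participant": meta.participant,
        "trial": meta.trial,
    }


def _meta_from_dict(d: dict) -> TrialMeta:
    length = d["edge_length"]
    return TrialMeta(
        go_time_ms=float(d["go_time_ms"]),
        shutter_open_ms=float(d["shutter_open_ms"]),
        initial_orientation=float(d["initial_orientation"]),
        edge_length=math.inf if length == "inf" else float(length),
        participant=int(d["participant"]),
        trial=int(d["trial"]),
    )


def save_trial(trial: TrialRecord, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "time_ms": trial.time_ms,
            "force_N": trial.force,
            "orientation_deg": trial.orientation,
        }
    ).to_csv(csv_path, index=False, float_format="%.6f")
    csv_path.with_suffix(".json").write_text(json.dumps(_meta_dict(trial.meta)))


def load_trial(csv_path: str | Path) -> TrialRecord:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = _meta_from_dict(json.loads(csv_path.with_suffix(".json").read_text()))
    return TrialRecord(
        time_ms=df["time_ms"].to_numpy(float),
        force=df["force_N"].to_numpy(float),
        orientation=df["orientation_deg"].to_numpy(float),
        meta=meta,
    )


def ground_truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "touch_ms": [t.touch_ms for t in truths],
            "onset_ms": [t.onset_ms for t in truths],
            "end_ms": [t.end_ms for t in truths],
            "n_submovements": [t.n_submovements for t in truths],
            "final_orientation": [t.final_orientation for t in truths],
            "plateau_force": [t.plateau_force for t in truths],
            "direction_correct": [t.direction_correct for t in truths],
            "shutter_open_ms": [t.shutter_open_ms for t in truths],
        }
    )


def save_dataset(
    pairs: list[tuple[TrialRecord, GroundTruth]], out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for rec, _ in pairs:
        name = f"p{rec.meta.participant:02d}_t{rec.meta.trial:04d}"
        save_trial(rec, out_dir / f"{name}.csv")
        names.append(name)
    ground_truth_frame([t for _, t in pairs]).to_csv(
        out_dir / "ground_truth.csv", index=False
    )
    (out_dir / "manifest.json").write_text(json.dumps({"trials": names}))


def load_dataset(in_dir: str | Path) -> list[TrialRecord]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    return [load_trial(in_dir / f"{name}.csv") for name in manifest["trials"]]
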