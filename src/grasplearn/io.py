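"""CSV/JSON serialization for trials, trajectories, datasets and studies.

Sensor trials and object trajectories are written as one-row-per-sample
CSV files with a JSON sidecar for metadata; a study becomes a directory
tree ``subject/session/block/trial.csv`` plus a manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import LabeledDataset
from .synth import (Block, FeedbackMode, GraspTrial, Grip, ObjectTrajectory,
                    Protocol, StudyDataset, TrainingCorpus)

__all__ = [
    "save_trial",
    "load_trial",
    "save_corpus",
    "load_corpus",
    "save_trajectory",
    "load_trajectory",
    "save_dataset",
    "load_dataset",
    "save_study",
    "save_report",
]

_FORCE_COLS = [f"f{i}" for i in range(1, 6)]
_FLEX_COLS = [f"x{i}" for i in range(1, 6)]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_trial(trial: GraspTrial, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(trial.volts, columns=_FORCE_COLS + _FLEX_COLS)
    df.insert(0, "t", trial.t)
    df.to_csv(path, index=False)
    meta = {"grip": trial.grip.value, "protocol": trial.protocol.value,
            "hold_window": list(trial.hold_window)
            if trial.hold_window else None,
            "seed": trial.seed, "v_max": trial.v_max}
    _sidecar(path).write_text(json.dumps(meta))


def load_trial(path: str | Path) -> GraspTrial:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    hw = meta["hold_window"]
    return GraspTrial(
        grip=Grip(meta["grip"]), protocol=Protocol(meta["protocol"]),
        t=df["t"].to_numpy(),
        volts=df[_FORCE_COLS + _FLEX_COLS].to_numpy(),
        hold_window=tuple(hw) if hw else None,
        seed=int(meta["seed"]), v_max=float(meta["v_max"]))


def save_corpus(corpus: TrainingCorpus, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, tr in enumerate(corpus.trials):
        name = f"trial_{i:03d}.csv"
        save_trial(tr, out / name)
        names.append(name)
    (out / "manifest.json").write_text(json.dumps(
        {"subject_id": corpus.subject_id, "trials": names}))


def load_corpus(in_dir: str | Path) -> TrainingCorpus:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    trials = [load_trial(in_dir / name) for name in manifest["trials"]]
    return TrainingCorpus(subject_id=manifest["subject_id"], trials=trials)


def save_trajectory(traj: ObjectTrajectory, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(traj.positions, columns=["X", "Y", "Z"])
    df.insert(0, "t", traj.timestamps)
    df.to_csv(path, index=False)
    meta = {"target_center": traj.target_center.tolist(),
            "table_point": traj.table_point.tolist(),
            "table_normal": traj.table_normal.tolist(),
            "trial_index": traj.trial_index, "block": traj.block.value,
            "feedback_mode": traj.feedback_mode.value,
            "configured": traj.configured}
    _sidecar(path).write_text(json.dumps(meta))


def load_trajectory(path: str | Path) -> ObjectTrajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return ObjectTrajectory(
        timestamps=df["t"].to_numpy(),
        positions=df[["X", "Y", "Z"]].to_numpy(),
        target_center=np.array(meta["target_center"]),
        table_point=np.array(meta["table_point"]),
        table_normal=np.array(meta["table_normal"]),
        trial_index=int(meta["trial_index"]),
        block=Block(meta["block"]),
        feedback_mode=FeedbackMode(meta["feedback_mode"]),
        configured=meta["configured"])


def save_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(dataset.features,
                      columns=_FORCE_COLS + _FLEX_COLS)
    df["label"] = dataset.labels
    df["split"] = dataset.split
    df["trial_id"] = dataset.trial_id
    df["frame_idx"] = dataset.frame_idx
    df["grip"] = dataset.grip
    df["protocol"] = dataset.protocol
    df.to_csv(path, index=False)
    meta = {"tol": dataset.tol, "activity_floor": dataset.activity_floor,
            "seed": dataset.seed, "class_counts": dataset.class_counts}
    _sidecar(path).write_text(json.dumps(meta))


def load_dataset(path: str | Path) -> LabeledDataset:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return LabeledDataset(
        features=df[_FORCE_COLS + _FLEX_COLS].to_numpy(),
        labels=df["label"].to_numpy(np.uint8),
        split=df["split"].to_numpy(str),
        trial_id=df["trial_id"].to_numpy(int),
        frame_idx=df["frame_idx"].to_numpy(int),
        grip=df["grip"].to_numpy(str),
        protocol=df["protocol"].to_numpy(str),
        tol=float(meta["tol"]),
        activity_floor=float(meta["activity_floor"]),
        seed=int(meta["seed"]))


def save_study(study: StudyDataset, out_dir: str | Path) -> None:
    """Directory tree subject/session/block plus per-trial metrics table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for sess in study.sessions:
        for tr in sess.trials:
            rel = None
            if tr.trajectory is not None:
                d = (out / tr.subject_id / sess.feedback_mode.value
                     / tr.block.value)
                d.mkdir(parents=True, exist_ok=True)
                rel = str((d / f"trial_{tr.trial_index:02d}.csv")
                          .relative_to(out))
                save_trajectory(tr.trajectory, out / rel)
            entries.append({"subject": tr.subject_id,
                            "mode": sess.feedback_mode.value,
                            "block": tr.block.value,
                            "trial": tr.trial_index,
                            "metrics": tr.metrics, "file": rel})
    (out / "manifest.json").write_text(json.dumps(
        {"seed": study.seed, "n_subjects": len(study.subject_ids),
         "trials": entries}))
    study.to_frame().to_csv(out / "metrics.csv", index=False)


def save_report(report, out_dir: str | Path) -> None:
    """Write every table of a StatsReport as CSV plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("outcomes", "block_anova", "block_pairwise",
                 "outcome_anova", "outcome_tukey", "one_sample"):
        getattr(report, name).to_csv(out / f"{name}.csv", index=False)
    (out / "summary.json").write_text(json.dumps(
        {"group_pre_mean": report.group_pre_mean,
         "normalized": report.normalized}))
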