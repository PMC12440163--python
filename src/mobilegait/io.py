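"""Plain-text persistence for pose sequences and dataset manifests.

One CSV per video in long form (video_id, frame_index, time_s, landmark_name,
x, y, z, visible) plus a manifest CSV (video_id, subject_id, view, direction,
label, fps, n_frames[, stage]).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PoseSequence
from .simulate import GaitDataset
from .skeleton import LANDMARK_NAMES, N_LANDMARKS

POSE_COLUMNS = ["video_id", "frame_index", "time_s", "landmark_name",
                "x", "y", "z", "visible"]


def pose_to_frame(seq: PoseSequence) -> pd.DataFrame:
    """Long-form table of one pose sequence (missing landmarks get NaN, visible=0)."""
    T = seq.n_frames
    frame_idx = np.repeat(np.arange(T), N_LANDMARKS)
    values = seq.values.reshape(T * N_LANDMARKS, 3)
    return pd.DataFrame({
        "video_id": seq.video_id,
        "frame_index": frame_idx,
        "time_s": frame_idx / seq.fps,
        "landmark_name": np.tile(np.asarray(LANDMARK_NAMES), T),
        "x": values[:, 0],
        "y": values[:, 1],
        "z": values[:, 2],
        "visible": (~seq.missing.reshape(-1)).astype(int),
    })


def write_pose_csv(seq: PoseSequence, path: str | Path) -> Path:
    path = Path(path)
    pose_to_frame(seq).to_csv(path, index=False, float_format="%.6f")
    return path


def read_pose_csv(path: str | Path, *, fps: float, subject_id: str, view: str,
                  direction: str, label: str) -> PoseSequence:
    """Read one long-form pose CSV back into a PoseSequence."""
    df = pd.read_csv(path)
    missing_cols = set(POSE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"pose file {path} lacks columns {sorted(missing_cols)}")
    T = int(df["frame_index"].max()) + 1
    values = np.full((T, N_LANDMARKS, 3), np.nan)
    lm_idx = df["landmark_name"].map(
        {n: i for i, n in enumerate(LANDMARK_NAMES)}).to_numpy()
    fi = df["frame_index"].to_numpy()
    values[fi, lm_idx, 0] = df["x"].to_numpy()
    values[fi, lm_idx, 1] = df["y"].to_numpy()
    values[fi, lm_idx, 2] = df["z"].to_numpy()
    visible = np.zeros((T, N_LANDMARKS), dtype=bool)
    visible[fi, lm_idx] = df["visible"].to_numpy().astype(bool)
    vid = str(df["video_id"].iloc[0])
    return PoseSequence(values=values, fps=fps, video_id=vid,
                        subject_id=subject_id, view=view, direction=direction,
                        label=label, missing=~visible)


def save_dataset(dataset: GaitDataset, out_dir: str | Path, *,
                 overwrite: bool = False, stage: str = "raw") -> Path:
    """Write a dataset as one pose CSV per video plus ``manifest.csv``.

    Refuses to touch an existing non-empty directory unless ``overwrite``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} exists and is not empty; pass overwrite=True to replace")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest.copy()
    manifest["stage"] = stage
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    for vid, seq in sorted(dataset.sequences.items()):
        write_pose_csv(seq, out_dir / f"{vid}.csv")
    return out_dir


def load_dataset(in_dir: str | Path) -> GaitDataset:
    """Read a dataset directory written by :func:`save_dataset`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    sequences = {}
    for row in manifest.itertuples():
        sequences[row.video_id] = read_pose_csv(
            in_dir / f"{row.video_id}.csv", fps=row.fps,
            subject_id=row.subject_id, view=row.view,
            direction=row.direction, label=row.label)
    return GaitDataset(manifest=manifest, sequences=sequences)
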