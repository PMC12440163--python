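"""Pose cleaning, normalization and windowing.

Fixed stage order: drop empty frames -> interpolate missing landmarks ->
downsample to 30 fps -> hip-centre with a 2-second rolling median ->
(frontal only) rescale to a common stature -> cut 30-frame windows with 50%
overlap. No stage reads the gait label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AnalysisWindow, PoseSequence
from .skeleton import LANDMARK_INDEX as LM
from .skeleton import LANDMARK_NAMES

TARGET_FPS = 30.0
WINDOW_FRAMES = 30
WINDOW_STEP = 15
#: 2-second median window at 30 fps, centred: frames [t-30, t+30]
MEDIAN_HALF_WINDOW = 30
#: common stature (px) that frontal poses are rescaled to; roughly the pixel
#: height of a subject at the sagittal camera's distance, so both views live
#: on comparable scales.
REFERENCE_HEIGHT = 170.0


def drop_empty_frames(seq: PoseSequence) -> PoseSequence:
    """Remove frames in which no landmark was observed, keeping frame order."""
    keep = ~seq.missing.all(axis=1)
    if not keep.any():
        raise ValueError(f"{seq.video_id}: no usable frames (all landmarks missing)")
    if keep.all():
        return seq
    return seq.with_values(seq.values[keep], missing=seq.missing[keep])


def interpolate_missing(seq: PoseSequence) -> PoseSequence:
    """Fill missing landmark observations by linear interpolation over time.

    Interior gaps are interpolated between the nearest observed frames;
    leading/trailing gaps take the nearest observed value. A landmark that is
    never observed cannot be reconstructed and raises an error naming it.
    """
    values = seq.values.copy()
    t = np.arange(seq.n_frames, dtype=float)
    for lm in range(values.shape[1]):
        miss = seq.missing[:, lm]
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(
                f"{seq.video_id}: landmark {LANDMARK_NAMES[lm]!r} never observed")
        obs = ~miss
        for ch in range(values.shape[2]):
            values[miss, lm, ch] = np.interp(t[miss], t[obs], values[obs, lm, ch])
    return seq.with_values(values, missing=np.zeros(values.shape[:2], dtype=bool))


def resample_to_30fps(seq: PoseSequence) -> PoseSequence:
    """Downsample onto a uniform 30 Hz grid by per-channel linear interpolation.

    The grid spans the original duration. Input already at 30 fps is returned
    unchanged; upsampling is not supported.
    """
    if seq.missing.any():
        raise ValueError("interpolate missing values before resampling")
    if seq.fps < TARGET_FPS:
        raise ValueError(f"cannot upsample from {seq.fps} fps to {TARGET_FPS} fps")
    if seq.fps == TARGET_FPS:
        return seq
    t_src = np.arange(seq.n_frames) / seq.fps
    n_out = int(np.floor(t_src[-1] * TARGET_FPS)) + 1
    t_out = np.arange(n_out) / TARGET_FPS
    flat = seq.values.reshape(seq.n_frames, -1)
    out = np.empty((n_out, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_out, t_src, flat[:, j])
    return seq.with_values(out.reshape(n_out, *seq.values.shape[1:]), fps=TARGET_FPS)


def _rolling_median(x: np.ndarray, half_window: int) -> np.ndarray:
    """Centred rolling median with truncated (not padded) windows at the ends."""
    return (pd.DataFrame(x)
            .rolling(2 * half_window + 1, center=True, min_periods=1)
            .median()
            .to_numpy())


def hip_center(seq: PoseSequence) -> PoseSequence:
    """Subtract the 2-second rolling median of the hip-centre point.

    The hip centre is the midpoint of left and right hip. Using the median
    over frames [t-30, t+30] (truncated at the sequence ends) removes the
    walker's gross position while preserving within-window hip sway. Applied
    to all three channels.
    """
    if seq.fps != TARGET_FPS:
        raise ValueError("hip_center expects a 30 fps sequence")
    if seq.n_frames < 2:
        raise ValueError("sequence too short to hip-centre")
    hip_mid = 0.5 * (seq.values[:, LM["left_hip"], :]
                     + seq.values[:, LM["right_hip"], :])
    baseline = _rolling_median(hip_mid, MEDIAN_HALF_WINDOW)
    return seq.with_values(seq.values - baseline[:, None, :],
                           missing=seq.missing)


def rescale_frontal(seq: PoseSequence) -> PoseSequence:
    """Rescale frontal poses to a common stature; sagittal passes through.

    Body height is the vertical extent from the nose to the ankle midpoint,
    median-smoothed over the same 2-second window; all channels of each frame
    are multiplied by REFERENCE_HEIGHT / smoothed height. A frontal walker
    approaching the camera therefore keeps a constant apparent size.
    """
    if seq.view != "frontal":
        return seq
    ankle_mid_y = 0.5 * (seq.values[:, LM["left_ankle"], 1]
                         + seq.values[:, LM["right_ankle"], 1])
    height = np.abs(ankle_mid_y - seq.values[:, LM["nose"], 1])
    smooth = _rolling_median(height[:, None], MEDIAN_HALF_WINDOW)[:, 0]
    if np.any(smooth <= 0):
        raise ValueError(f"{seq.video_id}: nonpositive body-height estimate")
    scale = REFERENCE_HEIGHT / smooth
    return seq.with_values(seq.values * scale[:, None, None], missing=seq.missing)


def segment_windows(seq: PoseSequence) -> list[AnalysisWindow]:
    """Cut 30-frame windows starting at 0, 15, 30, ...; partial tails dropped."""
    if seq.fps != TARGET_FPS:
        raise ValueError("segment_windows expects a 30 fps sequence")
    T = seq.n_frames
    if T < WINDOW_FRAMES:
        return []
    starts = range(0, T - WINDOW_FRAMES + 1, WINDOW_STEP)
    return [AnalysisWindow(values=seq.values[s:s + WINDOW_FRAMES],
                           video_id=seq.video_id, subject_id=seq.subject_id,
                           view=seq.view, direction=seq.direction,
                           label=seq.label, start_frame=s)
            for s in starts]


def preprocess_sequence(seq: PoseSequence) -> PoseSequence:
    """Run the full cleaning chain (everything before windowing)."""
    seq = drop_empty_frames(seq)
    seq = interpolate_missing(seq)
    seq = resample_to_30fps(seq)
    seq = hip_center(seq)
    seq = rescale_frontal(seq)
    return seq


def preprocess_and_window(seq: PoseSequence) -> list[AnalysisWindow]:
    return segment_windows(preprocess_sequence(seq))
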