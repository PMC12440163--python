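"""In-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .skeleton import N_CHANNELS, N_LANDMARKS

GAIT_CLASSES: tuple[str, ...] = ("ANT", "CIR", "CRO", "NOR", "PAR", "TRE", "VAU")
VIEWS: tuple[str, ...] = ("frontal", "sagittal")
DIRECTIONS: tuple[str, ...] = ("left", "right")


@dataclass
class PoseSequence:
    """A pose time series for one video.

    Attributes
    ----------
    values : (T, 33, 3) float array
        Per-frame landmark coordinates: x pixel, y pixel, z relative depth.
        Missing observations are NaN in all three channels.
    missing : (T, 33) bool array
        True where the landmark was not observed in that frame.
    fps : float
        Frame rate of the series.
    video_id, subject_id, view, direction, label : str
        Provenance and the video-level gait label.
    """

    values: np.ndarray
    fps: float
    video_id: str
    subject_id: str
    view: str
    direction: str
    label: str
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (N_LANDMARKS, N_CHANNELS):
            raise ValueError(
                f"values must be (T, {N_LANDMARKS}, {N_CHANNELS}); got {self.values.shape}"
            )
        if self.values.shape[0] < 1:
            raise ValueError("PoseSequence needs at least one frame")
        if self.missing is None:
            self.missing = np.isnan(self.values).any(axis=2)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape[:2]:
            raise ValueError("missing mask must be (T, 33)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def with_values(self, values: np.ndarray, *, fps: float | None = None,
                    missing: np.ndarray | None = None) -> "PoseSequence":
        """Copy of this sequence with new frame data (metadata preserved)."""
        if missing is None:
            missing = np.isnan(np.asarray(values)).any(axis=2)
        return replace(self, values=values, missing=missing,
                       fps=self.fps if fps is None else fps)


@dataclass
class AnalysisWindow:
    """A 30-frame slice of a preprocessed sequence (one 1-second analysis frame)."""

    values: np.ndarray          # (30, 33, 3)
    video_id: str
    subject_id: str
    view: str
    direction: str
    label: str
    start_frame: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (30, N_LANDMARKS, N_CHANNELS):
            raise ValueError(f"a window must be (30, 33, 3); got {self.values.shape}")
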