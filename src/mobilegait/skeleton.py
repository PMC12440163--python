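"""33-point pose topology shared by the simulator and the analysis pipeline.

The landmark set and ordering follow the standard on-device pose-estimation
topology (nose, eyes, ears, mouth, shoulders, elbows, wrists, hand points,
hips, knees, ankles, heels, foot indices). Every pose frame is a 33 x 3
array whose channels are (x, y, z): horizontal pixel, vertical pixel and
relative depth.
"""

from __future__ import annotations

LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye_inner",
    "left_eye",
    "left_eye_outer",
    "right_eye_inner",
    "right_eye",
    "right_eye_outer",
    "left_ear",
    "right_ear",
    "mouth_left",
    "mouth_right",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_pinky",
    "right_pinky",
    "left_index",
    "right_index",
    "left_thumb",
    "right_thumb",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_heel",
    "right_heel",
    "left_foot_index",
    "right_foot_index",
)

N_LANDMARKS = len(LANDMARK_NAMES)  # 33
CHANNELS: tuple[str, ...] = ("x", "y", "z")
N_CHANNELS = len(CHANNELS)

LANDMARK_INDEX: dict[str, int] = {n: i for i, n in enumerate(LANDMARK_NAMES)}

#: (left, right) landmark index pairs, used for mirroring and symmetry checks.
LEFT_RIGHT_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (LANDMARK_INDEX[n], LANDMARK_INDEX["right" + n[4:]])
    for n in LANDMARK_NAMES
    if n.startswith("left_")
)

LOWER_LIMB: tuple[str, ...] = (
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
)

UPPER_LIMB: tuple[str, ...] = (
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_pinky", "right_pinky",
    "left_index", "right_index",
    "left_thumb", "right_thumb",
)

FACE: tuple[str, ...] = LANDMARK_NAMES[:11]


def channel_names() -> list[str]:
    """All 99 keypoint-channel names, e.g. ``right_ankle_y``, in canonical order.

    Canonical order is landmark-major (landmark index, then channel), which
    fixes the column layout of every feature matrix downstream.
    """
    return [f"{lm}_{ch}" for lm in LANDMARK_NAMES for ch in CHANNELS]


def parse_channel(name: str) -> tuple[str, str]:
    """Split a keypoint-channel name into (landmark, channel).

    Raises ``ValueError`` for names that do not end in a valid channel or do
    not start with a known landmark.
    """
    base, _, ch = name.rpartition("_")
    if ch not in CHANNELS or base not in LANDMARK_INDEX:
        raise ValueError(f"not a keypoint-channel name: {name!r}")
    return base, ch
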