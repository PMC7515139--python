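"""Feature composition for sequence classifiers, the quantity-of-motion
statistic, and the handcrafted whole-recording baseline features.

Six feature sets combine two axes: channel content (P = positions,
O = orientations, PO = both) and joint scope (full = the 19 non-hand
joints, U = the 11 non-hand upper-body joints).  The six hand-related
joints are always excluded: their apparent motion is dominated by sensor
noise, and hand position is adequately represented by the wrists.  Every
set also carries one shared temporal channel — the keyframe's timestamp
normalized to [0, 1] over the recording — giving per-keyframe widths

    P = 3*19 + 1 = 58      PU  = 3*11 + 1 = 34
    O = 3*19 + 1 = 58      OU  = 3*11 + 1 = 34
    PO = 6*19 + 1 = 115    POU = 6*11 + 1 = 67

Orientation channels of joints the sensor does not report are zero-filled
so matrices stay rectangular.

The quantity of motion of a joint under an emotion is its average
per-transition displacement in hierarchical local coordinates (relative to
its parent joint), averaged over all recordings of that emotion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coords
from .skeleton import (
    MotionSequence,
    JOINT_NAMES,
    JOINT_INDEX,
    NON_HAND_JOINTS,
    UPPER_BODY_JOINTS,
    HAND_JOINTS,
    EMOTIONS,
    EMOTION_ABBREV,
)
from .keyframes import KeyframeSequence

__all__ = [
    "FEATURE_SETS",
    "EXPECTED_FEATURE_COUNTS",
    "FeatureMatrix",
    "compose_features",
    "feature_names",
    "quantity_of_motion",
    "qom_heatmap",
    "extract_baseline_features",
    "BASELINE_FEATURE_NAMES",
]

#: set id -> (include_positions, include_orientations, joint scope)
FEATURE_SETS: dict[str, tuple[bool, bool, tuple[str, ...]]] = {
    "P": (True, False, NON_HAND_JOINTS),
    "O": (False, True, NON_HAND_JOINTS),
    "PO": (True, True, NON_HAND_JOINTS),
    "PU": (True, False, UPPER_BODY_JOINTS),
    "OU": (False, True, UPPER_BODY_JOINTS),
    "POU": (True, True, UPPER_BODY_JOINTS),
}

EXPECTED_FEATURE_COUNTS = {"P": 58, "O": 58, "PO": 115, "PU": 34, "OU": 34, "POU": 67}


@dataclass
class FeatureMatrix:
    """Keyframes x features array for one recording.

    ``mask`` is filled in by padding: True rows are real keyframes, False
    rows are zero padding (always a suffix).
    """

    values: np.ndarray
    set_id: str
    subject: str
    emotion: str
    repetition: int = 0
    sequence_id: str | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (keyframes x features)")
        expected = EXPECTED_FEATURE_COUNTS.get(self.set_id)
        if expected is not None and self.values.shape[1] != expected:
            # the no-time-channel variant deliberately deviates; tagged "-"
            raise ValueError(
                f"set {self.set_id}: expected {expected} columns, got {self.values.shape[1]}"
            )

    @property
    def n_keyframes(self) -> int:
        return self.values.shape[0]


def feature_names(set_id: str, time_channel: bool = True) -> list[str]:
    """Column names of :func:`compose_features` output, in order."""
    try:
        use_p, use_o, joints = FEATURE_SETS[set_id]
    except KeyError:
        raise ValueError(f"unknown feature set id {set_id!r}") from None
    names: list[str] = []
    if use_p:
        names += [f"{j}_p{ax}" for j in joints for ax in "uvw"]
    if use_o:
        names += [f"{j}_o{ax}" for j in joints for ax in "uvw"]
    if time_channel:
        names.append("t_norm")
    return names


def compose_features(
    seq: MotionSequence,
    set_id: str,
    keyframes: KeyframeSequence | None = None,
    time_channel: bool = True,
) -> FeatureMatrix:
    """Build the keyframes x features matrix for one recording.

    ``seq`` must be scale-normalized (root-relative, subject-scale
    corrected).  ``keyframes`` selects rows; None keeps every frame (the
    un-keyframed variant).  Orientation channels absent at the source are
    zero-filled.  With ``time_channel=False`` the shared temporal column is
    dropped and the set id is suffixed with ``-`` to mark that the column
    count deviates from the canonical widths.
    """
    if set_id not in FEATURE_SETS:
        raise ValueError(f"unknown feature set id {set_id!r}")
    if seq.space != "scale_normalized":
        raise ValueError(
            f"compose_features expects scale_normalized input, got {seq.space!r}"
        )
    use_p, use_o, joints = FEATURE_SETS[set_id]
    idx = keyframes.indices if keyframes is not None else np.arange(seq.n_frames)
    jidx = np.array([JOINT_INDEX[j] for j in joints])

    blocks = []
    if use_p:
        blocks.append(seq.positions[idx][:, jidx, :].reshape(len(idx), -1))
    if use_o:
        ori = seq.orientations[idx][:, jidx, :].reshape(len(idx), -1)
        blocks.append(np.nan_to_num(ori, nan=0.0))
    if time_channel:
        ts = seq.timestamps
        span = ts[-1] - ts[0]
        tnorm = (ts[idx] - ts[0]) / span if span > 0 else np.zeros(len(idx))
        blocks.append(tnorm[:, None])
    values = np.hstack(blocks)
    out_id = set_id if time_channel else set_id + "-"
    if not time_channel:
        warnings.warn(
            f"feature set {set_id} without the temporal channel has "
            f"{values.shape[1]} columns (canonical width is "
            f"{EXPECTED_FEATURE_COUNTS[set_id]})",
            stacklevel=2,
        )
    return FeatureMatrix(
        values=values, set_id=out_id, subject=seq.subject, emotion=seq.emotion,
        repetition=seq.repetition, sequence_id=seq.sequence_id,
    )


def quantity_of_motion(
    corpus: list[MotionSequence],
    per_transition: bool = True,
) -> pd.DataFrame:
    """Joints x emotions table of average relative motion.

    For each recording, each joint's positions are first expressed in its
    parent joint's local frame; the recording's score is the mean norm of
    the frame-to-frame displacement (divided by the number of transitions
    F-1, or by the frame count F with ``per_transition=False``); the table
    entry is the mean over all recordings of the emotion.  Emotions with no
    recordings are NaN.
    """
    if not corpus:
        raise ValueError("empty corpus")
    sums = {e: np.zeros(25) for e in EMOTIONS}
    counts = {e: 0 for e in EMOTIONS}
    for seq in corpus:
        local = coords.to_hierarchical_local(seq)  # (T,25,3)
        steps = np.linalg.norm(np.diff(local, axis=0), axis=2)  # (T-1,25)
        denom = seq.n_frames if not per_transition else seq.n_frames - 1
        sums[seq.emotion] += steps.sum(axis=0) / denom
        counts[seq.emotion] += 1
    data = {
        e: (sums[e] / counts[e] if counts[e] else np.full(25, np.nan))
        for e in EMOTIONS
    }
    return pd.DataFrame(data, index=pd.Index(JOINT_NAMES, name="joint"))


def qom_heatmap(table: pd.DataFrame, exclude_hands: bool = False, ax=None):
    """Render a quantity-of-motion table as a heatmap.

    ``exclude_hands=True`` drops the six hand-related joint rows (the
    variant that shows genuine limb involvement rather than hand-tracking
    noise).  Returns the matplotlib Axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    view = table.drop(index=[j for j in table.index if j in HAND_JOINTS]) if exclude_hands else table
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(view.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(view.shape[1]))
    ax.set_xticklabels([EMOTION_ABBREV.get(c, str(c)) for c in view.columns])
    ax.set_yticks(range(view.shape[0]))
    ax.set_yticklabels(view.index)
    ax.figure.colorbar(im, ax=ax, label="avg motion per transition")
    return ax


_W_L, _W_R = JOINT_INDEX["WristLeft"], JOINT_INDEX["WristRight"]
_E_L, _E_R = JOINT_INDEX["ElbowLeft"], JOINT_INDEX["ElbowRight"]
_K_L, _K_R = JOINT_INDEX["KneeLeft"], JOINT_INDEX["KneeRight"]
_A_L, _A_R = JOINT_INDEX["AnkleLeft"], JOINT_INDEX["AnkleRight"]
_SMID, _SSH, _SB = JOINT_INDEX["SpineMid"], JOINT_INDEX["SpineShoulder"], JOINT_INDEX["SpineBase"]
_HEAD = JOINT_INDEX["Head"]

BASELINE_FEATURE_NAMES = [
    "velocity_mean", "velocity_max", "acceleration_mean", "acceleration_max",
    "kinetic_energy", "bbox_volume_mean", "bbox_volume_max",
    "contraction_index", "density", "jerk_mean", "leaning_mean",
    "wrist_distance_mean", "elbow_distance_mean",
    "knee_distance_mean", "ankle_distance_mean", "wrist_head_distance_mean",
]


def extract_baseline_features(seq: MotionSequence) -> pd.Series:
    """Whole-recording scalar summaries for the classic-classifier baseline.

    Operates on a full-frame (not keyframed) scale-normalized sequence.
    Definitions (p[t,j] = joint positions, dt = timestep):

    * velocity: per-joint speed ||p[t+1]-p[t]|| / dt; mean and max over all
      joints and frames
    * acceleration: ||p[t+2]-2 p[t+1]+p[t]|| / dt^2; mean and max
    * kinetic-energy proxy: mean over frames of sum_j ||v[t,j]||^2
    * bounding-box volume: per-frame product of axis extents over joints;
      mean and max
    * contraction index: mean over frames of the mean wrist-to-SpineMid
      distance divided by trunk length ||SpineShoulder-SpineBase||
    * density: mean over frames of the mean joint distance to the frame
      centroid
    * smoothness: mean third-difference (jerk) magnitude
      ||p[t+3]-3 p[t+2]+3 p[t+1]-p[t]|| / dt^3 (0 for 3-frame sequences)
    * leaning: mean trunk pitch, atan2(trunk_w, trunk_v) in degrees for
      the SpineBase->SpineShoulder vector
    * distances: mean separation of symmetric joint pairs (wrists, elbows,
      knees, ankles) and mean wrist-to-head distance

    Raises for sequences shorter than 3 frames (acceleration undefined).
    """
    if seq.n_frames < 3:
        raise ValueError("baseline features need at least 3 frames")
    p = seq.positions  # (T,25,3); root channel included as-is
    dt = np.diff(seq.timestamps)[:, None, None]

    v = np.diff(p, axis=0) / dt  # (T-1,25,3)
    speed = np.linalg.norm(v, axis=2)
    dt2 = (np.diff(seq.timestamps)[:-1] ** 2)[:, None, None]
    acc = np.linalg.norm((p[2:] - 2 * p[1:-1] + p[:-2]) / dt2, axis=2)
    if seq.n_frames >= 4:
        dt3 = (np.diff(seq.timestamps)[:-2] ** 3)[:, None, None]
        jerk = np.linalg.norm((p[3:] - 3 * p[2:-1] + 3 * p[1:-2] - p[:-3]) / dt3, axis=2)
        jerk_mean = float(jerk.mean())
    else:
        jerk_mean = 0.0

    extents = p.max(axis=1) - p.min(axis=1)  # (T,3)
    bbox = np.prod(extents, axis=1)

    trunk = p[:, _SSH] - p[:, _SB]
    trunk_len = np.linalg.norm(trunk, axis=1)
    trunk_len = np.where(trunk_len > 0, trunk_len, 1.0)
    wrist_torso = 0.5 * (
        np.linalg.norm(p[:, _W_L] - p[:, _SMID], axis=1)
        + np.linalg.norm(p[:, _W_R] - p[:, _SMID], axis=1)
    )
    centroid = p.mean(axis=1, keepdims=True)
    density = np.linalg.norm(p - centroid, axis=2).mean(axis=1)
    leaning = np.degrees(np.arctan2(trunk[:, 2], trunk[:, 1]))

    vals = [
        float(speed.mean()), float(speed.max()),
        float(acc.mean()), float(acc.max()),
        float((speed ** 2).sum(axis=1).mean()),
        float(bbox.mean()), float(bbox.max()),
        float((wrist_torso / trunk_len).mean()),
        float(density.mean()),
        jerk_mean,
        float(leaning.mean()),
        float(np.linalg.norm(p[:, _W_L] - p[:, _W_R], axis=1).mean()),
        float(np.linalg.norm(p[:, _E_L] - p[:, _E_R], axis=1).mean()),
        float(np.linalg.norm(p[:, _K_L] - p[:, _K_R], axis=1).mean()),
        float(np.linalg.norm(p[:, _A_L] - p[:, _A_R], axis=1).mean()),
        float(0.5 * (
            np.linalg.norm(p[:, _W_L] - p[:, _HEAD], axis=1)
            + np.linalg.norm(p[:, _W_R] - p[:, _HEAD], axis=1)
        ).mean()),
    ]
    out = pd.Series(vals, index=BASELINE_FEATURE_NAMES)
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValueError("non-finite baseline feature")
    return out
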