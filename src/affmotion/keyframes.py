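"""Keyframe extraction by trajectory curve simplification.

A joint's positions over a recording form a polyline in 3D.  Starting from
the chord connecting its first and last point, the polyline is split at the
interior point with the largest perpendicular distance to the chord
whenever that distance exceeds the error rate (in meters), and the rule is
applied recursively to both sublines.  The surviving split points, plus the
two endpoints, are the keyframes.

Two deterministic choices matter:

* deviation metric — Euclidean point-to-segment distance in 3D (the
  standard Douglas–Peucker / Lowe criterion), which is invariant to rigid
  motions of the trajectory;
* tie-breaking — among equally-far points the lowest index wins.  With
  that rule the binary split tree does not depend on the error rate, the
  rate only prunes it, so keyframe sets are nested: a larger tolerance
  always yields a subset of a smaller one.

Error rates of 0.03 m (default) and 0.05 m are the working settings;
0.01/0.02 m select nearly every frame (sensor noise scale) and
0.10/0.15 m leave little beyond the endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .skeleton import MotionSequence, NON_HAND_JOINTS, JOINT_INDEX, EMOTIONS

__all__ = [
    "KeyframeSequence",
    "DEFAULT_ERROR_RATE",
    "simplify_trajectory",
    "extract_keyframes",
    "keyframe_count_sweep",
]

DEFAULT_ERROR_RATE = 0.03  # meters
#: Rates the pipeline treats as validated working settings.
SUPPORTED_ERROR_RATES = (0.03, 0.05)
#: Explorable but flagged: noise-scale or too coarse.
FLAGGED_ERROR_RATES = (0.01, 0.02, 0.10, 0.15)


@dataclass(frozen=True)
class KeyframeSequence:
    """Selected frame indices for one recording."""

    indices: np.ndarray
    error_rate: float
    joints_used: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.size < 2 or not np.all(np.diff(idx) > 0):
            raise ValueError("keyframe indices must be >=2, unique and sorted")

    def __len__(self) -> int:
        return int(self.indices.size)


def _seg_distances(points: np.ndarray) -> np.ndarray:
    """Distance of each point to the segment from points[0] to points[-1]."""
    a, b = points[0], points[-1]
    ab = b - a
    denom = float(ab @ ab)
    rel = points - a
    if denom == 0.0:
        return np.linalg.norm(rel, axis=1)
    t = np.clip(rel @ ab / denom, 0.0, 1.0)
    proj = np.outer(t, ab)
    return np.linalg.norm(rel - proj, axis=1)


def simplify_trajectory(points: np.ndarray, error_rate: float) -> np.ndarray:
    """Indices kept by recursive chord-deviation simplification.

    Always contains 0 and len(points)-1; interior indices appear only where
    the maximum point-to-chord distance exceeded ``error_rate`` somewhere on
    the containing subline.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points with fixed dimensionality")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in trajectory")
    if not (error_rate > 0):
        raise ValueError("error_rate must be positive")

    n = pts.shape[0]
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        d = _seg_distances(pts[lo:hi + 1])
        k = int(np.argmax(d[1:-1])) + 1  # first (lowest-index) maximum
        if d[k] > error_rate:
            keep[lo + k] = True
            stack.append((lo, lo + k))
            stack.append((lo + k, hi))
    return np.flatnonzero(keep)


def extract_keyframes(
    seq: MotionSequence,
    error_rate: float = DEFAULT_ERROR_RATE,
    joints: tuple[str, ...] | None = None,
    merge: str = "union",
) -> KeyframeSequence | dict[str, KeyframeSequence]:
    """Keyframes of a recording from per-joint trajectory simplification.

    Each selected joint's position trajectory is simplified independently;
    with ``merge='union'`` (default) a frame is a keyframe if it is salient
    for any joint.  ``merge='per_joint'`` returns one
    :class:`KeyframeSequence` per joint instead.  Default joint scope is
    the 19 non-hand joints.
    """
    if seq.space not in ("body_local", "scale_normalized"):
        raise ValueError(
            f"keyframe extraction expects body_local or scale_normalized input, got {seq.space!r}"
        )
    if joints is None:
        joints = NON_HAND_JOINTS
    joints = tuple(joints)
    if not joints:
        raise ValueError("joint set must be nonempty")
    per_joint = {
        name: simplify_trajectory(seq.positions[:, JOINT_INDEX[name], :], error_rate)
        for name in joints
    }
    if merge == "per_joint":
        return {
            name: KeyframeSequence(idx, error_rate, (name,))
            for name, idx in per_joint.items()
        }
    if merge != "union":
        raise ValueError(f"unknown merge mode {merge!r}")
    union = np.unique(np.concatenate(list(per_joint.values())))
    return KeyframeSequence(union, error_rate, joints)


def keyframe_count_sweep(
    corpus: list[MotionSequence],
    error_rates: list[float],
    joints: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mean keyframe count per emotion at each error rate.

    Returns a DataFrame indexed by emotion (canonical order, only emotions
    present in the corpus) with one column per error rate.
    """
    if not corpus:
        raise ValueError("empty corpus")
    records: dict[float, dict[str, list[int]]] = {e: {} for e in error_rates}
    for seq in corpus:
        for eps in error_rates:
            kf = extract_keyframes(seq, error_rate=eps, joints=joints)
            records[eps].setdefault(seq.emotion, []).append(len(kf))
    present = [e for e in EMOTIONS if e in records[error_rates[0]]]
    return pd.DataFrame(
        {eps: [float(np.mean(records[eps][e])) for e in present] for eps in error_rates},
        index=pd.Index(present, name="emotion"),
    )
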