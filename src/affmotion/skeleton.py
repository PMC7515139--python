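"""Canonical 25-joint skeleton model, joint taxonomy, and sequence I/O.

The skeleton follows the Kinect-v2 joint set: 25 named joints, each with a
3D position in meters (sensor frame: x left, y up, z forward) and, for most
joints, an orientation given as three angles in degrees.  The sensor does
not report orientations for the head, the hand-related joints, the knees
and the feet; those are stored as NaN ("absent"), never as zeros, so that
downstream feature composition can choose its own fill policy.

A :class:`MotionSequence` is the unit of data throughout the package: an
ordered stack of frames for one recording, tagged with subject, emotion
label, repetition index, and a coordinate-space tag that each transform
updates exactly once (``sensor`` -> ``body_local`` -> ``scale_normalized``).

Sequences are serialized to a flat CSV (one row per sequence/frame/joint)
or JSON-lines (one object per frame); both round-trip losslessly to 1e-9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JOINT_NAMES",
    "JOINT_INDEX",
    "PARENT_NAME",
    "PARENT_INDEX",
    "HAND_JOINTS",
    "NON_HAND_JOINTS",
    "UPPER_BODY_JOINTS",
    "NO_ORIENTATION_JOINTS",
    "EMOTIONS",
    "EMOTION_ABBREV",
    "SIX_CLASS_SUBSET",
    "FOUR_CLASS_SUBSET",
    "MotionSequence",
    "ParseError",
    "SchemaError",
    "read_sequences",
    "write_sequences",
    "corpus_manifest",
]

# Standard Kinect-v2 numbering, SpineBase=0 ... ThumbRight=24.
JOINT_NAMES: tuple[str, ...] = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}

# Parent links form a tree rooted at SpineBase.
PARENT_NAME: dict[str, str | None] = {
    "SpineBase": None,
    "SpineMid": "SpineBase",
    "SpineShoulder": "SpineMid",
    "Neck": "SpineShoulder",
    "Head": "Neck",
    "ShoulderLeft": "SpineShoulder",
    "ElbowLeft": "ShoulderLeft",
    "WristLeft": "ElbowLeft",
    "HandLeft": "WristLeft",
    "HandTipLeft": "HandLeft",
    "ThumbLeft": "WristLeft",
    "ShoulderRight": "SpineShoulder",
    "ElbowRight": "ShoulderRight",
    "WristRight": "ElbowRight",
    "HandRight": "WristRight",
    "HandTipRight": "HandRight",
    "ThumbRight": "WristRight",
    "HipLeft": "SpineBase",
    "KneeLeft": "HipLeft",
    "AnkleLeft": "KneeLeft",
    "FootLeft": "AnkleLeft",
    "HipRight": "SpineBase",
    "KneeRight": "HipRight",
    "AnkleRight": "KneeRight",
    "FootRight": "AnkleRight",
}

PARENT_INDEX: np.ndarray = np.array(
    [-1 if PARENT_NAME[n] is None else JOINT_INDEX[PARENT_NAME[n]] for n in JOINT_NAMES],
    dtype=np.int64,
)

# The six hand-related joints excluded from all feature sets (their sensor
# noise dominates genuine motion).
HAND_JOINTS: frozenset[str] = frozenset(
    {"HandLeft", "HandRight", "HandTipLeft", "HandTipRight", "ThumbLeft", "ThumbRight"}
)

#: 19 non-hand joints, in index order.
NON_HAND_JOINTS: tuple[str, ...] = tuple(n for n in JOINT_NAMES if n not in HAND_JOINTS)

#: 11 non-hand upper-body joints, in index order.
UPPER_BODY_JOINTS: tuple[str, ...] = tuple(
    n for n in JOINT_NAMES
    if n in {
        "SpineBase", "SpineMid", "Neck", "Head", "ShoulderLeft", "ShoulderRight",
        "ElbowLeft", "ElbowRight", "WristLeft", "WristRight", "SpineShoulder",
    }
)

# Joints for which the sensor reports no orientation: head, hands, knees, feet.
NO_ORIENTATION_JOINTS: frozenset[str] = frozenset(
    {"Head", "KneeLeft", "KneeRight", "FootLeft", "FootRight"} | HAND_JOINTS
)

EMOTIONS: tuple[str, ...] = (
    "neutral", "sadness", "surprise", "fear", "anger", "disgust", "happiness",
)
EMOTION_ABBREV: dict[str, str] = {
    "neutral": "Ne", "sadness": "Sa", "surprise": "Su", "fear": "Fe",
    "anger": "An", "disgust": "Di", "happiness": "Ha",
}
#: 6-class subset: the seven basic emotions without neutral.
SIX_CLASS_SUBSET: tuple[str, ...] = tuple(e for e in EMOTIONS if e != "neutral")
#: 4-class subset most commonly used in the literature.
FOUR_CLASS_SUBSET: tuple[str, ...] = ("sadness", "fear", "anger", "happiness")

SPACES = ("sensor", "body_local", "scale_normalized")


class ParseError(ValueError):
    """A malformed row/record in a skeletal data file."""


class SchemaError(ValueError):
    """Data that parses but violates the skeletal schema (joint set, labels)."""


@dataclass
class MotionSequence:
    """One recording: an ordered stack of 25-joint skeleton frames.

    Parameters
    ----------
    positions : (T, 25, 3) float array, meters.  After the body-local
        transform, row 0 of axis 1 holds the root displacement relative to
        the first frame (expressed in the first frame's root axes).
    orientations : (T, 25, 3) float array, degrees; NaN rows mark joints
        whose orientation the sensor does not report.
    timestamps : (T,) float array, seconds, strictly increasing.
    subject, emotion, repetition : recording metadata.
    space : coordinate-space tag, one of ``sensor``, ``body_local``,
        ``scale_normalized``.
    """

    positions: np.ndarray
    orientations: np.ndarray
    timestamps: np.ndarray
    subject: str
    emotion: str
    repetition: int = 0
    space: str = "sensor"
    sequence_id: str | None = None
    quality_ok: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.orientations = np.asarray(self.orientations, dtype=np.float64)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        t = self.positions.shape[0]
        if self.positions.shape != (t, 25, 3):
            raise SchemaError(f"positions must be (T, 25, 3), got {self.positions.shape}")
        if self.orientations.shape != (t, 25, 3):
            raise SchemaError(f"orientations must be (T, 25, 3), got {self.orientations.shape}")
        if self.timestamps.shape != (t,):
            raise SchemaError("timestamps length must match frame count")
        if t < 2:
            raise SchemaError("a motion sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            raise SchemaError("non-finite joint position")
        if not np.all(np.diff(self.timestamps) > 0):
            raise SchemaError("timestamps must be strictly increasing")
        if self.emotion not in EMOTIONS:
            raise SchemaError(f"unknown emotion label {self.emotion!r}")
        if self.space not in SPACES:
            raise SchemaError(f"unknown space tag {self.space!r}")
        if self.sequence_id is None:
            self.sequence_id = f"{self.subject}_{self.emotion}_{self.repetition}"

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds (last minus first timestamp)."""
        return float(self.timestamps[-1] - self.timestamps[0])

    def copy(self, **changes) -> "MotionSequence":
        base = dict(
            positions=self.positions.copy(),
            orientations=self.orientations.copy(),
            timestamps=self.timestamps.copy(),
            subject=self.subject,
            emotion=self.emotion,
            repetition=self.repetition,
            space=self.space,
            sequence_id=self.sequence_id,
            quality_ok=self.quality_ok,
        )
        base.update(changes)
        return MotionSequence(**base)


_CSV_COLUMNS = [
    "sequence_id", "subject_id", "emotion", "repetition", "frame_index",
    "timestamp_s", "joint_name", "px", "py", "pz", "ox", "oy", "oz", "space",
]


def write_sequences(seqs: Sequence[MotionSequence], path, fmt: str = "csv") -> None:
    """Write sequences to ``path`` in CSV or JSON-lines form.

    CSV: one row per (sequence, frame, joint); orientation cells are empty
    for joints without orientation.  JSONL: one object per frame with a
    nested joint map.  Both are UTF-8 with '.' decimal and round-trip
    through :func:`read_sequences` to 1e-9.
    """
    if fmt == "csv":
        rows = []
        for seq in seqs:
            for t in range(seq.n_frames):
                for j, name in enumerate(JOINT_NAMES):
                    o = seq.orientations[t, j]
                    has_o = bool(np.all(np.isfinite(o)))
                    rows.append((
                        seq.sequence_id, seq.subject, seq.emotion, seq.repetition,
                        t, repr(float(seq.timestamps[t])), name,
                        *(repr(float(v)) for v in seq.positions[t, j]),
                        *((repr(float(v)) for v in o) if has_o else ("", "", "")),
                        seq.space,
                    ))
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for seq in seqs:
                for t in range(seq.n_frames):
                    joints = {}
                    for j, name in enumerate(JOINT_NAMES):
                        o = seq.orientations[t, j]
                        joints[name] = {
                            "p": [float(v) for v in seq.positions[t, j]],
                            "o": [float(v) for v in o] if np.all(np.isfinite(o)) else None,
                        }
                    rec = {
                        "sequence_id": seq.sequence_id,
                        "subject_id": seq.subject,
                        "emotion": seq.emotion,
                        "repetition": seq.repetition,
                        "frame_index": t,
                        "timestamp_s": float(seq.timestamps[t]),
                        "space": seq.space,
                        "joints": joints,
                    }
                    fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _assemble(seq_id, meta, frames) -> MotionSequence:
    order = sorted(frames)
    T = len(order)
    pos = np.empty((T, 25, 3))
    ori = np.full((T, 25, 3), np.nan)
    ts = np.empty(T)
    for row, fidx in enumerate(order):
        joints, stamp = frames[fidx]
        if len(joints) != 25:
            raise ParseError(
                f"sequence {seq_id!r} frame {fidx}: expected 25 joints, got {len(joints)}"
            )
        ts[row] = stamp
        for name, (p, o) in joints.items():
            j = JOINT_INDEX[name]
            pos[row, j] = p
            if o is not None:
                ori[row, j] = o
    return MotionSequence(
        positions=pos, orientations=ori, timestamps=ts,
        subject=meta["subject"], emotion=meta["emotion"],
        repetition=meta["repetition"], space=meta["space"], sequence_id=seq_id,
    )


def read_sequences(path, fmt: str = "csv") -> list[MotionSequence]:
    """Read sequences written by :func:`write_sequences`.

    Raises :class:`ParseError` for malformed rows (wrong joint count,
    non-numeric fields) naming the offending line, and :class:`SchemaError`
    for unknown joint names or labels.
    """
    per_seq: dict[str, dict] = {}

    def add(seq_id, meta, fidx, name, p, o, line_no):
        if name not in JOINT_INDEX:
            raise SchemaError(f"line {line_no}: unknown joint name {name!r}")
        entry = per_seq.setdefault(seq_id, {"meta": meta, "frames": {}})
        joints, _ = entry["frames"].setdefault(fidx, ({}, meta["timestamp"]))
        if name in joints:
            raise ParseError(f"line {line_no}: duplicate joint {name!r} in frame {fidx}")
        joints[name] = (p, o)
        entry["frames"][fidx] = (joints, meta["timestamp"])

    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _CSV_COLUMNS[:-1] if c not in df.columns]
        if missing:
            raise ParseError(f"missing CSV columns: {missing}")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                p = [float(row.px), float(row.py), float(row.pz)]
                fidx = int(row.frame_index)
                stamp = float(row.timestamp_s)
                rep = int(row.repetition)
                o = None
                if row.ox != "" or row.oy != "" or row.oz != "":
                    o = [float(row.ox), float(row.oy), float(row.oz)]
            except (TypeError, ValueError) as exc:
                raise ParseError(f"line {i}: non-numeric field ({exc})") from exc
            meta = {
                "subject": row.subject_id, "emotion": row.emotion,
                "repetition": rep, "timestamp": stamp,
                "space": getattr(row, "space", "sensor") or "sensor",
            }
            add(row.sequence_id, meta, fidx, row.joint_name, p, o, i)
    elif fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    fidx = int(rec["frame_index"])
                    stamp = float(rec["timestamp_s"])
                    meta = {
                        "subject": rec["subject_id"], "emotion": rec["emotion"],
                        "repetition": int(rec["repetition"]), "timestamp": stamp,
                        "space": rec.get("space", "sensor"),
                    }
                    for name, jv in rec["joints"].items():
                        p = [float(v) for v in jv["p"]]
                        o = None if jv.get("o") is None else [float(v) for v in jv["o"]]
                        add(rec["sequence_id"], meta, fidx, name, p, o, i)
                except (KeyError, TypeError, ValueError) as exc:
                    if isinstance(exc, (ParseError, SchemaError)):
                        raise
                    raise ParseError(f"line {i}: malformed record ({exc})") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}")

    out = []
    for seq_id, entry in per_seq.items():
        meta = entry["meta"].copy()
        # last meta wins; metadata is constant within a sequence by schema
        out.append(_assemble(seq_id, meta, entry["frames"]))
    return out


def corpus_manifest(seqs: Iterable[MotionSequence]) -> pd.DataFrame:
    """Per-emotion sample counts and mean recording durations.

    Returns a DataFrame indexed by the canonical emotion order with columns
    ``n_samples`` and ``mean_duration_s``; counts sum to the corpus size.
    """
    counts = {e: 0 for e in EMOTIONS}
    durs: dict[str, list[float]] = {e: [] for e in EMOTIONS}
    for s in seqs:
        counts[s.emotion] += 1
        durs[s.emotion].append(s.duration)
    return pd.DataFrame(
        {
            "n_samples": [counts[e] for e in EMOTIONS],
            "mean_duration_s": [float(np.mean(durs[e])) if durs[e] else np.nan for e in EMOTIONS],
        },
        index=pd.Index(EMOTIONS, name="emotion"),
    )
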