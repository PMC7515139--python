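"""Synthetic emotional-gesture corpus generator.

Produces labeled 25-joint skeletal recordings with the statistical
structure the pipeline assumes: a corpus of subjects x emotions x
repetitions (default 16 x 7 x 5 = 560 recordings, 80 per emotion) of
3.5-5 s at 30 fps, archetype-driven motion concentrated in arms and
wrists with visible knee/ankle involvement, per-subject stature, sensor
placement offsets, and Gaussian jitter that is larger on the hand joints.

Motion model
------------
Each subject is an articulated skeleton: fixed bone offsets (scaled by the
subject's height) connected in the standard joint tree.  An emotion
archetype actuates a set of joints — spine, neck, shoulders, elbows,
wrists, hips, knees — with smooth sinusoidal rotation strokes (per-joint
amplitude, tempo, phase and a per-repetition random variation), plus root
translation events (a bounce for happiness, a backing-out drift for fear
and disgust, sway for everyone).  Joint positions come from forward
kinematics, so bone lengths are exactly constant before jitter.  Disgust
and fear share a "backing out, hands near the head" motif on purpose so
confusion structure between them is meaningful.

The emitted joint orientations emulate what a depth sensor reports rather
than the exact kinematic frames: the root orientation plus a slow,
small-amplitude wobble per joint.  Exact kinematic frames would make each
joint's parent-relative position a constant and the quantity-of-motion
statistic degenerate; coarse orientation tracking is also what the real
device provides.  Joints of the head, hands, knees and feet carry no
orientation at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .skeleton import (
    MotionSequence,
    JOINT_NAMES,
    JOINT_INDEX,
    PARENT_NAME,
    HAND_JOINTS,
    NO_ORIENTATION_JOINTS,
    EMOTIONS,
)

__all__ = [
    "EmotionArchetype",
    "GeneratorConfig",
    "ARCHETYPES",
    "generate_corpus",
    "degrade",
    "reject_low_quality",
]

# Bone offsets for a 1.75 m reference stature, in body axes
# (u left, v up, w forward), rest pose standing with arms hanging.
_REF_HEIGHT = 1.75
_BONE_OFFSETS: dict[str, tuple[float, float, float]] = {
    "SpineMid": (0.0, 0.26, 0.0),
    "SpineShoulder": (0.0, 0.24, 0.0),
    "Neck": (0.0, 0.08, 0.0),
    "Head": (0.0, 0.16, 0.0),
    "ShoulderLeft": (0.19, -0.03, 0.0),
    "ElbowLeft": (0.03, -0.28, 0.0),
    "WristLeft": (0.01, -0.25, 0.0),
    "HandLeft": (0.0, -0.08, 0.0),
    "HandTipLeft": (0.0, -0.06, 0.0),
    "ThumbLeft": (-0.03, -0.04, 0.03),
    "ShoulderRight": (-0.19, -0.03, 0.0),
    "ElbowRight": (-0.03, -0.28, 0.0),
    "WristRight": (-0.01, -0.25, 0.0),
    "HandRight": (0.0, -0.08, 0.0),
    "HandTipRight": (0.0, -0.06, 0.0),
    "ThumbRight": (0.03, -0.04, 0.03),
    "HipLeft": (0.09, -0.08, 0.0),
    "KneeLeft": (0.01, -0.42, 0.0),
    "AnkleLeft": (0.0, -0.40, 0.0),
    "FootLeft": (0.0, -0.06, 0.13),
    "HipRight": (-0.09, -0.08, 0.0),
    "KneeRight": (-0.01, -0.42, 0.0),
    "AnkleRight": (0.0, -0.40, 0.0),
    "FootRight": (-0.0, -0.06, 0.13),
}

# topological order: parents before children
_TOPO: list[str] = []
_pending = [n for n in JOINT_NAMES if n != "SpineBase"]
while _pending:
    for n in list(_pending):
        if PARENT_NAME[n] == "SpineBase" or PARENT_NAME[n] in _TOPO:
            _TOPO.append(n)
            _pending.remove(n)


@dataclass(frozen=True)
class EmotionArchetype:
    """Motion signature of one emotional state.

    ``joint_moves``: actuated joint -> (rotation axis in body coords,
    amplitude rad, angle bias rad).  ``tempo_hz`` drives the shared stroke
    frequency; ``envelope`` shapes it over the recording ("sustain" —
    constant, "burst" — single early gaussian stroke, "tremble" — sustained
    with a high-frequency low-amplitude overlay).  ``bounce_amp``/
    ``bounce_hz`` move the root vertically (hop/squat class of events,
    positive amplitude = upward bounce); ``drift_w`` shifts the root along
    the forward axis over the recording (negative = backing out).
    """

    name: str
    joint_moves: dict[str, tuple[tuple[float, float, float], float, float]]
    tempo_hz: float
    envelope: str = "sustain"
    bounce_amp: float = 0.0
    bounce_hz: float = 0.0
    drift_w: float = 0.0
    sway_amp: float = 0.008


_U, _V, _W = (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)

ARCHETYPES: dict[str, EmotionArchetype] = {
    "neutral": EmotionArchetype(
        "neutral",
        {
            "SpineMid": (_U, 0.012, 0.0),
            "ShoulderLeft": (_U, 0.015, 0.0),
            "ShoulderRight": (_U, 0.015, 0.0),
        },
        tempo_hz=0.25,
    ),
    "sadness": EmotionArchetype(
        "sadness",
        {
            "SpineMid": (_U, 0.10, 0.28),      # slumping forward
            "Neck": (_U, 0.08, 0.30),
            "ShoulderLeft": (_U, 0.18, 0.10),
            "ShoulderRight": (_U, 0.16, 0.10),
            "ElbowLeft": (_U, 0.12, 0.08),
            "ElbowRight": (_U, 0.12, 0.08),
            "KneeLeft": (_U, 0.05, 0.05),
            "KneeRight": (_U, 0.05, 0.05),
        },
        tempo_hz=0.40,
    ),
    "surprise": EmotionArchetype(
        "surprise",
        {
            "ShoulderLeft": (_W, 0.95, -0.1),  # arms fly up/out
            "ShoulderRight": (_W, -0.95, 0.1),
            "ElbowLeft": (_U, 0.55, 0.2),
            "ElbowRight": (_U, 0.55, 0.2),
            "SpineMid": (_U, -0.10, -0.06),    # recoil upright
            "Neck": (_U, -0.08, 0.0),
            "KneeLeft": (_U, 0.10, 0.02),
            "KneeRight": (_U, 0.10, 0.02),
        },
        tempo_hz=1.2,
        envelope="burst",
        drift_w=-0.06,
    ),
    "fear": EmotionArchetype(
        "fear",
        {
            "ShoulderLeft": (_U, 0.80, 0.9),   # hands pulled near the head
            "ShoulderRight": (_U, 0.80, 0.9),
            "ElbowLeft": (_W, 1.05, 1.0),
            "ElbowRight": (_W, -1.05, -1.0),
            "WristLeft": (_U, 0.35, 0.2),
            "WristRight": (_U, 0.35, 0.2),
            "SpineMid": (_U, 0.10, 0.12),
            "KneeLeft": (_U, 0.18, 0.16),      # slight crouch
            "KneeRight": (_U, 0.18, 0.16),
            "HipLeft": (_U, -0.10, -0.08),
            "HipRight": (_U, -0.10, -0.08),
        },
        tempo_hz=1.6,
        envelope="tremble",
        drift_w=-0.16,
        bounce_amp=-0.03,
        bounce_hz=0.5,
    ),
    "anger": EmotionArchetype(
        "anger",
        {
            "ShoulderLeft": (_U, 0.95, 0.35),  # fast alternating punches
            "ShoulderRight": (_U, 0.95, 0.35),
            "ElbowLeft": (_U, 0.70, 0.35),
            "ElbowRight": (_U, 0.70, 0.35),
            "WristLeft": (_U, 0.30, 0.0),
            "WristRight": (_U, 0.30, 0.0),
            "SpineMid": (_U, 0.12, -0.10),     # leaning in
            "Neck": (_U, 0.06, -0.04),
            "HipLeft": (_U, 0.08, 0.04),
            "HipRight": (_U, 0.08, 0.04),
            "KneeLeft": (_U, 0.12, 0.06),
            "KneeRight": (_U, 0.12, 0.06),
        },
        tempo_hz=1.5,
    ),
    "disgust": EmotionArchetype(
        "disgust",
        {
            "ShoulderLeft": (_U, 0.55, 0.7),   # shares the fear motif,
            "ShoulderRight": (_U, 0.55, 0.7),  # slower and with a turn-away
            "ElbowLeft": (_W, 0.85, 0.8),
            "ElbowRight": (_W, -0.85, -0.8),
            "WristLeft": (_U, 0.25, 0.15),
            "WristRight": (_U, 0.25, 0.15),
            "SpineMid": (_V, 0.18, 0.12),      # torso yaw away
            "Neck": (_V, 0.15, 0.10),
            "KneeLeft": (_U, 0.08, 0.05),
            "KneeRight": (_U, 0.08, 0.05),
        },
        tempo_hz=0.9,
        drift_w=-0.10,
    ),
    "happiness": EmotionArchetype(
        "happiness",
        {
            "ShoulderLeft": (_W, 0.85, -0.3),  # open upward arm swings
            "ShoulderRight": (_W, -0.85, 0.3),
            "ElbowLeft": (_U, 0.50, -0.2),
            "ElbowRight": (_U, 0.50, -0.2),
            "WristLeft": (_U, 0.25, 0.0),
            "WristRight": (_U, 0.25, 0.0),
            "SpineMid": (_U, -0.08, -0.08),
            "HipLeft": (_U, 0.10, 0.05),
            "HipRight": (_U, 0.10, 0.05),
            "KneeLeft": (_U, 0.22, 0.10),      # springy legs for the hop
            "KneeRight": (_U, 0.22, 0.10),
        },
        tempo_hz=1.3,
        bounce_amp=0.06,                        # joyful hop
        bounce_hz=1.3,
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus design parameters (defaults mirror the study design)."""

    n_subjects: int = 16
    n_repetitions: int = 5
    emotions: tuple[str, ...] = EMOTIONS
    duration_range: tuple[float, float] = (3.5, 5.0)
    fps: float = 30.0
    height_range: tuple[float, float] = (1.55, 1.95)
    body_jitter_sd: float = 0.003
    hand_jitter_sd: float = 0.012
    orientation_jitter_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_repetitions < 1 or not self.emotions:
            raise ValueError("all counts must be >= 1")
        if self.body_jitter_sd < 0 or self.hand_jitter_sd < 0:
            raise ValueError("jitter sigmas must be >= 0")
        if self.fps <= 0 or self.duration_range[0] <= 0:
            raise ValueError("fps and durations must be positive")
        unknown = set(self.emotions) - set(EMOTIONS)
        if unknown:
            raise ValueError(f"unknown emotions {sorted(unknown)}")


def _envelope(kind: str, t: np.ndarray, dur: float, rng) -> np.ndarray:
    if kind == "burst":
        center = dur * rng.uniform(0.2, 0.45)
        width = dur * 0.18
        return np.exp(-0.5 * ((t - center) / width) ** 2)
    if kind == "tremble":
        return 0.75 + 0.25 * np.sin(2 * np.pi * 0.8 * t)
    ramp = np.clip(t / 0.4, 0.0, 1.0)  # ease-in from the rest pose
    return ramp


def _simulate_sequence(subject_id, emotion, rep, height, placement, cfg, rng):
    arch = ARCHETYPES[emotion]
    dur = rng.uniform(*cfg.duration_range)
    T = max(int(round(dur * cfg.fps)), 8)
    t = np.arange(T) / cfg.fps
    scale = height / _REF_HEIGHT

    env = _envelope(arch.envelope, t, dur, rng)
    tempo = arch.tempo_hz * rng.uniform(0.9, 1.1)

    # per-joint angle tracks
    angles: dict[str, np.ndarray] = {}
    axes: dict[str, np.ndarray] = {}
    for joint, (axis, amp, bias) in arch.joint_moves.items():
        phase = rng.uniform(0, 2 * np.pi)
        a = amp * rng.uniform(0.8, 1.2)
        track = bias * env + a * env * np.sin(2 * np.pi * tempo * t + phase)
        if arch.envelope == "tremble":
            track = track + 0.05 * a * np.sin(2 * np.pi * 5.0 * t + phase)
        angles[joint] = track
        axes[joint] = np.asarray(axis, dtype=float)

    # root trajectory in body axes
    root_y = 0.5 * height * 0.95  # SpineBase stands at about mid-height
    sway = arch.sway_amp * np.sin(2 * np.pi * 0.4 * t + rng.uniform(0, 2 * np.pi))
    bounce = arch.bounce_amp * np.clip(np.sin(2 * np.pi * arch.bounce_hz * t), 0, None) \
        if arch.bounce_amp else np.zeros(T)
    drift = arch.drift_w * env * (t / max(dur, 1e-9))
    root_body = np.stack([sway, root_y + bounce, drift], axis=1)

    # root orientation: slight yaw sway
    yaw = np.degrees(0.03 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi)))
    root_R = Rotation.from_euler("Y", yaw[:, None], degrees=True).as_matrix()

    # forward kinematics
    pos = np.empty((T, 25, 3))
    glob_R = {j: np.empty((T, 3, 3)) for j in JOINT_NAMES}
    pos[:, JOINT_INDEX["SpineBase"]] = root_body
    glob_R["SpineBase"] = root_R
    for name in _TOPO:
        parent = PARENT_NAME[name]
        off = np.asarray(_BONE_OFFSETS[name]) * scale
        pR = glob_R[parent]
        pos[:, JOINT_INDEX[name]] = pos[:, JOINT_INDEX[parent]] + np.einsum(
            "tij,j->ti", pR, off
        )
        if name in angles:
            local = Rotation.from_rotvec(
                np.outer(angles[name], axes[name])
            ).as_matrix()
            glob_R[name] = np.einsum("tij,tjk->tik", pR, local)
        else:
            glob_R[name] = pR

    # place in the sensor frame: facing yaw + standing offset from sensor
    face = Rotation.from_euler("Y", rng.uniform(-12, 12), degrees=True).as_matrix()
    offset = np.array([rng.uniform(-0.5, 0.5), 0.0, rng.uniform(2.0, 3.5)])
    pos = pos @ face.T + offset
    sensor_root_R = face @ root_R  # (T,3,3)

    # sensor-style orientations: root rotation + slow small wobble per joint
    ori = np.full((T, 25, 3), np.nan)
    for name in JOINT_NAMES:
        if name in NO_ORIENTATION_JOINTS:
            continue
        wob_ax = rng.normal(size=3)
        wob_ax /= np.linalg.norm(wob_ax)
        wob_ang = np.radians(cfg.orientation_jitter_sd) * np.sin(
            2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi)
        )
        wob = Rotation.from_rotvec(np.outer(wob_ang, wob_ax)).as_matrix()
        R = np.einsum("tij,tjk->tik", sensor_root_R, wob)
        ori[:, JOINT_INDEX[name]] = Rotation.from_matrix(R).as_euler(
            "YXZ", degrees=True
        )

    # positional jitter, larger on the hand joints
    sd = np.full(25, cfg.body_jitter_sd)
    for h in HAND_JOINTS:
        sd[JOINT_INDEX[h]] = cfg.hand_jitter_sd
    pos = pos + rng.normal(size=pos.shape) * sd[None, :, None]

    return MotionSequence(
        positions=pos, orientations=ori, timestamps=t + placement,
        subject=subject_id, emotion=emotion, repetition=rep, space="sensor",
        sequence_id=f"{subject_id}_{emotion}_{rep}",
    )


def generate_corpus(
    config: GeneratorConfig | None = None,
) -> tuple[list[MotionSequence], pd.DataFrame]:
    """Generate the synthetic corpus and its ground-truth manifest.

    Returns ``n_subjects * len(emotions) * n_repetitions`` sensor-space
    sequences and a manifest DataFrame (sequence id, subject, emotion,
    repetition, stature, duration, frame count).  Deterministic given
    ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    corpus: list[MotionSequence] = []
    rows = []
    for si in range(cfg.n_subjects):
        subject_id = f"S{si + 1:02d}"
        height = rng.uniform(*cfg.height_range)
        for emotion in cfg.emotions:
            for rep in range(cfg.n_repetitions):
                seq = _simulate_sequence(
                    subject_id, emotion, rep, height, placement=0.0,
                    cfg=cfg, rng=rng,
                )
                corpus.append(seq)
                rows.append({
                    "sequence_id": seq.sequence_id, "subject": subject_id,
                    "emotion": emotion, "repetition": rep,
                    "height_m": height, "duration_s": seq.duration,
                    "n_frames": seq.n_frames,
                })
    return corpus, pd.DataFrame(rows)


def degrade(
    corpus: list[MotionSequence], drop_rate: float, seed: int = 0
) -> list[MotionSequence]:
    """Simulate tracking failures on a random fraction of recordings.

    Each flagged recording gets one arm frozen at its first-frame pose (the
    classic limb mis-tracking failure) and ``quality_ok=False``.  Returns
    new sequences; the input is untouched.
    """
    if not (0.0 <= drop_rate <= 1.0):
        raise ValueError("drop_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arm_l = ["ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft", "HandTipLeft", "ThumbLeft"]
    arm_r = ["ShoulderRight", "ElbowRight", "WristRight", "HandRight", "HandTipRight", "ThumbRight"]
    out = []
    for seq in corpus:
        if rng.random() < drop_rate:
            bad = seq.copy(quality_ok=False)
            arm = arm_l if rng.random() < 0.5 else arm_r
            idx = [JOINT_INDEX[j] for j in arm]
            bad.positions[:, idx, :] = bad.positions[0, idx, :]
            out.append(bad)
        else:
            out.append(seq.copy())
    return out


def reject_low_quality(
    corpus: list[MotionSequence],
) -> tuple[list[MotionSequence], pd.DataFrame]:
    """Drop recordings whose quality flag is set; returns (kept, manifest).

    The manifest reports kept/removed counts per emotion; kept + removed
    always equals the input size.
    """
    import warnings
    from .skeleton import corpus_manifest

    kept = [s for s in corpus if s.quality_ok]
    if corpus and not kept:
        warnings.warn("all recordings were flagged low-quality", stacklevel=2)
    removed = len(corpus) - len(kept)
    manifest = corpus_manifest(kept)
    manifest.attrs["removed"] = removed
    manifest.attrs["total_input"] = len(corpus)
    return kept, manifest
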