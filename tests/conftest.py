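import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from affmotion import skeleton as sk
from affmotion import synthetic


def base_pose(scale: float = 1.0) -> np.ndarray:
    """A plausible standing rest pose, (25, 3) meters in sensor axes."""
    pos = np.zeros((25, 3))
    pos[sk.JOINT_INDEX["SpineBase"]] = (0.0, 0.85, 2.5)
    for name in synthetic._TOPO:
        parent = synthetic.PARENT_NAME[name]
        off = np.asarray(synthetic._BONE_OFFSETS[name]) * scale
        pos[sk.JOINT_INDEX[name]] = pos[sk.JOINT_INDEX[parent]] + off
    return pos


def make_sequence(
    n_frames=5,
    subject="S01",
    emotion="neutral",
    repetition=0,
    scale=1.0,
    space="sensor",
    move=None,
    root_angles=(0.0, 0.0, 0.0),
    rng=None,
):
    """Deterministic test sequence from the rest pose.

    ``move(t) -> (25, 3) displacement`` optionally animates it; joints with
    reported orientation get the root angles, NO-orientation joints NaN.
    """
    pose = base_pose(scale)
    pos = np.stack([pose.copy() for _ in range(n_frames)])
    if move is not None:
        for t in range(n_frames):
            pos[t] += move(t)
    ori = np.full((n_frames, 25, 3), np.nan)
    for name in sk.JOINT_NAMES:
        if name not in sk.NO_ORIENTATION_JOINTS:
            ori[:, sk.JOINT_INDEX[name], :] = root_angles
    ts = np.arange(n_frames) / 30.0
    return sk.MotionSequence(
        positions=pos, orientations=ori, timestamps=ts,
        subject=subject, emotion=emotion, repetition=repetition, space=space,
    )


def apply_rigid(seq, R: np.ndarray, t: np.ndarray):
    """Apply one rigid motion to a whole sensor-space sequence, rotating
    reported orientations consistently."""
    pos = seq.positions @ R.T + t
    ori = seq.orientations.copy()
    for j in range(25):
        ang = seq.orientations[:, j, :]
        finite = np.all(np.isfinite(ang), axis=1)
        if finite.any():
            Rj = Rotation.from_euler("YXZ", ang[finite], degrees=True).as_matrix()
            ori[finite, j, :] = Rotation.from_matrix(R @ Rj).as_euler("YXZ", degrees=True)
    return seq.copy(positions=pos, orientations=ori)


@pytest.fixture(scope="session")
def small_corpus():
    """4 subjects x 7 emotions x 2 repetitions = 56 recordings."""
    corpus, _ = synthetic.generate_corpus(
        synthetic.GeneratorConfig(n_subjects=4, n_repetitions=2, seed=11)
    )
    return corpus


@pytest.fixture(scope="session")
def default_corpus():
    """The full study-design corpus: 16 x 7 x 5 = 560 recordings."""
    corpus, manifest = synthetic.generate_corpus(synthetic.GeneratorConfig(seed=1))
    return corpus, manifest
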