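"""Coordinate transforms: sensor space -> body-local frame, and per-joint
hierarchical local coordinates.

The body-local frame [u, v, w] is anchored at the SpineBase (root) joint and
oriented by its rotation: u points left, v up, w forward relative to the
root, mirroring the sensor axes (x left, y up, z forward).  Projecting into
it removes the influence of where the subject stood relative to the sensor.

Orientations are triples of angles in degrees.  The angle order is not
fixed by the source data format, so it is a module-level configurable; the
default reads them as intrinsic yaw (about v) - pitch (about u) - roll
(about w).  Any fixed convention preserves the rigid-motion invariance of
the body-local coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .skeleton import MotionSequence, PARENT_INDEX, JOINT_INDEX

__all__ = ["RootDelta", "EULER_ORDER", "to_body_frame", "to_hierarchical_local"]

# Intrinsic yaw(v=Y) - pitch(u=X) - roll(w=Z); scipy's uppercase = intrinsic.
EULER_ORDER = "YXZ"

_ROOT = JOINT_INDEX["SpineBase"]


@dataclass(frozen=True)
class RootDelta:
    """Root-joint motion relative to the first frame.

    ``displacement`` (T, 3), meters, expressed in the first frame's root
    axes; ``rotation_delta`` (T, 3), degrees.  Both are exactly zero in the
    first frame.  Whole-body movements (a hop, a squat) survive body-local
    projection only here.
    """

    displacement: np.ndarray
    rotation_delta: np.ndarray


def _euler_to_matrix(angles_deg: np.ndarray, order: str = EULER_ORDER) -> np.ndarray:
    """(...,3) degree triples -> (...,3,3) rotation matrices."""
    flat = np.asarray(angles_deg, dtype=float).reshape(-1, 3)
    return Rotation.from_euler(order, flat, degrees=True).as_matrix().reshape(
        angles_deg.shape[:-1] + (3, 3)
    )


def _matrix_to_euler(mats: np.ndarray, order: str = EULER_ORDER) -> np.ndarray:
    flat = mats.reshape(-1, 3, 3)
    return Rotation.from_matrix(flat).as_euler(order, degrees=True).reshape(
        mats.shape[:-2] + (3,)
    )


def _root_rotations(seq: MotionSequence, euler_order: str, allow_missing: bool) -> np.ndarray:
    """Per-frame root rotation matrices with the continuity fallback.

    Non-finite root angles in a frame fall back to the previous frame's
    rotation; a bad first frame falls back to identity.
    """
    ang = seq.orientations[:, _ROOT, :]
    finite = np.all(np.isfinite(ang), axis=1)
    if not finite.all() and not allow_missing:
        bad = int(np.flatnonzero(~finite)[0])
        raise ValueError(
            f"missing root (SpineBase) orientation in frame {bad}; "
            "pass allow_missing_root_orientation=True to substitute identity/continuity"
        )
    mats = np.empty((seq.n_frames, 3, 3))
    prev = np.eye(3)
    for t in range(seq.n_frames):
        if finite[t]:
            prev = _euler_to_matrix(ang[t], euler_order)
        mats[t] = prev
    return mats


def to_body_frame(
    seq: MotionSequence,
    euler_order: str = EULER_ORDER,
    relative_orientations: bool = True,
    allow_missing_root_orientation: bool = False,
) -> tuple[MotionSequence, RootDelta]:
    """Project a sensor-space sequence into the body-local [u,v,w] frame.

    In every frame each non-root joint position becomes
    ``R_root^T (p_joint - p_root)`` and (by default) each non-root
    orientation is re-expressed relative to the root rotation.  The root
    channel is replaced by its :class:`RootDelta` against the first frame,
    so the returned sequence still carries whole-body displacement.

    Raises an error if the sequence is not in sensor space (guards against
    double projection).
    """
    if seq.space != "sensor":
        raise ValueError(f"to_body_frame expects space='sensor', got {seq.space!r}")

    R = _root_rotations(seq, euler_order, allow_missing_root_orientation)  # (T,3,3)
    p_root = seq.positions[:, _ROOT, :]  # (T,3)

    rel = seq.positions - p_root[:, None, :]  # (T,25,3)
    # R^T applied per frame: einsum over the 3x3
    local = np.einsum("tji,tkj->tki", R, rel)  # R[t].T @ rel[t,k]

    R0 = R[0]
    disp = (p_root - p_root[0]) @ R0  # R0^T (p_t - p_0), row-vector form
    rot_delta_mats = np.einsum("ji,tjk->tik", R0, R)  # R0^T R_t
    rot_delta = _matrix_to_euler(rot_delta_mats, euler_order)

    out_pos = local.copy()
    out_pos[:, _ROOT, :] = disp

    out_ori = seq.orientations.copy()
    if relative_orientations:
        for j in range(25):
            if j == _ROOT:
                continue
            ang = seq.orientations[:, j, :]
            finite = np.all(np.isfinite(ang), axis=1)
            if finite.any():
                Rj = _euler_to_matrix(ang[finite], euler_order)
                rel_mats = np.einsum("tji,tjk->tik", R[finite], Rj)  # R_root^T R_j
                out_ori[finite, j, :] = _matrix_to_euler(rel_mats, euler_order)
    out_ori[:, _ROOT, :] = rot_delta

    delta = RootDelta(displacement=disp.copy(), rotation_delta=rot_delta.copy())
    return seq.copy(positions=out_pos, orientations=out_ori, space="body_local"), delta


def to_hierarchical_local(seq: MotionSequence, euler_order: str = EULER_ORDER) -> np.ndarray:
    """Per-frame joint positions relative to each joint's parent.

    For every non-root joint the returned vector is the offset from its
    parent joint, rotated into the parent's orientation frame when the
    parent has a reported orientation, else left in the ambient frame.  The
    root maps to its displacement from the first frame.  Returns a
    (T, 25, 3) array in the input's units.
    """
    T = seq.n_frames
    out = np.empty((T, 25, 3))
    pos = seq.positions
    body_local = seq.space in ("body_local", "scale_normalized")

    # Parent positions; in body-local space the root sits at the origin and
    # its position channel holds the RootDelta displacement instead.
    parent_pos = np.empty((T, 25, 3))
    for j in range(25):
        pj = PARENT_INDEX[j]
        if pj < 0:
            continue
        if pj == _ROOT and body_local:
            parent_pos[:, j, :] = 0.0
        else:
            parent_pos[:, j, :] = pos[:, pj, :]

    for j in range(25):
        pj = PARENT_INDEX[j]
        if pj < 0:
            if body_local:
                out[:, j, :] = pos[:, j, :]  # already delta vs frame 1
            else:
                out[:, j, :] = pos[:, j, :] - pos[0, j, :]
            continue
        d = pos[:, j, :] - parent_pos[:, j, :]
        out[:, j, :] = d
        if pj == _ROOT and body_local:
            # body-local positions are already expressed in the per-frame
            # root axes, i.e. in the parent frame of the root's children
            continue
        ang = seq.orientations[:, pj, :]
        finite = np.all(np.isfinite(ang), axis=1)
        if finite.any():
            Rp = _euler_to_matrix(ang[finite], euler_order)
            out[finite, j, :] = np.einsum("tji,tj->ti", Rp, d[finite])  # Rp^T d
    return out
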