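"""Subject-scale normalization, zero padding, and pooled z-scoring.

Taller and shorter subjects trace geometrically similar but differently
sized trajectories.  Each subject's body-local joint vectors are therefore
divided by a personal scale: the median SpineBase-SpineShoulder distance
over all frames of that subject's *neutral* recordings (the two joints
with the lowest positional noise).  Using the neutral recordings keeps
whole-body events in emotional recordings — a joyful hop, a squat —
visible in the root-displacement channel instead of normalizing them away.
Orientations are angles and need no scale correction.

Keyframed recordings have varying lengths; they are zero-padded to the
corpus maximum with a boolean mask marking real rows.  Finally all feature
matrices are z-scored with a single mean/std per feature pooled over the
real (non-padded) rows of every sequence; pad rows stay exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .skeleton import MotionSequence, JOINT_INDEX
from .features import FeatureMatrix

__all__ = [
    "SubjectScale",
    "compute_subject_scale",
    "scale_normalize",
    "pad_sequences",
    "zscore_normalize",
    "SequenceStandardizer",
]

_SB = JOINT_INDEX["SpineBase"]
_SSH = JOINT_INDEX["SpineShoulder"]


@dataclass(frozen=True)
class SubjectScale:
    """Per-subject normalization length in meters (always > 0)."""

    subject: str
    spine_length: float

    def __post_init__(self):
        if not (self.spine_length > 0):
            raise ValueError("spine_length must be positive")


class NoNeutralRecordingsError(ValueError):
    """No neutral recordings available for the subject; the caller must
    supply a fallback scale (e.g. pooled over other subjects)."""


def compute_subject_scale(neutral_seqs: list[MotionSequence]) -> SubjectScale:
    """Median SpineBase-SpineShoulder distance over all neutral frames.

    Expects body-local sequences of a single subject's neutral recordings.
    In body-local coordinates the root sits at the origin, so the distance
    is the norm of the SpineShoulder position (rotation preserves norms).
    """
    if not neutral_seqs:
        raise NoNeutralRecordingsError(
            "no neutral recordings; supply a fallback SubjectScale explicitly"
        )
    subjects = {s.subject for s in neutral_seqs}
    if len(subjects) != 1:
        raise ValueError(f"sequences from multiple subjects: {sorted(subjects)}")
    dists = []
    for s in neutral_seqs:
        if s.space != "body_local":
            raise ValueError(f"expected body_local sequences, got {s.space!r}")
        if s.emotion != "neutral":
            raise ValueError("subject scale is defined over neutral recordings only")
        dists.append(np.linalg.norm(s.positions[:, _SSH, :], axis=1))
    return SubjectScale(subject=subjects.pop(), spine_length=float(np.median(np.concatenate(dists))))


def scale_normalize(seq: MotionSequence, scale: SubjectScale) -> MotionSequence:
    """Divide all body-local joint vectors (and the root displacement) by
    the subject's spine length; orientations are left untouched."""
    if seq.space != "body_local":
        raise ValueError(f"scale_normalize expects space='body_local', got {seq.space!r}")
    return seq.copy(positions=seq.positions / scale.spine_length, space="scale_normalized")


def pad_sequences(mats: list[FeatureMatrix]) -> list[FeatureMatrix]:
    """Zero-pad all feature matrices to the corpus maximum row count.

    Real rows are preserved bit-exactly; each returned matrix carries a
    boolean mask whose True prefix marks the real rows.
    """
    if not mats:
        raise ValueError("empty feature-matrix list")
    widths = {m.values.shape[1] for m in mats}
    if len(widths) != 1:
        raise ValueError(f"inconsistent feature widths: {sorted(widths)}")
    max_len = max(m.n_keyframes for m in mats)
    out = []
    for m in mats:
        k = m.n_keyframes
        values = np.zeros((max_len, m.values.shape[1]))
        values[:k] = m.values
        mask = np.zeros(max_len, dtype=bool)
        mask[:k] = True
        out.append(FeatureMatrix(
            values=values, set_id=m.set_id, subject=m.subject, emotion=m.emotion,
            repetition=m.repetition, sequence_id=m.sequence_id, mask=mask,
        ))
    return out


class SequenceStandardizer(BaseEstimator, TransformerMixin):
    """Pooled per-feature z-scoring over the real rows of padded sequences.

    fit(X, mask): X is (n_sequences, max_len, n_features), mask
    (n_sequences, max_len) boolean.  Mean and standard deviation are
    computed per feature over the union of real rows of all sequences;
    transform standardizes real rows and leaves pad rows exactly zero.
    Zero-variance features are mapped to zero (orientation channels of
    joints without reported orientation are constant by construction).

    Fitting on training folds only and transforming test folds avoids
    normalization leakage in cross-validation; fitting on the whole corpus
    reproduces the single-pass variant.

    Parameters
    ----------
    per_feature : if False, a single scalar mean/std pooled over all
        features is used instead.
    """

    def __init__(self, per_feature: bool = True):
        self.per_feature = per_feature

    def fit(self, X, y=None, mask=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_sequences, max_len, n_features)")
        if mask is None:
            mask = np.ones(X.shape[:2], dtype=bool)
        rows = X[np.asarray(mask, dtype=bool)]  # (n_real_rows, F)
        if rows.size == 0:
            raise ValueError("no real rows to fit on")
        if self.per_feature:
            self.mean_ = rows.mean(axis=0)
            self.std_ = rows.std(axis=0)
        else:
            self.mean_ = np.full(X.shape[2], rows.mean())
            self.std_ = np.full(X.shape[2], rows.std())
        # relative tolerance: a constant column's std is rounding noise
        self.zero_variance_ = self.std_ <= 1e-12 * np.maximum(1.0, np.abs(self.mean_))
        if np.any(self.zero_variance_):
            warnings.warn(
                f"{int(self.zero_variance_.sum())} zero-variance feature(s) "
                "standardized to 0",
                stacklevel=2,
            )
        self.n_features_in_ = X.shape[2]
        return self

    def transform(self, X, mask=None):
        X = np.asarray(X, dtype=float)
        if mask is None:
            mask = np.ones(X.shape[:2], dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        safe_std = np.where(self.zero_variance_, 1.0, self.std_)
        out = (X - self.mean_) / safe_std
        out[:, :, self.zero_variance_] = 0.0
        out[~mask] = 0.0
        return out

    def fit_transform(self, X, y=None, mask=None):
        return self.fit(X, mask=mask).transform(X, mask=mask)


def zscore_normalize(mats: list[FeatureMatrix], per_feature: bool = True) -> list[FeatureMatrix]:
    """Z-score a padded dataset in place of the array contents.

    Thin wrapper over :class:`SequenceStandardizer` fit on the real rows of
    all given matrices.  Returns new :class:`FeatureMatrix` objects.
    """
    if not mats:
        raise ValueError("empty feature-matrix list")
    if any(m.mask is None for m in mats):
        raise ValueError("matrices must be padded (carry masks) before z-scoring")
    X = np.stack([m.values for m in mats])
    mask = np.stack([m.mask for m in mats])
    Z = SequenceStandardizer(per_feature=per_feature).fit_transform(X, mask=mask)
    return [
        FeatureMatrix(
            values=Z[i], set_id=m.set_id, subject=m.subject, emotion=m.emotion,
            repetition=m.repetition, sequence_id=m.sequence_id, mask=m.mask.copy(),
        )
        for i, m in enumerate(mats)
    ]
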