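"""End-to-end dataset assembly: raw corpus -> padded feature tensors.

Order of operations: sensor-space sequences are projected into the
body-local frame; keyframes are extracted from the body-local trajectories
(the error rate is in meters, so this happens before subject-scale
division); each subject's scale comes from their neutral body-local
recordings; sequences are scale-normalized, composed into feature
matrices at the keyframes, zero-padded to the corpus maximum, and
optionally z-scored with pooled statistics.

When preparing data for cross-validation, leave ``zscore=False`` and let
:func:`affmotion.models.subject_grouped_cv` fit the standardizer on the
training subjects of each fold.
"""

from __future__ import annotations

import numpy as np

from . import coords, keyframes as kf, normalize as nz, features as ft
from .skeleton import MotionSequence

__all__ = ["preprocess_corpus", "prepare_dataset", "save_dataset", "load_dataset"]


def preprocess_corpus(corpus: list[MotionSequence]) -> list[MotionSequence]:
    """Project every sensor-space sequence into the body-local frame."""
    return [coords.to_body_frame(s)[0] for s in corpus]


def prepare_dataset(
    corpus: list[MotionSequence],
    set_id: str = "P",
    error_rate: float = kf.DEFAULT_ERROR_RATE,
    keyframe: bool = True,
    zscore: bool = True,
    fallback_scale: float | None = None,
) -> dict:
    """Run the full preprocessing chain on a sensor-space corpus.

    Returns a dict with ``X`` (n, max_len, n_features), boolean ``mask``,
    ``labels``, ``subjects``, ``sequence_ids`` and ``feature_names``.
    ``keyframe=False`` keeps every frame (the un-keyframed variant).
    Subjects with no neutral recordings need ``fallback_scale`` (meters).
    """
    body = preprocess_corpus(corpus)

    scales: dict[str, nz.SubjectScale] = {}
    for subj in sorted({s.subject for s in body}):
        neutral = [s for s in body if s.subject == subj and s.emotion == "neutral"]
        if neutral:
            scales[subj] = nz.compute_subject_scale(neutral)
        elif fallback_scale is not None:
            scales[subj] = nz.SubjectScale(subj, fallback_scale)
        else:
            raise nz.NoNeutralRecordingsError(
                f"subject {subj!r} has no neutral recordings; pass fallback_scale"
            )

    mats = []
    for seq in body:
        keys = kf.extract_keyframes(seq, error_rate=error_rate) if keyframe else None
        normed = nz.scale_normalize(seq, scales[seq.subject])
        mats.append(ft.compose_features(normed, set_id, keyframes=keys))
    mats = nz.pad_sequences(mats)
    if zscore:
        mats = nz.zscore_normalize(mats)

    return {
        "X": np.stack([m.values for m in mats]),
        "mask": np.stack([m.mask for m in mats]),
        "labels": np.array([m.emotion for m in mats]),
        "subjects": np.array([m.subject for m in mats]),
        "sequence_ids": np.array([m.sequence_id for m in mats]),
        "feature_names": ft.feature_names(set_id),
        "set_id": set_id,
        "error_rate": error_rate,
    }


def save_dataset(ds: dict, path) -> None:
    """Cache a prepared dataset in HDF5 (datasets ``features``, ``mask``,
    ``labels``, ``subjects``)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("features", data=ds["X"])
        fh.create_dataset("mask", data=ds["mask"])
        str_dt = h5py.string_dtype()
        fh.create_dataset("labels", data=np.asarray(ds["labels"], dtype=object), dtype=str_dt)
        fh.create_dataset("subjects", data=np.asarray(ds["subjects"], dtype=object), dtype=str_dt)
        fh.create_dataset("sequence_ids", data=np.asarray(ds["sequence_ids"], dtype=object), dtype=str_dt)
        fh.attrs["set_id"] = ds["set_id"]
        fh.attrs["error_rate"] = ds["error_rate"]
        fh.attrs["feature_names"] = [str(n) for n in ds["feature_names"]]


def load_dataset(path) -> dict:
    """Load a dataset cached by :func:`save_dataset`."""
    import h5py

    with h5py.File(path, "r") as fh:
        return {
            "X": fh["features"][...],
            "mask": fh["mask"][...].astype(bool),
            "labels": fh["labels"].asstr()[...],
            "subjects": fh["subjects"].asstr()[...],
            "sequence_ids": fh["sequence_ids"].asstr()[...],
            "feature_names": list(fh.attrs["feature_names"]),
            "set_id": str(fh.attrs["set_id"]),
            "error_rate": float(fh.attrs["error_rate"]),
        }
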