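"""Feature composition widths, quantity of motion, and baseline features."""

import numpy as np
import pandas as pd
import pytest

from affmotion import coords, features as ft, normalize as nz
from affmotion import skeleton as sk
from affmotion.keyframes import extract_keyframes
from conftest import make_sequence


def _normalized(seq=None, **kw):
    seq = seq if seq is not None else make_sequence(6, **kw)
    body, _ = coords.to_body_frame(seq)
    scale = np.median(np.linalg.norm(body.positions[:, 20], axis=1))
    return nz.scale_normalize(body, nz.SubjectScale(seq.subject, float(scale)))


class TestComposeFeatures:
    @pytest.mark.parametrize("set_id,width", sorted(ft.EXPECTED_FEATURE_COUNTS.items()))
    def test_canonical_widths(self, set_id, width):
        mat = ft.compose_features(_normalized(), set_id)
        assert mat.values.shape[1] == width
        assert len(ft.feature_names(set_id)) == width

    def test_width_identity_structure(self):
        # each family is 3 (or 6) channels per joint plus one shared channel
        c = ft.EXPECTED_FEATURE_COUNTS
        assert c["P"] == 3 * 19 + 1 and c["PU"] == 3 * 11 + 1
        assert c["PO"] == c["P"] + c["O"] - 1
        assert c["POU"] == c["PU"] + c["OU"] - 1

    def test_keyframe_selection_and_time_channel(self):
        seq = _normalized(make_sequence(11))
        keys = extract_keyframes(seq, 1e6)  # endpoints only
        mat = ft.compose_features(seq, "P", keyframes=keys)
        assert mat.values.shape[0] == 2
        np.testing.assert_allclose(mat.values[:, -1], [0.0, 1.0])
        full = ft.compose_features(seq, "P")
        assert full.values.shape[0] == 11
        assert np.all(np.diff(full.values[:, -1]) > 0)

    def test_orientation_channels_zero_filled_for_unreported_joints(self):
        mat = ft.compose_features(_normalized(), "O")
        names = ft.feature_names("O")
        head_cols = [i for i, n in enumerate(names) if n.startswith("Head_")]
        np.testing.assert_array_equal(mat.values[:, head_cols], 0.0)

    def test_no_time_channel_variant_warns_and_shrinks(self):
        with pytest.warns(UserWarning, match="canonical width"):
            mat = ft.compose_features(_normalized(), "P", time_channel=False)
        assert mat.values.shape[1] == 57
        assert mat.set_id == "P-"

    def test_rejects_unknown_set_and_wrong_space(self):
        with pytest.raises(ValueError, match="unknown feature set"):
            ft.compose_features(_normalized(), "PX")
        body, _ = coords.to_body_frame(make_sequence(4))
        with pytest.raises(ValueError, match="scale_normalized"):
            ft.compose_features(body, "P")


class TestQuantityOfMotion:
    def test_stationary_corpus_scores_zero(self):
        corpus = [make_sequence(5, emotion=e) for e in sk.EMOTIONS]
        table = ft.quantity_of_motion(corpus)
        np.testing.assert_allclose(table.to_numpy(), 0, atol=1e-12)

    def test_constant_step_joint_scores_its_step_length(self):
        step = 0.01
        wrist = sk.JOINT_INDEX["WristLeft"]

        def move(t):
            d = np.zeros((25, 3))
            d[wrist] = (0.0, step * t, 0.0)
            return d

        corpus = [make_sequence(8, emotion=e, move=move) for e in sk.EMOTIONS]
        table = ft.quantity_of_motion(corpus)
        # wrist's parent (elbow) has identity orientation and never moves
        assert table.loc["WristLeft", "anger"] == pytest.approx(step, abs=1e-12)

    def test_matches_brute_force_double_loop(self, small_corpus):
        corpus = small_corpus[:20]
        table = ft.quantity_of_motion(corpus)
        sums = {e: np.zeros(25) for e in sk.EMOTIONS}
        counts = {e: 0 for e in sk.EMOTIONS}
        for seq in corpus:
            local = coords.to_hierarchical_local(seq)
            acc = np.zeros(25)
            for f in range(1, seq.n_frames):
                for j in range(25):
                    acc[j] += np.linalg.norm(local[f, j] - local[f - 1, j])
            sums[seq.emotion] += acc / (seq.n_frames - 1)
            counts[seq.emotion] += 1
        for e in sk.EMOTIONS:
            if counts[e]:
                np.testing.assert_allclose(
                    table[e].to_numpy(), sums[e] / counts[e], atol=1e-12
                )
            else:
                assert table[e].isna().all()

    def test_translation_invariant_and_nonnegative(self, small_corpus):
        corpus = small_corpus[:7]
        t1 = ft.quantity_of_motion(corpus)
        shifted = [s.copy(positions=s.positions + np.array([2.0, 0.5, -1.0]))
                   for s in corpus]
        t2 = ft.quantity_of_motion(shifted)
        np.testing.assert_allclose(t2.to_numpy(), t1.to_numpy(), atol=1e-9)
        assert (t1.fillna(0).to_numpy() >= 0).all()

    def test_wrists_dominate_torso_for_emotional_states(self, small_corpus):
        table = ft.quantity_of_motion(small_corpus)
        for emo in ("anger", "fear", "happiness", "surprise"):
            wrists = table.loc[["WristLeft", "WristRight"], emo].mean()
            torso = table.loc[["SpineMid", "SpineShoulder"], emo].mean()
            assert wrists > 2 * torso
            assert table.loc[["KneeLeft", "KneeRight", "AnkleLeft", "AnkleRight"], emo].min() > 0

    def test_per_frame_normalization_variant(self):
        corpus = [make_sequence(5, emotion="anger")]
        a = ft.quantity_of_motion(corpus, per_transition=True)
        b = ft.quantity_of_motion(corpus, per_transition=False)
        # stationary: both zero; relationship checked on a moving joint
        def move(t):
            d = np.zeros((25, 3))
            d[6] = (0.01 * t, 0, 0)
            return d
        corpus = [make_sequence(5, emotion="anger", move=move)]
        a = ft.quantity_of_motion(corpus, per_transition=True)
        b = ft.quantity_of_motion(corpus, per_transition=False)
        assert a.loc["WristLeft", "anger"] == pytest.approx(
            b.loc["WristLeft", "anger"] * 5 / 4
        )


class TestHeatmap:
    def test_variants_and_row_counts(self):
        table = pd.DataFrame(
            np.zeros((25, 7)), index=sk.JOINT_NAMES, columns=sk.EMOTIONS
        )
        ax_all = ft.qom_heatmap(table)
        ax_nh = ft.qom_heatmap(table, exclude_hands=True)
        assert len(ax_all.get_yticklabels()) == 25
        assert len(ax_nh.get_yticklabels()) == 19
        import matplotlib.pyplot as plt
        plt.close("all")


class TestBaselineFeatures:
    def test_stationary_sequence_zeroes_kinematics(self):
        v = ft.extract_baseline_features(_normalized(make_sequence(6)))
        # rotation round-trips leave only float noise
        assert v["velocity_mean"] == pytest.approx(0, abs=1e-9)
        assert v["velocity_max"] == pytest.approx(0, abs=1e-9)
        assert v["acceleration_mean"] == pytest.approx(0, abs=1e-6)
        assert v["kinetic_energy"] == pytest.approx(0, abs=1e-12)
        assert v["jerk_mean"] == pytest.approx(0, abs=1e-4)
        assert v["bbox_volume_mean"] == pytest.approx(v["bbox_volume_max"])
        assert v["bbox_volume_mean"] > 0

    def test_uniform_drift_matches_closed_form(self):
        speed_mps = 0.3
        wrist = sk.JOINT_INDEX["WristLeft"]

        def move(t):
            d = np.zeros((25, 3))
            d[wrist] = (speed_mps * t / 30.0, 0.0, 0.0)
            return d

        seq = make_sequence(10, move=move, space="sensor")
        seq = seq.copy(space="scale_normalized")  # unit-scale shortcut
        v = ft.extract_baseline_features(seq)
        # one joint of 25 moves at constant speed
        assert v["velocity_mean"] == pytest.approx(speed_mps / 25, rel=1e-9)
        assert v["velocity_max"] == pytest.approx(speed_mps, rel=1e-9)
        assert v["acceleration_mean"] == pytest.approx(0, abs=1e-9)

    def test_kinetic_energy_homogeneity(self):
        rng = np.random.default_rng(0)
        disp = rng.normal(0, 0.05, (8, 25, 3))
        s1 = make_sequence(8, move=lambda t: disp[t]).copy(space="scale_normalized")
        s2 = s1.copy(positions=2.0 * s1.positions)
        v1 = ft.extract_baseline_features(s1)
        v2 = ft.extract_baseline_features(s2)
        assert v2["kinetic_energy"] == pytest.approx(4 * v1["kinetic_energy"], rel=1e-9)

    def test_too_short_sequence_rejected(self):
        seq = make_sequence(2).copy(space="scale_normalized")
        with pytest.raises(ValueError, match="3 frames"):
            ft.extract_baseline_features(seq)

    def test_vector_is_finite_and_fixed_length(self, small_corpus):
        v = ft.extract_baseline_features(_normalized(small_corpus[5]))
        assert list(v.index) == ft.BASELINE_FEATURE_NAMES
        assert np.isfinite(v.to_numpy()).all()
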