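import numpy as np
import pytest

from hjdpose.features import (JOINT_SETS, FrameError, FusionError,
                              SphericalBinning, Window, WindowSpec, assign_bin,
                              bin_indices, body_frame, body_frames,
                              center_on_pelvis, compute_hjd, displacement_rate,
                              extract_dataset, from_spherical, fuse,
                              make_windows, to_spherical)
from hjdpose.io import KeypointSchema, MocapRecording, StageAnnotation

from conftest import random_recording


def posed_recording(n_frames=5):
    """Recording with hips on x, head on +y: body frame == world axes."""
    schema = KeypointSchema()
    pos = np.zeros((n_frames, 12, 3))
    rest = {
        "Head": (0, 300, 0), "CenterPelvis": (0, 0, 0),
        "LHip": (-40, 0, 0), "RHip": (40, 0, 0),
        "LShoulder": (-70, 250, 20), "RShoulder": (70, 250, 20),
        "LHand": (-110, 150, 40), "RHand": (110, 150, 40),
        "LKnee": (-60, -90, 50), "RKnee": (60, -90, 50),
        "LFoot": (-70, -180, 40), "RFoot": (70, -180, 40),
    }
    for k, name in enumerate(schema.names):
        pos[:, k, :] = rest[name]
    return MocapRecording("P", pos, 100.0, 0.0, schema)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rigid_apply(rec, R, T):
    return MocapRecording(rec.subject_id, rec.positions @ R.T + T,
                          rec.sample_rate, rec.start_time, rec.schema)


class TestGeometry:
    def test_center_on_pelvis_zero_at_root(self):
        rec = posed_recording()
        disp = center_on_pelvis(rec)
        assert np.all(disp[:, rec.schema.index("CenterPelvis"), :] == 0)

    def test_translation_invariance(self, rng):
        rec = random_recording(rng)
        shifted = rigid_apply(rec, np.eye(3), np.array([100.0, -50.0, 30.0]))
        np.testing.assert_allclose(center_on_pelvis(rec), center_on_pelvis(shifted),
                                   atol=1e-9)

    def test_matches_elementwise_subtraction(self, rng):
        rec = random_recording(rng)
        disp = center_on_pelvis(rec)
        root = rec.joint("CenterPelvis")
        for k in range(12):
            np.testing.assert_array_equal(disp[:, k], rec.positions[:, k] - root)

    def test_canonical_posture_gives_identity_frame(self):
        frame = body_frame(posed_recording(), 0)
        np.testing.assert_allclose(frame.e_lat, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.e_long, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(frame.e_up, [0, 0, 1], atol=1e-12)

    def test_frame_equivariant_under_rotation(self, rng):
        rec = posed_recording()
        R = random_rotation(rng)
        rot = rigid_apply(rec, R, np.zeros(3))
        f0, f1 = body_frame(rec, 0), body_frame(rot, 0)
        for a, b in ((f0.e_lat, f1.e_lat), (f0.e_long, f1.e_long), (f0.e_up, f1.e_up)):
            np.testing.assert_allclose(R @ a, b, atol=1e-9)

    def test_frame_matches_gram_schmidt_oracle(self, rng):
        for _ in range(10):
            rec = random_recording(rng, n_frames=1)
            try:
                f = body_frame(rec, 0)
            except FrameError:
                continue
            lhip, rhip = rec.joint("LHip")[0], rec.joint("RHip")[0]
            head, pelv = rec.joint("Head")[0], rec.joint("CenterPelvis")[0]
            e1 = (rhip - lhip) / np.linalg.norm(rhip - lhip)
            v = head - pelv
            v = v - (v @ e1) * e1
            e2 = v / np.linalg.norm(v)
            e3 = np.cross(e1, e2)
            np.testing.assert_allclose(f.e_lat, e1, atol=1e-9)
            np.testing.assert_allclose(f.e_long, e2, atol=1e-9)
            np.testing.assert_allclose(f.e_up, e3, atol=1e-9)
            # orthonormal right-handed
            M = f.rotation()
            np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(M) > 0

    def test_degenerate_geometry_rejected(self):
        rec = posed_recording()
        rec.positions[:, rec.schema.index("Head")] = [500, 0, 0]  # on hip axis
        with pytest.raises(FrameError):
            body_frame(rec, 0)

    def test_spherical_axes(self):
        frame = body_frame(posed_recording(), 0)
        a, t, r = to_spherical(np.array([2.0, 0, 0]), frame)  # along e_lat
        assert (a, t, r) == (0.0, 0.0, 2.0)
        a, t, r = to_spherical(np.array([0, 0, 3.0]), frame)  # along e_up
        assert t == pytest.approx(np.pi / 2)

    def test_spherical_round_trip(self, rng):
        frame = body_frame(posed_recording(), 0)
        for _ in range(50):
            v = rng.normal(size=3) * 100
            a, t, r = to_spherical(v, frame)
            assert -np.pi <= a < np.pi and -np.pi / 2 <= t <= np.pi / 2
            np.testing.assert_allclose(from_spherical(a, t, r, frame), v, atol=1e-9)


class TestBinning:
    def test_forward_direction_is_bin_36(self):
        assert assign_bin(0.0, 0.0, SphericalBinning(8, 8)) == 36

    def test_top_edge_clamped(self):
        s = SphericalBinning(8, 8)
        assert assign_bin(0.0, np.pi / 2, s) // 8 == 7

    def test_partition_and_solid_angles(self, rng):
        s = SphericalBinning(8, 8)
        n = 100_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        alpha = np.arctan2(v[:, 1], v[:, 0])
        alpha = np.where(alpha >= np.pi, -np.pi, alpha)
        theta = np.arcsin(np.clip(v[:, 2], -1, 1))
        idx = assign_bin(alpha, theta, s)
        assert idx.min() >= 0 and idx.max() < 64
        counts = np.bincount(idx, minlength=64)
        assert counts.sum() == n  # exactly one bin per direction
        # closed-form solid angle of band x sector over the full sphere
        el_edges = -np.pi / 2 + np.pi / 8 * np.arange(9)
        for b in range(64):
            el = b // 8
            frac = (np.sin(el_edges[el + 1]) - np.sin(el_edges[el])) / 2 / 8
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(counts[b] / n - frac) <= 3 * se + 1e-12


class TestHJD:
    def test_stationary_joint_single_bin(self):
        rec = posed_recording(n_frames=100)
        h = compute_hjd(rec, "LFoot", (0.0, 1.0))
        assert h.hist.max() == 1.0
        assert h.hist.sum() == 1.0

    def test_two_direction_alternation(self):
        rec = posed_recording(n_frames=100)
        k = rec.schema.index("RHand")
        rec.positions[1::2, k] = [0, 0, 200.0]  # straight up on odd frames
        h = compute_hjd(rec, "RHand", (0.0, 1.0))
        assert sorted(h.hist[h.hist > 0]) == [0.5, 0.5]

    def test_matches_per_frame_counting_oracle(self, short_subject):
        rec, _ = short_subject
        scheme = SphericalBinning()
        window = (7.0, 5.0)
        for joint in ("LFoot", "RHand"):
            h = compute_hjd(rec, joint, window, scheme)
            counts = np.zeros(64)
            for f in range(700, 1200):
                frame = body_frame(rec, f)
                d = rec.joint(joint)[f] - rec.joint("CenterPelvis")[f]
                a, t, _ = to_spherical(d, frame)
                counts[assign_bin(a, t, scheme)] += 1
            np.testing.assert_allclose(h.hist, counts / counts.sum(), atol=1e-12)

    def test_normalization_and_invariances(self, short_subject, rng):
        rec, _ = short_subject
        scheme = SphericalBinning()
        R, T = random_rotation(rng), rng.uniform(-300, 300, 3)
        moved = rigid_apply(rec, R, T)
        scaled = MocapRecording(rec.subject_id, rec.positions * 2.0,
                                rec.sample_rate, rec.start_time, rec.schema)
        bins0 = bin_indices(rec, scheme)
        for joint in ("LFoot", "LHand", "RKnee"):
            for start in (0.0, 33.0, 71.0):
                h0 = compute_hjd(rec, joint, (start, 5.0), scheme, _bins=bins0)
                assert abs(h0.hist.sum() - 1.0) <= 1e-12
                h1 = compute_hjd(moved, joint, (start, 5.0), scheme)
                h2 = compute_hjd(scaled, joint, (start, 5.0), scheme)
                assert np.abs(h0.hist - h1.hist).max() <= 1e-9
                assert np.abs(h0.hist - h2.hist).max() <= 1e-9


class TestFusion:
    def _hjds(self, rec, joints, window=(0.0, 1.0)):
        return [compute_hjd(rec, j, window) for j in joints]

    def test_feet_shapes(self):
        rec = posed_recording(n_frames=110)
        f = fuse(self._hjds(rec, JOINT_SETS["Feet"]), "Feet")
        assert f.vector_1d.shape == (128,)
        assert f.matrix_2d.shape == (2, 64)

    def test_fullbody_shapes(self):
        rec = posed_recording(n_frames=110)
        f = fuse(self._hjds(rec, JOINT_SETS["FullBody"]), "FullBody")
        assert f.vector_1d.shape == (384,)
        assert f.matrix_2d.shape == (6, 64)
        assert f.vector_1d.sum() == pytest.approx(6.0, abs=1e-11)

    def test_wrong_order_rejected(self):
        rec = posed_recording(n_frames=110)
        hjds = self._hjds(rec, ("RFoot", "LFoot"))
        with pytest.raises(FusionError):
            fuse(hjds, "Feet")

    def test_mismatched_windows_rejected(self):
        rec = posed_recording(n_frames=210)
        hjds = [compute_hjd(rec, "LFoot", (0.0, 1.0)),
                compute_hjd(rec, "RFoot", (1.0, 1.0))]
        with pytest.raises(FusionError):
            fuse(hjds, "Feet")


class TestWindows:
    def test_18s_stage_gives_4_windows(self):
        rec = posed_recording(n_frames=1800)
        ann = StageAnnotation(((0.0, 18.0, "B1"),))
        ws = make_windows(rec, ann, WindowSpec(5.0, 4.0))
        labelled = [w for w in ws if w.label is not None]
        assert [w.start for w in labelled] == [0.0, 4.0, 8.0, 12.0]

    def test_boundary_straddlers_dropped(self):
        rec = posed_recording(n_frames=1200)
        ann = StageAnnotation(((0.0, 6.0, "B1"), (6.0, 12.0, "B2")))
        ws = make_windows(rec, ann, WindowSpec(5.0, 4.0))
        for w in ws:
            if w.label is not None:
                s, e, _ = ann.intervals[w.label]
                assert s <= w.start and w.start + w.width <= e + 1e-9

    def test_counts_match_closed_form(self, short_subject):
        rec, ann = short_subject
        spec = WindowSpec(5.0, 4.0)
        ws = [w for w in make_windows(rec, ann, spec) if w.label is not None]
        import math
        expected = sum(
            math.floor((e - s - spec.width) / spec.stride) + 1 for s, e, _ in ann.intervals
        )
        assert len(ws) == expected

    def test_uncovered_span_yields_unlabelled(self):
        rec = posed_recording(n_frames=2000)
        ann = StageAnnotation(((10.0, 20.0, "B1"),))
        ws = make_windows(rec, ann, WindowSpec(5.0, 5.0))
        assert any(w.label is None for w in ws)
        assert any(w.label == 0 for w in ws)


class TestDisplacementRate:
    def test_steady_1mm_per_frame_is_6_m_per_min(self):
        pos = np.zeros((200, 12, 3))
        pos[:, 10, 0] = np.arange(200)  # LFoot moves 1 mm per frame
        rec = MocapRecording("S", pos, 100.0)
        assert displacement_rate(rec, "LFoot", (0.0, 2.0)) == pytest.approx(6.0)

    def test_stationary_joint_zero(self):
        rec = posed_recording(n_frames=300)
        assert displacement_rate(rec, "RHand", (0.0, 3.0)) == 0.0

    def test_random_walk_matches_direct_summation(self, rng):
        pos = np.cumsum(rng.normal(size=(300, 12, 3)), axis=0)
        rec = MocapRecording("S", pos, 100.0)
        got = displacement_rate(rec, "Head", (0.5, 2.5))
        traj = pos[50:250, 0]
        total = sum(
            float(np.linalg.norm(traj[i + 1] - traj[i])) for i in range(len(traj) - 1)
        )
        assert got == pytest.approx(total / (199 / 100.0) * 60 / 1000)


def test_extract_dataset_shapes(short_subject):
    rec, ann = short_subject
    X, y, starts = extract_dataset(rec, ann, JOINT_SETS["Feet"])
    assert X.shape[1:] == (2, 64)
    assert len(X) == len(y) == len(starts)
    assert set(np.unique(y)) == {0, 1, 2, 3, 4}
    np.testing.assert_allclose(X.sum(axis=2), 1.0, atol=1e-12)
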