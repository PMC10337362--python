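import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmtrace import (
    dtw_distance,
    extract_keypoints,
    fast_dtw_distance,
    gaussian_smooth,
    load_templates,
    pairwise_dtwd,
    save_templates,
    select_template,
    template_features,
    temporal_restructure,
    vq_cluster,
)
from tmtrace.template import KeyPointSequence, RawCluster, TemplateSet

from .conftest import line_traj, make_traj
from .oracles import dtw_enumerate, gaussian_convolve, two_means_brute

points = st.lists(
    st.tuples(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        st.floats(min_value=-100, max_value=100, allow_nan=False),
    ),
    min_size=1,
    max_size=6,
)


class TestDtwDistance:
    def test_identical_sequences_are_zero(self):
        a = [(0, 0), (1, 2), (3, 4)]
        assert dtw_distance(a, a) == 0.0

    def test_single_points(self):
        assert dtw_distance([(0, 0)], [(3, 4)]) == 5.0

    def test_worked_three_vs_two(self):
        assert dtw_distance([(0, 0), (1, 0), (2, 0)], [(0, 0), (2, 0)]) == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(points, points)
    def test_matches_exhaustive_enumeration(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(dtw_enumerate(a, b), abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(points, points)
    def test_symmetry_and_nonnegativity(self, a, b):
        d = dtw_distance(a, b)
        assert d >= 0
        assert d == pytest.approx(dtw_distance(b, a), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance(np.empty((0, 2)), [(0, 0)])


class TestFastDtw:
    def test_identical_sequences_any_radius(self):
        a = np.random.default_rng(0).normal(size=(30, 2))
        for r in (1, 3, 10):
            assert fast_dtw_distance(a, a, radius=r) == 0.0

    def test_exact_when_radius_covers_matrix(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=(rng.integers(5, 40), 2))
            b = rng.normal(size=(rng.integers(5, 40), 2))
            r = max(len(a), len(b))
            assert fast_dtw_distance(a, b, radius=r) == pytest.approx(
                dtw_distance(a, b), abs=1e-9
            )

    def test_close_to_exact_at_small_radius(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=(100, 2)).cumsum(axis=0)
            b = rng.normal(size=(100, 2)).cumsum(axis=0)
            e = dtw_distance(a, b)
            f = fast_dtw_distance(a, b, radius=10)
            assert f >= e - 1e-9  # windowed optimum cannot beat the true one
            assert f <= 1.05 * e

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            fast_dtw_distance([(0, 0)], [(1, 1)], radius=0)


class TestPairwise:
    def test_identical_pair_gives_zero_matrix(self):
        a = [(0, 0), (1, 1)]
        D = pairwise_dtwd([a, a], method="exact")
        assert np.all(D == 0)

    def test_consistent_with_scalar_calls_and_symmetric(self):
        rng = np.random.default_rng(3)
        seqs = [rng.normal(size=(rng.integers(3, 8), 2)) for _ in range(4)]
        D = pairwise_dtwd(seqs, method="exact")
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
        for i in range(4):
            for j in range(4):
                assert D[i, j] == pytest.approx(
                    dtw_distance(seqs[i], seqs[j]), abs=1e-9
                )


class TestSelectTemplate:
    def test_pool_of_one(self):
        tr = line_traj(subject_id="only")
        assert select_template([tr], seed=0) is tr

    def test_middle_translation_wins(self):
        trs = [
            line_traj(offset=(0, off), subject_id=f"s{off}")
            for off in (0.0, 1.0, 10.0)
        ]
        chosen = select_template(trs, subset_size=3, seed=0, method="exact")
        assert chosen.subject_id == "s1.0"

    def test_tie_breaks_to_lowest_subject_id(self):
        trs = [
            line_traj(subject_id="b"),
            line_traj(subject_id="a"),
            line_traj(offset=(0, 500), subject_id="z"),
        ]
        chosen = select_template(trs, subset_size=3, seed=0, method="exact")
        assert chosen.subject_id == "a"

    def test_invariant_to_pool_order(self):
        rng = np.random.default_rng(4)
        trs = [
            line_traj(offset=(0, float(rng.uniform(0, 50))), subject_id=f"s{i}")
            for i in range(7)
        ]
        a = select_template(trs, subset_size=5, seed=9, method="exact")
        b = select_template(trs[::-1], subset_size=5, seed=9, method="exact")
        assert a.subject_id == b.subject_id

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_template([], seed=0)


class TestGaussianSmooth:
    def test_sigma_zero_is_identity(self):
        traj = line_traj()
        assert gaussian_smooth(traj, 0.0) is traj

    def test_constant_path_unchanged(self):
        traj = make_traj([5] * 20, [7] * 20, [1] * 20, range(20))
        sm = gaussian_smooth(traj, 2.0)
        assert np.allclose(sm.x, 5) and np.allclose(sm.y, 7)

    def test_step_matches_convolution_oracle(self):
        x = np.array([0.0] * 15 + [100.0] * 15)
        traj = make_traj(x, x[::-1], [1] * 30, range(30))
        sm = gaussian_smooth(traj, 2.0)
        assert np.allclose(sm.x, gaussian_convolve(x, 2.0), atol=1e-9)
        assert np.allclose(sm.y, gaussian_convolve(x[::-1], 2.0), atol=1e-9)

    def test_pressure_and_time_untouched(self):
        traj = line_traj()
        sm = gaussian_smooth(traj, 3.0)
        assert np.array_equal(sm.pressure, traj.pressure)
        assert np.array_equal(sm.t, traj.t)


class TestVqCluster:
    def test_k1_gives_centroid(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 6.0]])
        (c,) = vq_cluster(pts, [0, 1, 2], k=1, seed=0)
        assert c.center == pytest.approx((2.0, 2.0))

    def test_k_equals_n_gives_points(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        clusters = vq_cluster(pts, [0, 1, 2], k=3, seed=0)
        centers = sorted(c.center for c in clusters)
        assert centers == sorted(map(tuple, pts))

    def test_k_capped_at_distinct_points(self):
        pts = np.array([[1.0, 1.0]] * 5)
        clusters = vq_cluster(pts, range(5), k=40, seed=0)
        assert len(clusters) == 1 and clusters[0].n_points == 5

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(7)
        blob1 = rng.normal([1000, 1000], 10, size=(40, 2))
        blob2 = rng.normal([3000, 1000], 10, size=(40, 2))
        pts = np.vstack([blob1, blob2])
        clusters = vq_cluster(pts, np.arange(80), k=2, seed=0)
        got = np.array(sorted(c.center for c in clusters))
        expected = two_means_brute(pts)
        assert np.linalg.norm(got - expected, axis=1).max() < 3.0


class TestTemporalRestructure:
    def test_consistent_clusters_unchanged(self):
        c1 = RawCluster(np.array([0.0, 2.0]), np.array([0.0, 0.0]),
                        np.array([0.0, 1.0]))
        c2 = RawCluster(np.array([10.0, 12.0]), np.array([0.0, 0.0]),
                        np.array([2.0, 3.0]))
        kps = temporal_restructure([c1, c2])
        assert list(kps.cx) == [1.0, 11.0]
        assert list(kps.n_points) == [2, 2]
        assert kps.weight.sum() == 1.0

    def test_stray_point_removed_worked_example(self):
        """Two clusters at mean times 1.0 and 3.0; the second contains a
        stray point at t=0.5 (earlier than cluster 1's mean), which the rule
        removes before the center is re-averaged."""
        c1 = RawCluster(
            np.array([0.0, 0.0, 0.0]), np.array([0.0, 2.0, 4.0]),
            np.array([0.5, 1.0, 1.5]),
        )
        c2 = RawCluster(
            np.array([10.0, 10.0, 10.0]), np.array([0.0, 2.0, 4.0]),
            np.array([0.5, 3.25, 5.25]),
        )
        assert c2.mean_t == 3.0
        kps = temporal_restructure([c1, c2])
        assert len(kps) == 2
        assert kps.cx[1] == 10.0 and kps.cy[1] == 3.0  # mean of survivors
        assert kps.n_points[1] == 2
        assert kps.mean_t[1] == 4.25
        # cluster 1 is untouched (all its points precede cluster 2's mean)
        assert kps.cy[0] == 2.0 and kps.n_points[0] == 3
        assert kps.weight.sum() == pytest.approx(5 / 6)

    def test_single_cluster_unchanged(self):
        c = RawCluster(np.array([1.0, 3.0]), np.array([0.0, 0.0]),
                       np.array([9.0, 10.0]))
        kps = temporal_restructure([c])
        assert len(kps) == 1 and kps.cx[0] == 2.0

    def test_strictly_increasing_mean_times(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            clusters = [
                RawCluster(
                    rng.normal(size=5), rng.normal(size=5),
                    rng.uniform(0, 10, size=5),
                )
                for _ in range(6)
            ]
            kps = temporal_restructure(clusters)
            assert np.all(np.diff(kps.mean_t) > 0)


class TestExtractKeypoints:
    def test_dwell_blobs_recovered(self):
        """A pen that dwells at k well-separated spots yields key points at
        those spots, in temporal order."""
        rng = np.random.default_rng(9)
        k = 5
        centers = np.array([[2000 + 4000 * i, 5000.0] for i in range(k)])
        xs, ys, ts = [], [], []
        t = 0.0
        for c in centers:
            for _ in range(30):
                xs.append(c[0] + rng.normal(0, 5))
                ys.append(c[1] + rng.normal(0, 5))
                ts.append(t)
                t += 0.02
        traj = make_traj(xs, ys, [1000] * len(xs), ts)
        kps = extract_keypoints(traj, k=k, sigma=0.1, seed=0)
        assert len(kps) == k
        assert np.all(np.diff(kps.mean_t) > 0)
        d = np.linalg.norm(kps.centers() - centers, axis=1)
        assert d.max() < 30

    def test_deterministic_and_bounded(self, small_cohort):
        records, _ = small_cohort
        traj = records[0].trajectories[("A", 1)]
        a = extract_keypoints(traj, k=40, seed=5)
        b = extract_keypoints(traj, k=40, seed=5)
        assert np.array_equal(a.cx, b.cx) and np.array_equal(a.mean_t, b.mean_t)
        assert len(a) <= 40
        assert np.all(np.diff(a.mean_t) > 0)
        assert 0 < a.weight.sum() <= 1.0 + 1e-12


class TestTemplateFeatures:
    @staticmethod
    def _kps(centers, weights=None, times=None):
        centers = np.asarray(centers, float)
        k = len(centers)
        w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, float)
        t = np.arange(k, dtype=float) if times is None else np.asarray(times, float)
        return KeyPointSequence(
            cx=centers[:, 0], cy=centers[:, 1], mean_t=t,
            n_points=np.ones(k, dtype=int), weight=w,
        )

    def test_identity_is_zero(self):
        kp = self._kps([(0, 0), (10, 0), (20, 5)])
        tf = template_features(kp, kp)
        assert (tf.dtwd, tf.vq_unweighted, tf.vq_weighted) == (0, 0, 0)

    def test_translation_gives_d_and_md(self):
        # translate perpendicular to the key-point line: every cross
        # distance is >= d, so even warping cannot beat m * d
        ref = self._kps([(0, 0), (0, 10), (0, 20)])
        shifted = self._kps([(7, 0), (7, 10), (7, 20)])
        tf = template_features(ref, shifted)
        assert tf.vq_unweighted == pytest.approx(7.0)
        assert tf.vq_weighted == pytest.approx(7.0)
        assert tf.dtwd == pytest.approx(3 * 7.0)

    def test_hand_weighted_arithmetic(self):
        ref = self._kps([(0, 0), (100, 0), (200, 0)])
        traj = self._kps(
            [(10, 0), (120, 0), (230, 0)], weights=[0.5, 0.3, 0.2]
        )
        tf = template_features(ref, traj)
        assert tf.vq_unweighted == pytest.approx(20.0)
        assert tf.vq_weighted == pytest.approx(17.0)

    def test_unequal_lengths_pair_up_to_shorter(self):
        ref = self._kps([(0, 0), (10, 0), (20, 0), (30, 0)])
        traj = self._kps([(1, 0), (11, 0)])
        tf = template_features(ref, traj)
        assert tf.vq_unweighted == pytest.approx(1.0)


def test_template_archive_round_trip(tmp_path, small_cohort):
    records, _ = small_cohort
    traj = records[0].trajectories[("A", 2)]
    kp = extract_keypoints(traj, k=10, seed=3)
    ts = TemplateSet(keypoints={("A", 2): kp}, seed=3, codebook_size=10, sigma=0.1)
    save_templates(ts, tmp_path / "tpl.json")
    back = load_templates(tmp_path / "tpl.json")
    kb = back.keypoints[("A", 2)]
    assert np.allclose(kb.cx, kp.cx) and np.allclose(kb.weight, kp.weight)
    assert kb.subject_id == kp.subject_id
    assert back.codebook_size == 10 and back.sigma == 0.1
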