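import numpy as np
import pytest
from scipy.spatial.distance import cdist

from capdyn.cap_clustering import (
    anticorrelated_pairs,
    attribute_networks,
    cap_similarity,
    compute_cap_zmaps,
    compute_validity,
    correlation_distance,
    kmeans_correlation,
    match_caps,
    pool_frames,
    row_standardize,
)
from capdyn.io_model import RoiTimeSeries, zscore_series
from capdyn.synthetic import make_atlas


def orthogonal_templates(k, r, rng):
    q, _ = np.linalg.qr(rng.normal(size=(r, k)))
    return q.T


class TestDistanceContract:
    def test_correlation_distance_equals_scaled_sq_euclidean(self):
        """d(x,y) = 1 - r(x,y) = ||x~-y~||^2 / (2(R-1)) for standardized rows."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 17))
        xs = row_standardize(x)
        for i in range(0, 30, 3):
            for j in range(1, 30, 7):
                d_corr = correlation_distance(x[i], x[j])
                d_sq = ((xs[i] - xs[j]) ** 2).sum() / (2 * (17 - 1))
                assert d_corr == pytest.approx(d_sq, abs=1e-12)

    def test_partition_matches_direct_correlation_assignment(self):
        """Euclidean assignment on standardized rows equals correlation-cdist
        assignment against the same centroids, over 20 random pools."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            pool = rng.normal(size=(60, 12))
            model = kmeans_correlation(pool, 3, seed=int(rng.integers(1000)))
            d = cdist(row_standardize(pool), model.centroids, metric="correlation")
            assert np.array_equal(d.argmin(axis=1), model.pooled_labels)


class TestKmeans:
    def test_noiseless_templates_recovered_exactly(self):
        rng = np.random.default_rng(2)
        templates = orthogonal_templates(3, 20, rng)
        idx = rng.integers(3, size=90)
        pool = templates[idx] * rng.uniform(0.5, 2.0, size=(90, 1))  # scale-free
        model = kmeans_correlation(pool, 3, seed=0, sort_by_occupancy=False)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)
        # same-template frames share a label
        for c in range(3):
            assert len(np.unique(model.pooled_labels[idx == c])) == 1
        perm, rs = match_caps(templates, model.centroids)
        assert rs.min() > 1 - 1e-12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pool = rng.normal(size=(200, 10))
        a = kmeans_correlation(pool, 4, seed=42)
        b = kmeans_correlation(pool, 4, seed=42)
        assert np.array_equal(a.pooled_labels, b.pooled_labels)
        assert a.inertia == b.inertia

    def test_objective_non_increasing_within_initialization(self):
        rng = np.random.default_rng(4)
        pool = rng.normal(size=(300, 8))
        model = kmeans_correlation(pool, 5, n_init=1, seed=0)
        trace = np.array(model.objective_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_constant_frame_rejected(self):
        pool = np.random.default_rng(5).normal(size=(40, 6))
        pool[7] = 3.0
        with pytest.raises(ValueError, match="7"):
            kmeans_correlation(pool, 2, seed=0)

    def test_assignments_partition_the_pool(self):
        rng = np.random.default_rng(6)
        pool = rng.normal(size=(150, 9))
        model = kmeans_correlation(pool, 4, seed=1)
        counts = np.bincount(model.pooled_labels, minlength=4)
        assert counts.sum() == 150
        assert (counts > 0).all()


class TestPoolFrames:
    def test_concatenation_and_map(self, standardized_series):
        pool, fmap = pool_frames(standardized_series)
        assert pool.shape == (16 * 120, 24)
        assert all(sl.stop - sl.start == 120 for sl in fmap.values())
        sid = standardized_series[3].subject_id
        assert np.array_equal(pool[fmap[sid]], standardized_series[3].data)

    def test_unstandardized_input_rejected(self):
        ts = RoiTimeSeries("s", np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError, match="not standardized"):
            pool_frames([ts])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_frames([])


class TestValidity:
    def test_two_separated_pattern_blobs_maximize_silhouette_at_k2(self):
        # blobs must differ in pattern, not offset: correlation geometry is
        # invariant to adding a constant to a frame
        rng = np.random.default_rng(7)
        t1, t2 = orthogonal_templates(2, 10, rng) * 3.0
        a = t1 + rng.normal(0, 0.3, size=(40, 10))
        b = t2 + rng.normal(0, 0.3, size=(40, 10))
        pool = np.vstack([a, b])
        table = compute_validity(pool, (2, 6), seed=0, n_init=3)
        assert len(table) == 5
        best = table.loc[table["silhouette"].idxmax(), "k"]
        assert best == 2

    def test_single_cloud_ch_decreases_beyond_2(self):
        wins = 0
        for seed in range(10):
            pool = np.random.default_rng(seed).normal(size=(80, 6))
            table = compute_validity(pool, (2, 4), seed=seed, n_init=2)
            ch = table.set_index("k")["calinski_harabasz"]
            wins += ch[2] >= ch[4]
        assert wins > 5

    def test_k_range_bounds_checked(self):
        pool = np.random.default_rng(8).normal(size=(15, 5))
        with pytest.raises(ValueError, match="k_range"):
            compute_validity(pool, (2, 20), seed=0)


class TestZmaps:
    def _series_with_means(self, values, label):
        """Subjects whose standardized frames average to the given value in
        ROI 0 for a single CAP."""
        series, assignments = [], {}
        rng = np.random.default_rng(9)
        for i, v in enumerate(values):
            data = rng.normal(size=(8, 4))
            data[:, 0] = v
            ts = RoiTimeSeries(f"s{i}", data, standardized=True)
            series.append(ts)
            assignments[f"s{i}"] = np.full(8, label)
        return series, assignments

    def test_symmetric_subject_means_cancel(self):
        series, asg = self._series_with_means([+1.0, -1.0], 0)
        zmaps, n = compute_cap_zmaps(series, asg, k=1)
        assert zmaps[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert n[0] == 2

    def test_hand_computed_z(self):
        # subject means (1,2,3,4): mean 2.5, SD 1.2910, SE = SD/2 -> Z = 3.873
        series, asg = self._series_with_means([1.0, 2.0, 3.0, 4.0], 0)
        zmaps, _ = compute_cap_zmaps(series, asg, k=1)
        assert zmaps[0, 0] == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2))
        assert zmaps[0, 0] == pytest.approx(3.873, abs=5e-4)

    def test_undersubscribed_cap_flagged_not_zeroed(self):
        series, asg = self._series_with_means([1.0, 2.0], 0)
        asg["s1"] = np.full(8, 1)  # CAP 1 now visited by one subject only
        with pytest.warns(UserWarning, match="CAP 1"):
            zmaps, n = compute_cap_zmaps(series, asg, k=2)
        assert np.isnan(zmaps[1]).all()
        assert n[1] == 1

    def test_output_shape_matches_atlas(self, standardized_series):
        k = 3
        rng = np.random.default_rng(10)
        asg = {ts.subject_id: rng.integers(k, size=ts.n_frames) for ts in standardized_series}
        zmaps, _ = compute_cap_zmaps(standardized_series, asg, k=k)
        assert zmaps.shape == (k, 24)


class TestAttribution:
    def test_toy_proportions_hand_computed(self):
        atlas = make_atlas({"A": 2, "B": 2})
        zmaps = np.array([[3.0, -2.5, 1.0, 2.0]])
        table = attribute_networks(zmaps, atlas, z_threshold=1.96)
        props = table.set_index("network")["proportion"]
        assert props["A"] == pytest.approx(5.5 / 7.5)
        assert props["B"] == pytest.approx(2.0 / 7.5)
        # signed masses: A has +3 and -2.5; B has +2 only
        row_a = table[table.network == "A"].iloc[0]
        assert row_a.positive_mass == pytest.approx(3.0)
        assert row_a.negative_mass == pytest.approx(2.5)

    def test_concentrated_map_gives_proportion_one(self):
        atlas = make_atlas({"DMN": 3, "ATN": 3})
        zmaps = np.array([[4.0, 3.0, 2.5, 0.0, 1.0, -1.5]])
        table = attribute_networks(zmaps, atlas)
        props = table.set_index("network")["proportion"]
        assert props["DMN"] == pytest.approx(1.0)
        assert props["ATN"] == 0.0

    def test_subthreshold_map_warns_all_zero(self):
        atlas = make_atlas({"A": 2, "B": 2})
        with pytest.warns(UserWarning, match="no supra-threshold"):
            table = attribute_networks(np.array([[0.5, -0.3, 1.0, 0.2]]), atlas)
        assert (table["proportion"] == 0).all()


class TestSimilarity:
    def test_self_and_negation(self):
        rng = np.random.default_rng(11)
        m = rng.normal(size=12)
        sim = cap_similarity(np.vstack([m, -m, rng.normal(size=12)]))
        assert sim[0, 0] == pytest.approx(1.0)
        assert sim[0, 1] == pytest.approx(-1.0)
        assert np.allclose(sim, sim.T)
        pairs = anticorrelated_pairs(sim)
        assert (0, 1, pytest.approx(-1.0)) in [(i, j, r) for i, j, r in pairs]
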