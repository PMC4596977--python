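"""Manhattan distance, region queries and the serial density scanner."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_region_query, random_sweep_cases
from dermborder.density import (
    NOISE,
    NO_LABEL,
    ClusterMap,
    canonicalize_labels,
    dbscan_serial,
    manhattan_distance,
    neighbor_counts,
    region_query,
)
from dermborder.image import Params


class TestManhattanDistance:
    def test_identity(self):
        assert manhattan_distance((3, 4), (3, 4)) == 0

    def test_radius_four_ring(self):
        """Offsets on the distance-4 ring of the Manhattan region figure."""
        c = (10, 10)
        for dx, dy in [(4, 0), (-4, 0), (0, 4), (0, -4), (2, 2), (1, 3)]:
            assert manhattan_distance(c, (c[0] + dx, c[1] + dy)) == 4

    def test_simple_sum_of_deltas(self):
        assert manhattan_distance((1, 2), (4, 6)) == 7

    @given(st.tuples(st.integers(0, 50), st.integers(0, 50)), st.tuples(st.integers(0, 50), st.integers(0, 50)))
    def test_symmetric_and_zero_iff_equal(self, p, q):
        assert manhattan_distance(p, q) == manhattan_distance(q, p)
        assert (manhattan_distance(p, q) == 0) == (p == q)


class TestRegionQuery:
    def test_radius_one_diamond_on_full_grid(self):
        mask = np.ones((9, 9), dtype=bool)
        assert len(region_query((4, 4), mask, 1)) == 5

    def test_radius_four_diamond_on_full_grid(self):
        mask = np.ones((11, 11), dtype=bool)
        # brute-force count of {(dx,dy): |dx|+|dy| <= 4}
        expected = sum(
            1 for dx in range(-4, 5) for dy in range(-4, 5) if abs(dx) + abs(dy) <= 4
        )
        assert expected == 41
        assert len(region_query((5, 5), mask, 4)) == 41

    def test_lonely_center_returns_itself(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert region_query((2, 2), mask, 2).tolist() == [2 * 5 + 2]

    def test_out_of_bounds_center_rejected(self):
        with pytest.raises(ValueError):
            region_query((9, 0), np.ones((3, 3), bool), 1)

    @pytest.mark.parametrize("eps", range(1, 7))
    def test_disc_size_closed_form_far_from_boundary(self, eps):
        """|N_eps| on a full grid equals eps^2 + (eps+1)^2."""
        side = 2 * eps + 3
        mask = np.ones((side, side), dtype=bool)
        c = side // 2
        assert len(region_query((c, c), mask, eps)) == eps**2 + (eps + 1) ** 2

    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    def test_matches_exhaustive_scan(self, seed, eps):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 17)) < rng.uniform(0.2, 0.8)
        x = int(rng.integers(0, 17))
        y = int(rng.integers(0, 12))
        got = set(region_query((x, y), mask, eps).tolist())
        assert got == brute_region_query(mask.tolist(), x, y, eps)

    def test_counts_agree_with_query_sizes(self):
        rng = np.random.default_rng(11)
        mask = rng.random((20, 20)) < 0.5
        counts = neighbor_counts(mask, 2)
        for x, y in [(0, 0), (5, 7), (19, 19), (10, 0)]:
            assert counts[y, x] == len(region_query((x, y), mask, 2))


class TestCanonicalize:
    def test_cluster_ids_become_min_member_pid(self):
        labels = np.full((2, 5), NO_LABEL, dtype=np.int64)
        labels[0, 2:5] = 99  # pids 2,3,4 in one cluster
        labels[1, 0:2] = 7  # pids 5,6 in another
        out = canonicalize_labels(ClusterMap(labels))
        assert set(out.labels[0, 2:5]) == {2}
        assert set(out.labels[1, 0:2]) == {5}

    def test_idempotent_and_preserves_noise(self):
        labels = np.array([[3, 3, NOISE, NO_LABEL]], dtype=np.int64)
        labels[0, 0] = 0
        labels[0, 1] = 0
        once = canonicalize_labels(ClusterMap(labels))
        twice = canonicalize_labels(once)
        assert np.array_equal(once.labels, twice.labels)
        assert once.labels[0, 2] == NOISE


class TestSerialScanner:
    def test_empty_mask_yields_nothing(self):
        cmap = dbscan_serial(np.zeros((8, 8), bool), Params(eps=2, min_pts=3))
        assert cmap.n_clusters == 0
        assert (cmap.labels == NO_LABEL).all()

    def test_isolated_node_is_noise(self):
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        cmap = dbscan_serial(mask, Params(eps=1, min_pts=4))
        assert cmap.labels[3, 3] == NOISE

    def test_solid_block_is_one_cluster_including_sparse_corners(self, solid_block):
        """Corners have |N|=3 < 4 but are density-reachable border points."""
        mask = solid_block(5, 5)
        cmap = dbscan_serial(mask, Params(eps=1, min_pts=4))
        assert cmap.n_clusters == 1
        assert (cmap.labels[mask] >= 0).all()
        assert cmap.cluster_sizes() == {int(cmap.cluster_ids()[0]): 25}

    def test_label_is_min_member_pid(self, solid_block):
        mask = solid_block(4, 4, margin=2)
        cmap = dbscan_serial(mask, Params(eps=1, min_pts=3))
        ys, xs = np.nonzero(mask)
        min_pid = int((ys * mask.shape[1] + xs).min())
        assert set(cmap.labels[mask]) == {min_pid}

    def test_wide_eps_min_pts_one_gives_single_cluster_with_global_min_pid(self):
        rng = np.random.default_rng(3)
        mask = rng.random((10, 12)) < 0.4
        cmap = dbscan_serial(mask, Params(eps=25, min_pts=1))
        ys, xs = np.nonzero(mask)
        assert set(cmap.labels[mask]) == {int((ys * 12 + xs).min())}

    @pytest.mark.parametrize("case", range(8))
    def test_partitions_nodes_and_every_cluster_contains_a_core(self, case):
        mask, eps, min_pts = random_sweep_cases(8, seed=77)[case]
        params = Params(eps=eps, min_pts=min_pts)
        cmap = dbscan_serial(mask, params)
        # every node labelled, no non-node labelled
        assert (cmap.labels[mask] != NO_LABEL).all()
        assert (cmap.labels[~mask] == NO_LABEL).all()
        counts = neighbor_counts(mask, eps)
        dense = mask & (counts >= min_pts)
        for cid in cmap.cluster_ids():
            members = cmap.labels == cid
            assert (members & dense).any(), "cluster without a core node"
            # every member within eps of a dense member of the same cluster
            from scipy import ndimage

            from dermborder.density import diamond_footprint

            near_core = ndimage.binary_dilation(members & dense, diamond_footprint(eps))
            assert (members <= near_core).all()

    def test_matches_sklearn_on_core_partition_and_noise(self):
        """Independent cross-check: sklearn DBSCAN (manhattan metric).

        Border attribution is order-dependent in sklearn, so agreement is
        asserted on the noise set and on the partition of core points only.
        """
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        for mask, eps, min_pts in random_sweep_cases(6, seed=123):
            params = Params(eps=eps, min_pts=min_pts)
            cmap = dbscan_serial(mask, params)
            ys, xs = np.nonzero(mask)
            pts = np.column_stack([xs, ys])
            sk = sklearn_cluster.DBSCAN(eps=eps, min_samples=min_pts, metric="manhattan").fit(pts)
            ours = cmap.labels[ys, xs]
            counts = neighbor_counts(mask, eps)
            dense = counts[ys, xs] >= min_pts
            # sklearn "core_sample_indices_" should be exactly our dense nodes
            sk_core = np.zeros(len(pts), dtype=bool)
            sk_core[sk.core_sample_indices_] = True
            assert np.array_equal(sk_core, dense)
            # same partition of core points: label maps are each other's
            # refinement.  Our map demotes sub-min_pts clusters to noise, a
            # rule sklearn lacks, so the comparison is on surviving clusters.
            keep = dense & (ours >= 0)
            for arr_a, arr_b in [
                (ours[keep], sk.labels_[keep]),
                (sk.labels_[keep], ours[keep]),
            ]:
                mapping = {}
                for a, b in zip(arr_a.tolist(), arr_b.tolist()):
                    assert mapping.setdefault(a, b) == b
            # sklearn noise (no core within eps) is a subset of our noise
            assert (ours[sk.labels_ == -1] == NOISE).all()

    def test_demotes_border_only_when_cluster_too_small(self):
        # two dense seeds sharing one border node stay separate clusters
        mask = np.zeros((5, 9), bool)
        mask[2, 0:3] = True   # left cluster, dense for eps=1,min_pts=3 at centre
        mask[1:4, 1] = True
        mask[2, 6:9] = True   # right cluster
        mask[1:4, 7] = True
        mask[2, 4] = True     # lone middle node: noise (no dense neighbour at eps=1)
        cmap = dbscan_serial(mask, Params(eps=1, min_pts=3))
        assert cmap.n_clusters == 2
        assert cmap.labels[2, 4] == NOISE
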