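"""Cluster centers, the quantile criterion and the subsampling retry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screscale import (
    align_clusters,
    candidate_queries,
    cluster_centers,
    quantile_criterion,
    retry_subsample_size,
)
from screscale.alignment import ClusterCenters
from screscale.datatypes import Clustering, ScaledMatrix
from screscale.embedding import pca, snn_graph, cluster_snn


class TestClusterCenters:
    def test_center_is_brute_force_mean(self, rng):
        scores = rng.normal(size=(9, 4))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        cc = cluster_centers(scores, Clustering(labels, 1.0), np.arange(9))
        for c in range(3):
            assert np.allclose(cc.centers[c], scores[labels == c].mean(axis=0),
                               atol=1e-8)

    def test_singleton_cluster(self):
        scores = np.array([[1.0, 2.0], [5.0, 5.0]])
        cc = cluster_centers(scores, Clustering(np.array([0, 1]), 1.0),
                             np.arange(2))
        assert np.allclose(cc.centers[0], [1.0, 2.0])

    def test_symmetric_pair_centers_at_origin(self):
        scores = np.array([[3.0, -2.0], [-3.0, 2.0]])
        cc = cluster_centers(scores, Clustering(np.array([0, 0]), 1.0),
                             np.arange(2))
        assert np.allclose(cc.centers[0], 0.0)


class TestQuantileCriterion:
    def test_coincident_centers_pass(self, rng):
        cells = rng.normal(size=(10, 3))
        center = cells.mean(axis=0)
        assert quantile_criterion(center, cells, center)

    def test_radii_all_one_distance_four_fails(self):
        # four cells at squared radius 1, anchor at squared distance 4
        cells = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        assert not quantile_criterion(np.array([2.0, 0.0]), cells,
                                      np.zeros(2))

    def test_interpolated_quantile_passes(self):
        # squared radii {0,1,2,3}: Q75 = 2.25 by linear interpolation
        cells = np.array([[0, 0], [1, 0], [np.sqrt(2), 0], [np.sqrt(3), 0]])
        center_a = np.array([np.sqrt(2), 0.0])  # squared distance 2 < 2.25
        assert quantile_criterion(center_a, cells, np.zeros(2))

    def test_single_cell_query_warns_and_rejects(self):
        with pytest.warns(UserWarning, match="single-cell"):
            ok = quantile_criterion(np.array([1.0]), np.array([[0.0]]),
                                    np.array([0.0]))
        assert not ok

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_sorted_distance_oracle(self, seed):
        """Exact agreement with a sort-based quantile oracle."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        cells = rng.normal(size=(n, 3))
        center_b = cells.mean(axis=0)
        center_a = rng.normal(size=3)
        radii = np.sort(np.sum((cells - center_b) ** 2, axis=1))
        # type-7 quantile by hand: h = (n-1) * 0.75
        h = (n - 1) * 0.75
        lo = int(np.floor(h))
        q = radii[lo] + (h - lo) * (radii[min(lo + 1, n - 1)] - radii[lo])
        expected = float(np.sum((center_a - center_b) ** 2)) < q
        assert quantile_criterion(center_a, cells, center_b) == expected


class TestCandidateQueries:
    def _centers(self, arr):
        arr = np.asarray(arr, dtype=float)
        return ClusterCenters(centers=arr,
                              cluster_sizes=np.ones(len(arr), dtype=int))

    def test_fewer_than_m_returns_all(self):
        qc = self._centers([[0], [1], [2]])
        assert candidate_queries(np.array([0.0]), qc, m=5) == [0, 1, 2]

    def test_sorted_by_distance(self):
        qc = self._centers([[3], [1], [2]])
        assert candidate_queries(np.array([0.0]), qc, m=5) == [1, 2, 0]

    def test_tie_broken_by_smaller_id(self):
        qc = self._centers([[1], [-1]])
        assert candidate_queries(np.array([0.0]), qc, m=5) == [0, 1]


class TestRetrySubsampleSize:
    def test_worked_example(self):
        n_prime = retry_subsample_size(500, 1000, 0.25)
        assert n_prime == 166
        assert n_prime / (1000 - 500 + n_prime) <= 0.25

    def test_fixed_point_at_current_proportion(self):
        # target equal to the current proportion: subsampling is a no-op
        assert retry_subsample_size(500, 1000, 0.5) == 500

    def test_degenerate_tiny_target(self):
        with pytest.raises(ValueError):
            retry_subsample_size(2, 1000, 0.0001)

    def test_not_overrepresented_raises(self):
        with pytest.raises(ValueError, match="over-represented"):
            retry_subsample_size(100, 1000, 0.5)

    @settings(deadline=None, max_examples=1000)
    @given(st.integers(0, 2**31 - 1))
    def test_proportion_sandwich(self, seed):
        """n'/(N-n+n') <= p < (n'+1)/(N-n+n'+1) whenever n' is defined."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 100_000))
        n = int(rng.integers(2, N))
        p = float(rng.uniform(1e-4, 1 - 1e-4))
        if n / N <= p:
            return
        try:
            n_prime = retry_subsample_size(n, N, p)
        except ValueError:
            return
        rest = N - n
        assert n_prime / (rest + n_prime) <= p
        assert p < (n_prime + 1) / (rest + n_prime + 1)


def _self_pair(rng, n=220, genes=60):
    """One dataset duplicated into two 'platforms' with the same clusters."""
    import screscale as s
    cfg = s.SimulationConfig(
        n_genes=genes, type_names=("t0", "t1"),
        compositions=((0.5, 0.5),), n_cells=(n,),
        depths=(50_000.0,), dropout=(None,), seed=3, platforms=("x",))
    (ds,), truth = s.simulate_pair(cfg)
    sm = s.scale_genes(s.lognormalize(ds))
    emb = pca(sm, n_pcs=10)
    snn = snn_graph(emb.scores, k_neighbors=15)
    cl = cluster_snn(snn, 0.8, seed=0)
    return sm, cl, truth


class TestAlignClusters:
    def test_self_alignment_perfect_matching_no_retry(self, rng):
        sm, cl, _ = _self_pair(rng)
        sm_b = ScaledMatrix(sm.values.copy(), sm.gene_ids,
                            [f"b_{c}" for c in sm.cell_ids], platform="y")
        am = align_clusters(sm, sm_b, cl, cl, n_pcs=10, seed=0)
        assert am.pairs == [(c, c) for c in range(cl.n_clusters)]
        assert am.retry_log == []
        assert am.unaligned_anchor_clusters == []

    def test_two_anchor_clusters_sharing_query_are_merged(self, rng):
        sm, cl, _ = _self_pair(rng)
        # split anchor cluster 0 artificially into two ids -> both should
        # align to query cluster 0 and be merged
        labels = cl.labels.copy()
        zero_cells = np.flatnonzero(labels == 0)
        labels[zero_cells[: len(zero_cells) // 2]] = cl.n_clusters
        split = Clustering(_contiguous(labels), cl.resolution)
        sm_b = ScaledMatrix(sm.values.copy(), sm.gene_ids,
                            [f"b_{c}" for c in sm.cell_ids], platform="y")
        am = align_clusters(sm, sm_b, split, cl, n_pcs=10, seed=0)
        groups = am.groups_by_query()
        assert any(len(g) >= 2 for g in groups.values())
        assert am.merged_anchor_groups

    def test_alignment_map_serializable(self, rng):
        import json
        sm, cl, _ = _self_pair(rng)
        sm_b = ScaledMatrix(sm.values.copy(), sm.gene_ids,
                            [f"b_{c}" for c in sm.cell_ids], platform="y")
        am = align_clusters(sm, sm_b, cl, cl, n_pcs=10, seed=0)
        blob = json.dumps(am.to_dict())
        assert "pairs" in json.loads(blob)


def _contiguous(labels):
    out = np.empty_like(labels)
    seen = {}
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(lab, len(seen))
    return out


def test_retry_rescues_skewed_composition():
    """A type over-represented 80/20 vs 20/80 fails pass one but aligns after
    the subsampling retry, and the retry log records it."""
    import screscale as s
    cfg = s.SimulationConfig(
        n_genes=300, type_names=("t0", "t1"),
        compositions=((0.8, 0.2), (0.2, 0.8)),
        n_cells=(500, 500), depths=(100_000.0, 100_000.0),
        dropout=(None, None), seed=0, platforms=("a", "b"),
        marker_fraction=0.25, marker_fold=3.0, dispersion=1.2,
        burst_prob=0.4,
    )
    datasets, truth = s.simulate_pair(cfg)
    sms = [s.scale_genes(s.lognormalize(d)) for d in datasets]
    clusterings = []
    for sm in sms:
        emb = pca(sm, n_pcs=10)
        clusterings.append(cluster_snn(snn_graph(emb.scores), 0.4, seed=0))
    am = align_clusters(sms[0], sms[1], clusterings[0], clusterings[1],
                        n_pcs=10, seed=0)
    # every anchor cluster ends up aligned; if pass one could not do it the
    # retry log shows the subsampling attempt
    assert am.unaligned_anchor_clusters == []
    assert am.pairs
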