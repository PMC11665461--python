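"""Correlation, edge construction against a brute-force reference, hub selection."""

import itertools
import math

import numpy as np
import pytest

from peaknet.network import (
    build_network,
    network_from_matrix,
    pairwise_correlation,
    select_hubs,
)
from peaknet.qc import OutlierMask, mask_outliers
from peaknet.synthetic import SyntheticConfig, generate

from .conftest import make_matrix


def brute_pearson(x, y):
    """Textbook Pearson formula, no numpy vector tricks."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def reference_network(corr, threshold=0.4):
    """Independent edge constructor: adjacency sets + pairwise intersection."""
    n = corr.shape[0]
    direct = {
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if not np.isnan(corr[i, j]) and abs(corr[i, j]) >= threshold
    }
    neigh = {i: set() for i in range(n)}
    for i, j in direct:
        neigh[i].add(j)
        neigh[j].add(i)
    indirect = {
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if (i, j) not in direct and neigh[i] & neigh[j]
    }
    degree = [0] * n
    for i, j in direct | indirect:
        degree[i] += 1
        degree[j] += 1
    return direct, indirect, degree


class TestPairwiseCorrelation:
    def test_affine_relation_gives_unit_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 7.0])
        m = make_matrix(np.vstack([x, 2 * x + 1, 9 - x]))
        r = pairwise_correlation(m, min_pairs=2)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        r = pairwise_correlation(np.vstack([x, y]), min_pairs=2)
        assert r[0, 1] == pytest.approx(brute_pearson(x, y), abs=1e-12)

    def test_mask_restricts_to_pairwise_complete_observations(self, rng):
        vals = rng.uniform(0, 5, size=(2, 12))
        mask = np.zeros_like(vals, dtype=bool)
        mask[0, 2] = mask[1, 7] = True
        r = pairwise_correlation(vals, OutlierMask(mask), min_pairs=2)
        keep = ~(mask[0] | mask[1])
        expected = brute_pearson(vals[0, keep].tolist(), vals[1, keep].tolist())
        assert r[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_min_pairs_floor_yields_missing(self, rng):
        vals = rng.uniform(0, 5, size=(2, 10))
        mask = np.zeros_like(vals, dtype=bool)
        mask[0, :5] = True  # only 5 complete pairs remain
        r = pairwise_correlation(vals, OutlierMask(mask), min_pairs=8)
        assert np.isnan(r[0, 1])

    def test_zero_variance_yields_missing(self):
        r = pairwise_correlation(np.vstack([[1.0] * 6, np.arange(6.0)]), min_pairs=2)
        assert np.isnan(r[0, 1])

    def test_matches_numpy_corrcoef_unmasked(self, rng):
        vals = rng.uniform(0, 100, size=(15, 30))
        r = pairwise_correlation(vals)
        np.testing.assert_allclose(r, np.corrcoef(vals), atol=1e-10)


class TestBuildNetwork:
    def test_shared_neighbor_triangle(self):
        corr = np.eye(3)
        corr[0, 2] = corr[2, 0] = 0.9  # A-C
        corr[1, 2] = corr[2, 1] = 0.8  # B-C
        corr[0, 1] = corr[1, 0] = 0.1
        net = build_network(corr, node_ids=["A", "B", "C"])
        assert net.direct_edges == {("A", "C"), ("B", "C")}
        assert net.indirect_edges == {("A", "B")}
        assert net.degree_map == {"A": 2, "B": 2, "C": 2}

    def test_subthreshold_network_is_empty(self):
        corr = np.full((4, 4), 0.39)
        np.fill_diagonal(corr, 1.0)
        net = build_network(corr)
        assert not net.direct_edges and not net.indirect_edges
        assert net.degree.sum() == 0

    def test_threshold_is_inclusive(self):
        corr = np.eye(2)
        corr[0, 1] = corr[1, 0] = 0.4
        assert len(build_network(corr).direct_edges) == 1

    @pytest.mark.parametrize("trial", range(30))
    def test_equals_bruteforce_reference_on_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 100))
        raw = rng.uniform(-1, 1, size=(n, n)) * rng.choice([0.3, 0.5, 1.0])
        corr = (raw + raw.T) / 2
        np.fill_diagonal(corr, 1.0)
        net = build_network(corr)
        ids = {pid: i for i, pid in enumerate(net.node_ids)}
        direct = {tuple(sorted((ids[a], ids[b]))) for a, b in net.direct_edges}
        indirect = {tuple(sorted((ids[a], ids[b]))) for a, b in net.indirect_edges}
        ref_direct, ref_indirect, ref_degree = reference_network(corr)
        assert direct == ref_direct
        assert indirect == ref_indirect
        assert net.degree.tolist() == ref_degree

    def test_lowering_threshold_never_removes_direct_edges(self, rng):
        raw = rng.uniform(-1, 1, size=(30, 30))
        corr = (raw + raw.T) / 2
        np.fill_diagonal(corr, 1.0)
        high = build_network(corr, r_threshold=0.6).direct_edges
        low = build_network(corr, r_threshold=0.3).direct_edges
        assert high <= low

    def test_degrees_invariant_under_relabeling(self, rng):
        raw = rng.uniform(-1, 1, size=(25, 25))
        corr = (raw + raw.T) / 2
        np.fill_diagonal(corr, 1.0)
        perm = rng.permutation(25)
        net = build_network(corr)
        net_p = build_network(corr[np.ix_(perm, perm)])
        assert sorted(net.degree.tolist()) == sorted(net_p.degree.tolist())
        np.testing.assert_array_equal(net.degree[perm], net_p.degree)

    def test_streaming_matches_dense_path(self):
        cfg = SyntheticConfig(seed=9, n_peaks=300, n_samples=60, n_hub_blocks=5)
        matrix, *_ = generate(cfg)
        mask = mask_outliers(matrix)
        dense = build_network(
            pairwise_correlation(matrix, mask), node_ids=matrix.peak_ids
        )
        streamed = network_from_matrix(matrix, mask, block_size=64)
        assert streamed.direct_edges == dense.direct_edges
        assert streamed.indirect_edges == dense.indirect_edges

    def test_indirect_depth_zero_disables_indirect_edges(self):
        corr = np.eye(3)
        corr[0, 2] = corr[2, 0] = 0.9
        corr[1, 2] = corr[2, 1] = 0.8
        net = build_network(corr, indirect_depth=0)
        assert net.indirect_edges == set()


class TestSelectHubs:
    def _network_with_degrees(self, degrees, ids=None):
        n = len(degrees)
        corr = np.eye(n)
        net = build_network(corr, node_ids=ids or [f"n{i:03d}" for i in range(n)])
        net._degree = np.asarray(degrees)
        return net

    def test_exact_count_from_fraction(self):
        net = self._network_with_degrees(list(range(20)))
        assert len(select_hubs(net, 0.10)) == 2

    def test_single_top_node(self):
        net = self._network_with_degrees([5, 1, 1, 1, 1, 1, 1, 1, 1, 1])
        assert select_hubs(net, 0.10) == ["n000"]

    def test_ties_break_lexicographically(self):
        net = self._network_with_degrees([2, 2, 2, 2, 2], ids=["e", "c", "a", "d", "b"])
        assert select_hubs(net, 0.4) == ["a", "b"]

    def test_zero_selection_is_an_error(self):
        net = self._network_with_degrees([1, 2, 3])
        with pytest.raises(ValueError, match="fraction"):
            select_hubs(net, 0.1)

    def test_hub_recovery_on_planted_blocks(self):
        from peaknet.qc import filter_low_quality

        matrix, *_rest, truth = generate(SyntheticConfig(seed=2))
        filtered = filter_low_quality(matrix)
        net = network_from_matrix(filtered, mask_outliers(filtered))
        hubs = select_hubs(net, 0.10)
        precision = len(set(hubs) & truth.hub_peak_ids) / len(hubs)
        assert precision >= 0.9
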