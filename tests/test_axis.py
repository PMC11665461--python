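"""PCA scores and explained variance, axis partitions, Grubbs, group t-test."""

import numpy as np
import pytest
from scipy import stats

from peaknet.axis import (
    AxisPartition,
    axis_partition,
    compare_groups,
    grubbs_exclude,
    run_pca,
)
from peaknet.io import ClinicalRecord
from peaknet.synthetic import SyntheticConfig, generate

from .conftest import make_matrix


def _partition_from_distances(dists):
    ids = [f"S{i + 1}" for i in range(len(dists))]
    border = float(np.mean(dists))
    distance = dict(zip(ids, map(float, dists)))
    inside = {s for s, d in distance.items() if d < border}
    return AxisPartition(
        component_index=1, sample_ids=ids, distance=distance, border=border,
        inside=inside, outside=set(ids) - inside,
    )


class TestRunPca:
    def test_two_collinear_variables_give_rank_one(self, rng):
        x = rng.uniform(0, 5, 10)
        m = make_matrix(np.vstack([x, 3 * x + 2]))
        res = run_pca(m, m.peak_ids, n_components=5)
        assert res.n_components == 1
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_scores_are_centered(self, rng):
        m = make_matrix(rng.uniform(0, 10, size=(6, 8)))
        res = run_pca(m, m.peak_ids)
        np.testing.assert_allclose(res.scores.sum(axis=0), 0.0, atol=1e-9)

    def test_explained_fractions_match_eigendecomposition(self):
        # independent oracle: eigenvalues of the variable correlation matrix
        vals = np.array(
            [
                [1.0, 4.0, 2.0, 7.0],
                [3.0, 1.0, 5.0, 2.0],
                [2.0, 2.0, 2.5, 9.0],
                [8.0, 1.0, 4.0, 3.0],
                [5.0, 5.0, 5.5, 1.0],
            ]
        )
        m = make_matrix(vals)  # 5 peak variables (rows) x 4 samples
        res = run_pca(m, m.peak_ids, n_components=5)
        corr = np.corrcoef(vals)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        expected = eig / eig.sum()
        assert res.n_components == 3  # centering 4 samples leaves rank 3
        np.testing.assert_allclose(
            res.explained_fraction, expected[: res.n_components], atol=1e-9
        )

    def test_constant_peak_dropped_with_warning(self, rng, caplog):
        vals = rng.uniform(1, 5, size=(4, 10))
        vals[2] = 3.0
        m = make_matrix(vals)
        with caplog.at_level("WARNING"):
            res = run_pca(m, m.peak_ids, n_components=3)
        assert "constant" in caplog.text
        assert m.peak_ids[2] not in res.peak_ids

    def test_sample_permutation_permutes_scores(self, rng):
        m = make_matrix(rng.uniform(0, 10, size=(8, 9)))
        perm = rng.permutation(m.n_samples)
        m_p = m.subset_samples([m.sample_ids[j] for j in perm])
        res = run_pca(m, m.peak_ids)
        res_p = run_pca(m_p, m.peak_ids)
        np.testing.assert_allclose(res_p.scores, res.scores[perm], atol=1e-8)

    def test_component_sign_fixed_by_leading_variable(self, rng):
        m = make_matrix(rng.uniform(0, 10, size=(6, 12)))
        res = run_pca(m, m.peak_ids)
        for c in range(res.n_components):
            lead = np.argmax(np.abs(res.peak_pc_correlation[:, c]))
            assert res.peak_pc_correlation[lead, c] > 0

    def test_peak_pc_correlation_bounded(self, rng):
        m = make_matrix(rng.uniform(0, 10, size=(7, 11)))
        res = run_pca(m, m.peak_ids)
        assert np.all(np.abs(res.peak_pc_correlation) <= 1.0)


class TestAxisPartition:
    def test_forced_arithmetic_example(self, rng):
        # scores (1, -1, 3, -3): distances (1,1,3,3), border 2
        m = make_matrix(rng.uniform(0, 10, size=(6, 4)))
        res = run_pca(m, m.peak_ids, n_components=2)
        res.scores[:, 0] = [1.0, -1.0, 3.0, -3.0]
        part = axis_partition(res, 1)
        assert part.border == pytest.approx(2.0)
        assert part.inside == {"S1", "S2"}
        assert part.outside == {"S3", "S4"}
        assert part.distance["S4"] == pytest.approx(3.0)

    def test_equal_distances_leave_inside_empty(self, rng):
        m = make_matrix(rng.uniform(0, 10, size=(6, 4)))
        res = run_pca(m, m.peak_ids, n_components=1)
        res.scores[:, 0] = [2.0, -2.0, 2.0, -2.0]
        part = axis_partition(res, 1)
        assert part.inside == set()
        assert part.outside == {"S1", "S2", "S3", "S4"}

    def test_partition_covers_cohort_for_every_component(self, rng):
        m = make_matrix(rng.uniform(0, 10, size=(10, 9)))
        res = run_pca(m, m.peak_ids)
        for c in range(1, res.n_components + 1):
            part = axis_partition(res, c)
            assert part.inside | part.outside == set(m.sample_ids)
            assert not part.inside & part.outside


class TestGrubbs:
    @staticmethod
    def oracle_critical(n, alpha=0.05):
        t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
        return (n - 1) * np.sqrt(t2 / (n * (n - 2 + t2)))

    def test_single_extreme_value_excluded(self):
        values = [8.0, 9.0, 10.0, 11.0, 50.0]
        kept, excluded = grubbs_exclude(values)
        assert excluded == [4]
        assert kept == [8.0, 9.0, 10.0, 11.0]
        # oracle: G for 50 exceeds the critical value, remaining G does not
        a = np.asarray(values)
        g = np.max(np.abs(a - a.mean())) / a.std(ddof=1)
        assert g > self.oracle_critical(5)
        b = np.asarray(kept)
        g2 = np.max(np.abs(b - b.mean())) / b.std(ddof=1)
        assert g2 < self.oracle_critical(4)

    def test_no_extreme_value_nothing_excluded(self):
        kept, excluded = grubbs_exclude([1.0, 2.0, 3.0])
        assert kept == [1.0, 2.0, 3.0] and excluded == []

    def test_constant_list_untouched(self):
        kept, excluded = grubbs_exclude([4.0, 4.0, 4.0, 4.0])
        assert kept == [4.0] * 4 and excluded == []

    def test_iterative_removal_tracks_original_indices(self):
        # one-sided pair: the larger outlier falls first, then the second
        kept, excluded = grubbs_exclude([10.0, 11.0, 9.0, 10.5, 10.2, 9.8, 50.0, 30.0])
        assert excluded == [6, 7]
        assert kept == [10.0, 11.0, 9.0, 10.5, 10.2, 9.8]

    def test_opposite_outliers_can_mask_each_other(self):
        # symmetric extremes inflate the SD; Grubbs tests one value at a time
        kept, excluded = grubbs_exclude([100.0, 10.0, 11.0, 9.0, 10.5, -80.0, 10.2])
        assert excluded == []
        assert len(kept) == 7


class TestCompareGroups:
    @staticmethod
    def _clinical(n_light, n_heavy):
        recs = [
            ClinicalRecord(f"S{i + 1}", pack_years=5.0) for i in range(n_light)
        ] + [
            ClinicalRecord(f"S{n_light + i + 1}", pack_years=40.0) for i in range(n_heavy)
        ]
        return recs

    def test_identical_distances_give_null_result(self):
        part = _partition_from_distances([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = compare_groups(part, self._clinical(3, 3))
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_welch(self):
        a = [1.1, 2.3, 0.7, 1.9, 1.5]
        b = [3.2, 4.1, 2.8, 3.9, 5.0]
        part = _partition_from_distances(a + b)
        res = compare_groups(part, self._clinical(5, 5))
        na, nb = 5, 5
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t = (np.mean(a) - np.mean(b)) / np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p = 2 * stats.t.sf(abs(t), df)
        assert res.t_statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_unknown_smokers_are_dropped(self):
        part = _partition_from_distances([1.0, 2.0, 5.0, 6.0, 9.0])
        recs = self._clinical(2, 2) + [ClinicalRecord("S5", pack_years=None)]
        res = compare_groups(part, recs)
        assert len(res.group_a) == 2 and len(res.group_b) == 2

    def test_grubbs_outlier_excluded_within_group(self):
        a = [1.0, 1.1, 0.9, 1.05, 40.0]  # one wild light-smoker distance
        b = [3.0, 3.2, 2.9, 3.1, 3.05]
        part = _partition_from_distances(a + b)
        res = compare_groups(part, self._clinical(5, 5))
        assert res.excluded == ["S5"]
        assert res.mean_a == pytest.approx(np.mean(a[:4]))

    def test_empty_group_is_an_error(self):
        part = _partition_from_distances([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups(part, self._clinical(3, 0))

    def test_heavy_group_spreads_wider_on_planted_axis(self):
        """Direction of the group effect over 200 simulated small cohorts.

        With heavy smokers' factor-2 scores inflated (sd x2), the heavy
        group should show the larger mean |PC2| distance in >=80% of
        11-vs-11 cohorts.
        """
        direction = 0
        reps = 200
        for seed in range(reps):
            cfg = SyntheticConfig(seed=seed, n_samples=22, heavy_fraction=0.5)
            matrix, clinical, *_rest, truth = generate(cfg)
            res_pca = run_pca(matrix, sorted(truth.hub_peak_ids))
            res = compare_groups(axis_partition(res_pca, 2), clinical)
            direction += res.mean_b > res.mean_a
        assert direction / reps >= 0.8
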