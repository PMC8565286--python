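import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from qda.io_volumes import BrainMask
from qda.group_stats import (
    anticorr_network,
    critical_t,
    extract_clusters,
    fit_age_regression,
    overlap_rois,
    permutation_cluster_fwe,
    roi_mean_trend,
    seed_corr_map,
    select_subgroups,
    two_sample_ttest,
)
from qda.qda_core import standardize_rows


def make_pheno(ages, genders=None, rng=None):
    n = len(ages)
    if genders is None:
        genders = (rng or np.random.default_rng(0)).integers(0, 2, n)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age_years": np.asarray(ages, dtype=float),
            "gender": np.asarray(genders, dtype=int),
        }
    )


def flood_fill_clusters(grid):
    """Brute-force 6-connected components of a boolean 3D grid."""
    grid = np.asarray(grid, dtype=bool)
    seen = np.zeros_like(grid)
    comps = []
    for start in zip(*np.nonzero(grid)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            comp.append((x, y, z))
            for dx, dy, dz in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                p = (x + dx, y + dy, z + dz)
                if all(0 <= pi < si for pi, si in zip(p, grid.shape)) \
                        and grid[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
        comps.append(frozenset(comp))
    return set(comps)


class TestAgeRegression:
    def test_perfect_linear_relation(self, rng):
        ages = rng.uniform(20, 70, 30)
        pheno = make_pheno(ages, rng=rng)
        maps = (2.0 + 0.05 * ages)[:, None] * np.ones((1, 4))
        reg = fit_age_regression(maps, pheno)
        np.testing.assert_allclose(reg.beta, 0.05, atol=1e-10)
        np.testing.assert_allclose(reg.r, 1.0, atol=1e-9)
        assert np.all(np.isfinite(reg.t)) and np.all(reg.t > 1e6)

    def test_degrees_of_freedom(self, rng):
        pheno = make_pheno(rng.uniform(18, 76, 227), rng=rng)
        reg = fit_age_regression(rng.standard_normal((227, 5)), pheno)
        assert reg.df == 224

    def test_r_t_identity(self, rng):
        pheno = make_pheno(rng.uniform(18, 76, 40), rng=rng)
        reg = fit_age_regression(rng.standard_normal((40, 200)), pheno)
        np.testing.assert_allclose(reg.r**2, reg.t**2 / (reg.t**2 + reg.df),
                                   atol=1e-10)
        assert np.all(np.sign(reg.r) == np.sign(reg.beta))

    def test_null_calibration_monte_carlo(self, rng):
        """With age independent of maps, P(|t| > t_crit(0.001)) ~ 0.001."""
        n, V, reps = 50, 100, 200
        t_crit = critical_t(0.001, n - 3)
        exceed = 0
        for _ in range(reps):
            pheno = make_pheno(rng.uniform(18, 76, n), rng=rng)
            reg = fit_age_regression(rng.standard_normal((n, V)), pheno)
            exceed += int((np.abs(reg.t) > t_crit).sum())
        frac = exceed / (reps * V)
        assert 2e-4 < frac < 3e-3

    def test_nan_propagates(self, rng):
        pheno = make_pheno(rng.uniform(18, 76, 20), rng=rng)
        maps = rng.standard_normal((20, 3))
        maps[4, 1] = np.nan
        reg = fit_age_regression(maps, pheno)
        assert np.isnan(reg.beta[1]) and np.isfinite(reg.beta[[0, 2]]).all()

    def test_rank_deficient_design(self):
        pheno = make_pheno([30.0] * 10, genders=[0] * 10)
        with pytest.raises(ValueError, match="rank"):
            fit_age_regression(np.zeros((10, 2)), pheno)


class TestCriticalT:
    def test_printed_value_at_df_224(self):
        t = critical_t(0.001, 224)
        assert 3.33 <= t <= 3.34

    def test_normal_limit(self):
        assert critical_t(0.05, 10**6) == pytest.approx(1.95996, abs=1e-4)

    def test_monotone_in_df(self):
        vals = [critical_t(0.001, df) for df in (5, 20, 100, 1000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            critical_t(1.5, 10)


class TestExtractClusters:
    def _mask(self, shape=(6, 6, 4)):
        return BrainMask(np.ones(shape, dtype=bool), [2.0, 2.0, 2.0],
                         origin_mm=np.array([10.0, 0.0, 0.0]))

    def test_singleton_cluster(self):
        mask = self._mask()
        t = np.zeros(mask.n_voxels)
        t[17] = 5.0
        clusters = extract_clusters(t, mask, t_crit=3.0)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.size == 1 and c.sign == 1 and c.peak_t == 5.0
        np.testing.assert_allclose(
            c.com_mm, mask.world_coordinates()[17]
        )

    def test_edge_touching_voxels_are_separate(self):
        mask = self._mask()
        grid = np.zeros(mask.shape)
        grid[2, 2, 1] = 5.0
        grid[3, 3, 1] = 5.0  # diagonal neighbors share only an edge
        coords = mask.coordinates()
        t = grid[coords[:, 0], coords[:, 1], coords[:, 2]]
        clusters = extract_clusters(t, mask, t_crit=3.0)
        assert sorted(c.size for c in clusters) == [1, 1]

    def test_positive_and_negative_clusters(self):
        mask = self._mask()
        grid = np.zeros(mask.shape)
        grid[1:3, 1, 1] = 6.0
        grid[4:6, 4, 2] = -6.0
        coords = mask.coordinates()
        t = grid[coords[:, 0], coords[:, 1], coords[:, 2]]
        clusters = extract_clusters(t, mask, t_crit=3.0)
        assert sorted((c.sign, c.size) for c in clusters) == [(-1, 2), (1, 2)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (5, 5, 5)
        mask = BrainMask(np.ones(shape, dtype=bool), [1, 1, 1])
        t = rng.standard_normal(mask.n_voxels) * 3
        clusters = extract_clusters(t, mask, t_crit=2.0)
        coords = mask.coordinates()
        for sign in (+1, -1):
            grid = np.zeros(shape, dtype=bool)
            sel = t >= 2.0 if sign > 0 else t <= -2.0
            grid[tuple(coords[sel].T)] = True
            expected = flood_fill_clusters(grid)
            got = {
                frozenset(map(tuple, coords[c.voxel_ids]))
                for c in clusters if c.sign == sign
            }
            assert got == expected


class TestPermutationFWE:
    def _strong_effect_data(self, rng, n=30):
        mask = BrainMask(np.ones((8, 8, 4), dtype=bool), [4, 4, 4])
        ages = rng.uniform(18, 76, n)
        pheno = make_pheno(ages, rng=rng)
        maps = rng.standard_normal((n, mask.n_voxels))
        effect = np.zeros(mask.shape)
        effect[2:5, 2:5, 1:3] = 1.0
        coords = mask.coordinates()
        eff_v = effect[coords[:, 0], coords[:, 1], coords[:, 2]]
        maps += 0.5 * np.outer(ages - ages.mean(), eff_v)
        return maps, pheno, mask

    def test_pvalue_floor(self, rng):
        maps, pheno, mask = self._strong_effect_data(rng)
        t_crit = critical_t(0.001, len(pheno) - 3)
        clusters = permutation_cluster_fwe(
            maps, pheno, mask, t_crit, n_perm=100, seed=3
        )
        assert clusters, "expected the planted cluster to form"
        assert min(c.fwe_p for c in clusters) == pytest.approx(1 / 101)

    def test_deterministic_given_seed(self, rng):
        maps, pheno, mask = self._strong_effect_data(rng)
        t_crit = critical_t(0.01, len(pheno) - 3)
        p1 = [c.fwe_p for c in permutation_cluster_fwe(
            maps, pheno, mask, t_crit, n_perm=120, seed=9)]
        p2 = [c.fwe_p for c in permutation_cluster_fwe(
            maps, pheno, mask, t_crit, n_perm=120, seed=9)]
        assert p1 == p2

    def test_pvalues_in_valid_range(self, rng):
        maps, pheno, mask = self._strong_effect_data(rng)
        t_crit = critical_t(0.01, len(pheno) - 3)
        clusters = permutation_cluster_fwe(
            maps, pheno, mask, t_crit, n_perm=100, seed=1
        )
        for c in clusters:
            assert 1 / 101 <= c.fwe_p <= 1.0

    def test_too_few_permutations(self, rng):
        maps, pheno, mask = self._strong_effect_data(rng)
        with pytest.raises(ValueError):
            permutation_cluster_fwe(maps, pheno, mask, 3.0, n_perm=50)


class TestTwoSampleTTest:
    def test_identical_groups_give_zero(self, rng):
        a = rng.standard_normal((5, 20))
        t, df = two_sample_ttest(a, a.copy())
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        assert df == 8

    def test_zero_variance_shift_is_large_finite(self):
        a = np.ones((3, 2))
        b = np.ones((4, 2))
        b[:, 1] += 1.0
        t, _ = two_sample_ttest(a, b)
        assert t[0] == 0.0
        assert np.isfinite(t[1]) and t[1] <= -1e9

    def test_matches_scipy_oracle(self, rng):
        a = rng.standard_normal((12, 50))
        b = rng.standard_normal((17, 50)) + 0.3
        t, df = two_sample_ttest(a, b)
        expected = sstats.ttest_ind(a, b, axis=0)
        np.testing.assert_allclose(t, expected.statistic, atol=1e-12)
        assert df == 27

    def test_small_group_error(self, rng):
        with pytest.raises(ValueError):
            two_sample_ttest(rng.standard_normal((1, 5)), rng.standard_normal((5, 5)))


class TestSelectSubgroups:
    def _cohort_227(self):
        ages = np.concatenate([
            np.linspace(18, 30, 124),
            np.linspace(31, 63, 27),
            np.linspace(64, 76, 76),
        ])
        return make_pheno(ages, genders=[0] * 227)

    def test_published_cohort_arithmetic(self):
        young, old, excluded = select_subgroups(
            self._cohort_227(), (18, 30), (64, 76)
        )
        assert (len(young), len(old), len(excluded)) == (124, 76, 27)

    def test_all_young(self):
        pheno = make_pheno([20, 22, 25], genders=[0, 1, 0])
        young, old, excluded = select_subgroups(pheno, (18, 30), (64, 76))
        assert len(young) == 3 and old == [] and excluded == []

    def test_closed_interval_boundary(self):
        pheno = make_pheno([30.0, 30.5], genders=[0, 1])
        young, old, excluded = select_subgroups(pheno, (18, 30), (64, 76))
        assert young == ["s0"] and excluded == ["s1"]

    def test_overlapping_ranges_error(self):
        with pytest.raises(ValueError, match="overlap"):
            select_subgroups(self._cohort_227(), (18, 40), (35, 76))


class TestOverlapRois:
    def _mask(self):
        return BrainMask(np.ones((10, 3, 3), dtype=bool), [1, 1, 1])

    def _line_clusters(self, mask, lo, hi):
        t = np.zeros(mask.n_voxels)
        coords = mask.coordinates()
        sel = (coords[:, 0] >= lo) & (coords[:, 0] < hi) & \
              (coords[:, 1] == 0) & (coords[:, 2] == 0)
        t[sel] = 5.0
        return extract_clusters(t, mask, 3.0)

    def test_disjoint_sets_empty(self):
        mask = self._mask()
        a = self._line_clusters(mask, 0, 3)
        b = self._line_clusters(mask, 6, 9)
        assert overlap_rois(a, b, mask) == []

    def test_identical_sets_idempotent(self):
        mask = self._mask()
        a = self._line_clusters(mask, 2, 7)
        out = overlap_rois(a, a, mask)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].voxel_ids, a[0].voxel_ids)

    def test_partial_overlap(self):
        mask = self._mask()
        a = self._line_clusters(mask, 0, 6)   # x = 0..5
        b = self._line_clusters(mask, 3, 10)  # x = 3..9
        out = overlap_rois(a, b, mask)
        assert len(out) == 1 and out[0].size == 3


class TestSeedCorrMap:
    def test_single_voxel_roi_reduces_to_cc_row(self, ts_factory, rng):
        from qda.qda_core import cc_row

        x = rng.standard_normal((8, 40))
        ts = ts_factory(x)
        sm = seed_corr_map([ts], roi=np.array([3]))
        row = cc_row(standardize_rows(ts), 3)
        expected = np.insert(row.values, 3, 1.0)
        np.testing.assert_allclose(sm.subject_corr[0], expected, atol=1e-10)

    def test_identical_subjects_large_finite_t(self, ts_factory, rng):
        x = rng.standard_normal((6, 30))
        subjects = [ts_factory(x.copy()) for _ in range(4)]
        sm = seed_corr_map(subjects, roi=np.array([0, 1]))
        assert np.all(np.isfinite(sm.group_t))
        assert np.abs(sm.group_t[2:]).min() >= 0  # no NaN blowups

    def test_empty_roi_error(self, ts_factory, rng):
        with pytest.raises(ValueError):
            seed_corr_map([ts_factory(rng.standard_normal((4, 30)))],
                          roi=np.array([], dtype=int))

    def test_planted_network_detected(self, ts_factory, rng):
        """Subjects share a network containing the ROI: positive group t."""
        hits = 0
        runs = 20
        for _ in range(runs):
            subjects = []
            for _s in range(8):
                latent = rng.standard_normal(60)
                x = rng.standard_normal((30, 60))
                x[:6] += 1.5 * latent
                subjects.append(ts_factory(x))
            sm = seed_corr_map(subjects, roi=np.arange(3))
            if np.all(sm.group_t[3:6] > 2.0):
                hits += 1
        assert hits >= runs * 0.95


class TestAnticorrNetwork:
    def test_conjunction_full(self):
        a = np.full(20, -0.6)
        ids, product = anticorr_network(a, a)
        assert len(ids) == 20
        np.testing.assert_allclose(product, 0.36)

    def test_mixed_signs_excluded(self):
        a = np.array([-0.6, -0.6])
        b = np.array([0.6, -0.7])
        ids, _ = anticorr_network(a, b)
        assert ids.tolist() == [1]

    def test_nonnegative_threshold_error(self):
        with pytest.raises(ValueError):
            anticorr_network(np.zeros(3), np.zeros(3), thr=0.1)


class TestRoiMeanTrend:
    def test_constant_maps_null(self, rng):
        pheno = make_pheno(rng.uniform(18, 76, 20), rng=rng)
        trend = roi_mean_trend(np.ones((20, 10)), np.arange(4), pheno)
        assert trend.beta == pytest.approx(0.0, abs=1e-12)
        assert trend.p == pytest.approx(1.0, abs=1e-6)

    def test_perfect_linear_trend(self, rng):
        ages = rng.uniform(18, 76, 25)
        pheno = make_pheno(ages, rng=rng)
        maps = np.tile((1 + 0.02 * ages)[:, None], (1, 6))
        trend = roi_mean_trend(maps, np.arange(6), pheno)
        assert trend.r == pytest.approx(1.0, abs=1e-9)
        assert trend.beta == pytest.approx(0.02, abs=1e-10)

    def test_consistent_with_voxelwise_fit(self, rng):
        ages = rng.uniform(18, 76, 30)
        pheno = make_pheno(ages, rng=rng)
        maps = rng.standard_normal((30, 12))
        roi = np.array([2, 5, 7])
        trend = roi_mean_trend(maps, roi, pheno)
        reg = fit_age_regression(maps[:, roi].mean(axis=1, keepdims=True), pheno)
        assert trend.beta == pytest.approx(reg.beta[0], abs=1e-12)
        assert trend.r == pytest.approx(reg.r[0], abs=1e-12)
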