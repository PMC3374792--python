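"""Smoothing, voxelwise GLM, cluster extraction and summary t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lapthick.groupstats import (
    DesignError,
    DesignMatrix,
    build_design,
    demographics_ttest,
    smooth_map,
    threshold_clusters,
    voxelwise_glm,
)
from lapthick.groupstats import StatMap


def _design(groups, ages=None):
    df = pd.DataFrame({"group": groups})
    if ages is not None:
        df["age"] = ages
        return build_design(df)
    return build_design(df, age_col=None)


class TestSmoothing:
    def test_constant_map_invariant(self):
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        arr = np.where(mask, 4.0, np.nan)
        out = smooth_map(arr, fwhm=8.0, mask=mask, spacing=(1, 1, 1))
        assert np.nanmax(np.abs(out[mask] - 4.0)) < 1e-9
        assert np.isnan(out[~mask]).all()

    def test_zero_fwhm_is_identity(self, rng):
        mask = np.ones((8, 8, 8), dtype=bool)
        arr = rng.normal(size=(8, 8, 8))
        out = smooth_map(arr, fwhm=0.0, mask=mask, spacing=(1, 1, 1))
        assert np.array_equal(out, arr)

    def test_kernel_ratio_matches_gaussian(self):
        """Center-to-offset ratio of a smoothed point source equals
        exp(h^2 / (2 sigma^2))."""
        n = 41
        mask = np.ones((n, n, n), dtype=bool)
        arr = np.zeros((n, n, n))
        c = n // 2
        arr[c, c, c] = 1.0
        fwhm = 4.0
        out = smooth_map(arr, fwhm=fwhm, mask=mask, spacing=(1, 1, 1))
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        expected = np.exp(1.0 / (2 * sigma**2))
        assert out[c, c, c] / out[c, c, c + 1] == pytest.approx(expected, rel=1e-3)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_map(np.zeros((4, 4, 4)), -1.0, np.ones((4, 4, 4), bool), (1, 1, 1))


class TestVoxelwiseGLM:
    def test_identical_groups_give_zero_t(self, rng):
        per_subject = [rng.normal(3.0, 0.2, size=(4, 4, 4)) for _ in range(3)]
        arrs = per_subject * 2  # both groups see the same three maps
        design = _design(["ptsd"] * 3 + ["control"] * 3, ages=[30, 40, 50, 30, 40, 50])
        stat = voxelwise_glm(arrs, design, mask=np.ones((4, 4, 4), bool), spacing=(1, 1, 1))
        assert np.nanmax(np.abs(stat.t[stat.mask])) < 1e-10

    def test_matches_hand_computed_pooled_t(self):
        """Without an age column the GLM t is the classic pooled two-sample
        t: {4,5,6} vs {6,7,8} gives -2.449."""
        vals = [4, 5, 6, 6, 7, 8]
        arrs = [np.full((3, 3, 3), float(v)) for v in vals]
        design = _design(["ptsd"] * 3 + ["control"] * 3)
        stat = voxelwise_glm(arrs, design, mask=np.ones((3, 3, 3), bool), spacing=(1, 1, 1))
        assert stat.df == 4
        expected = -2.0 / np.sqrt(2.0 / 3.0)
        assert np.allclose(stat.t[stat.mask], expected, atol=1e-10)
        assert expected == pytest.approx(-2.449, abs=1e-3)

    def test_reduces_to_pooled_t_on_random_voxels(self, rng):
        """GLM without covariate == scipy pooled t to 1e-10 everywhere."""
        n = 12
        data = rng.normal(5.0, 0.5, size=(n, 5, 5, 5))
        arrs = list(data)
        design = _design(["ptsd"] * 6 + ["control"] * 6)
        stat = voxelwise_glm(arrs, design, mask=np.ones((5, 5, 5), bool), spacing=(1, 1, 1))
        a = data[:6].reshape(6, -1)
        b = data[6:].reshape(6, -1)
        t_ref = stats.ttest_ind(a, b, axis=0, equal_var=True).statistic
        assert np.abs(stat.t[stat.mask] - t_ref).max() < 1e-10

    def test_age_covariate_matches_statsmodels(self, rng):
        """Single-voxel cross-check against an independent OLS fit."""
        import statsmodels.api as sm

        n = 14
        ages = rng.uniform(25, 55, n)
        groups = ["ptsd"] * 7 + ["control"] * 7
        y = rng.normal(4.0, 0.3, n) - 0.5 * (np.array(groups) == "ptsd") + 0.01 * ages
        arrs = [np.full((2, 2, 2), v) for v in y]
        design = _design(groups, ages=ages)
        stat = voxelwise_glm(arrs, design, mask=np.ones((2, 2, 2), bool), spacing=(1, 1, 1))
        fit = sm.OLS(y, design.X).fit()
        t_ref = fit.tvalues[1]
        assert stat.t[0, 0, 0] == pytest.approx(t_ref, abs=1e-10)
        p_ref = stats.t.sf(t_ref, n - 3)
        assert stat.p_greater[0, 0, 0] == pytest.approx(p_ref, abs=1e-12)

    def test_balanced_age_column_changes_little_under_null_slope(self, rng):
        """With a zero true age effect and balanced ages, the covariate-
        adjusted t matches the unadjusted t in distribution (simulation)."""
        n = 20
        ages = np.tile(np.linspace(25, 55, 10), 2)
        groups = ["ptsd"] * 10 + ["control"] * 10
        diffs = []
        for _ in range(200):
            y = rng.normal(0, 1, n)
            arrs = [np.full((1, 1, 1), v) for v in y]
            with_age = voxelwise_glm(arrs, _design(groups, ages=ages),
                                     mask=np.ones((1, 1, 1), bool), spacing=(1, 1, 1))
            without = voxelwise_glm(arrs, _design(groups),
                                    mask=np.ones((1, 1, 1), bool), spacing=(1, 1, 1))
            diffs.append(float(with_age.t[0, 0, 0] - without.t[0, 0, 0]))
        assert abs(np.mean(diffs)) < 0.05
        assert np.std(diffs) < 0.3

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(DesignError, match="rank"):
            DesignMatrix(
                np.column_stack([np.ones(6), np.ones(6)]),
                ["intercept", "dup"], np.array([0.0, 1.0]),
            )

    def test_zero_variance_voxels_excluded(self):
        arrs = [np.full((2, 2, 2), 1.0) for _ in range(6)]
        design = _design(["ptsd"] * 3 + ["control"] * 3)
        stat = voxelwise_glm(arrs, design, mask=np.ones((2, 2, 2), bool), spacing=(1, 1, 1))
        assert not stat.mask.any()


class TestClusters:
    def _stat_from_t(self, t_map, df=17):
        mask = np.isfinite(t_map)
        return StatMap(
            t=t_map, df=df,
            p_greater=np.where(mask, stats.t.sf(t_map, df), np.nan),
            p_less=np.where(mask, stats.t.cdf(t_map, df), np.nan),
            mask=mask, spacing=(1.0, 1.0, 1.0),
        )

    def test_empty_when_nothing_suprathreshold(self):
        stat = self._stat_from_t(np.zeros((6, 6, 6)))
        table = threshold_clusters(stat, alpha=0.001, contrast="less")
        assert len(table) == 0

    def test_two_separated_blobs(self):
        t = np.zeros((10, 10, 10))
        t[1:2, 1:7, 1:2] = -9.0   # 6 voxels + 1 more
        t[1, 7, 1] = -9.0
        t[8, 8, 8] = -9.0
        t[8, 8, 7] = -9.0
        t[8, 7, 7] = -9.0
        stat = self._stat_from_t(t)
        table = threshold_clusters(stat, alpha=0.001, connectivity=18, contrast="less")
        assert len(table) == 2
        assert sorted(table.table["size"]) == [3, 7]

    def test_corner_touching_blobs_connectivity(self):
        t = np.zeros((8, 8, 8))
        t[2, 2, 2] = 9.0
        t[3, 3, 3] = 9.0  # touches only at a corner
        stat = self._stat_from_t(t)
        t26 = threshold_clusters(stat, 0.001, 26, "greater")
        t6 = threshold_clusters(stat, 0.001, 6, "greater")
        assert len(t26) == 1
        assert len(t6) == 2

    def test_peak_is_max_abs_t_with_index_tiebreak(self):
        t = np.zeros((6, 6, 6))
        t[2, 2, 2] = -5.0
        t[2, 2, 3] = -8.0
        t[2, 3, 2] = -8.0  # tie with the above; smaller linear index wins
        stat = self._stat_from_t(t)
        table = threshold_clusters(stat, 0.001, 26, "less")
        row = table.table.iloc[0]
        assert row["peak_t"] == -8.0
        assert (row["peak_x"], row["peak_y"], row["peak_z"]) == (2, 2, 3)

    def test_mm_coordinates_from_affine(self):
        t = np.zeros((6, 6, 6))
        t[3, 1, 2] = 9.0
        stat = self._stat_from_t(t)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-4, -4, -4]
        table = threshold_clusters(stat, 0.001, 18, "greater", affine=affine)
        row = table.table.iloc[0]
        assert (row["peak_mm_x"], row["peak_mm_y"], row["peak_mm_z"]) == (2.0, -2.0, 0.0)

    def test_bonferroni_reduces_clusters(self):
        t = np.zeros((8, 8, 8))
        t[2, 2, 2] = 4.0   # p ~ 4e-4 uncorrected at df 17, dies under Bonferroni
        stat = self._stat_from_t(t)
        assert len(threshold_clusters(stat, 0.001, 18, "greater")) == 1
        assert len(threshold_clusters(stat, 0.001, 18, "greater", correction="bonferroni")) == 0


class TestDemographics:
    def test_identical_groups(self):
        t, p = demographics_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_textbook_example(self):
        t, p = demographics_ttest([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert t == pytest.approx(-3.674, abs=1e-3)
        # df = 4
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4), abs=1e-12)

    def test_antisymmetry(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(1.0, size=8)
        t1, p1 = demographics_ttest(a, b)
        t2, p2 = demographics_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_distinct_means_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            demographics_ttest([1.0, 1.0], [2.0, 2.0])


class TestBuildDesign:
    def test_missing_age_names_subject(self):
        df = pd.DataFrame(
            {"subject_id": ["s1", "s2", "s3", "s4"],
             "group": ["ptsd", "ptsd", "control", "control"],
             "age": [30.0, np.nan, 40.0, 45.0]}
        )
        with pytest.raises(DesignError, match="s2"):
            build_design(df)
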