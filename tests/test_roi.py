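"""Streamline ROIs and correlation statistics."""

import numpy as np
import pytest

from lapthick import grow_streamline_roi, mean_roi_thickness, partial_correlation, pearson
from lapthick.roi import ROIError
from hypothesis import given, settings, strategies as st


def residual_partial_r(x, y, z):
    """Independent oracle: Pearson correlation of the residuals of x and y
    after regressing each on the control."""
    x, y, z = map(np.asarray, (x, y, z))
    Z = np.column_stack([np.ones_like(z), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


class TestGrowROI:
    def test_slab_single_voxel_grows_full_column(self, slab, slab_tangent, slab_thickness):
        gm = slab.volume.gm_mask
        zs = np.unique(np.nonzero(gm)[2])
        cluster = np.zeros(slab.volume.shape, dtype=bool)
        cluster[10, 10, zs[2]] = True
        roi = grow_streamline_roi(cluster, slab_tangent, slab.volume)
        column = np.zeros_like(cluster)
        column[10, 10, zs] = True
        assert (roi.mask & column).sum() == len(zs)
        # straight streamlines: no lateral spill beyond the immediate line
        assert roi.mask.sum() <= 3 * len(zs)

    def test_roi_superset_of_cluster(self, shell, shell_tangent):
        gm = shell.volume.gm_mask
        idx = np.argwhere(gm)
        cluster = np.zeros(shell.volume.shape, dtype=bool)
        cluster[tuple(idx[2000:2010].T)] = True
        roi = grow_streamline_roi(cluster, shell_tangent, shell.volume)
        assert (roi.mask & cluster).sum() == cluster.sum()

    def test_shell_patch_grows_radial_wedge(self, shell, shell_tangent):
        """An ROI grown from a mid-radius patch spans the full shell depth."""
        r = shell.masks["radius_mm"]
        gm = shell.volume.gm_mask
        patch = gm & (np.abs(r - 10.0) < 0.3)
        idx = np.argwhere(patch)[:20]
        cluster = np.zeros(shell.volume.shape, dtype=bool)
        cluster[tuple(idx.T)] = True
        roi = grow_streamline_roi(cluster, shell_tangent, shell.volume)
        rr = r[roi.mask]
        assert rr.min() < 8.6          # reaches the inner interface region
        assert rr.max() > 11.4         # and the outer
        assert (roi.mask & ~gm).sum() == 0

    def test_deterministic_and_order_invariant(self, slab, slab_tangent):
        gm = slab.volume.gm_mask
        idx = np.argwhere(gm)[:6]
        cluster = np.zeros(slab.volume.shape, dtype=bool)
        cluster[tuple(idx.T)] = True
        a = grow_streamline_roi(cluster, slab_tangent, slab.volume)
        b = grow_streamline_roi(cluster, slab_tangent, slab.volume)
        assert np.array_equal(a.mask, b.mask)

    def test_empty_cluster_rejected(self, slab, slab_tangent):
        with pytest.raises(ROIError, match="empty"):
            grow_streamline_roi(np.zeros(slab.volume.shape, bool), slab_tangent, slab.volume)

    def test_cluster_outside_gm_rejected(self, slab, slab_tangent):
        cluster = np.zeros(slab.volume.shape, dtype=bool)
        cluster[0, 0, 0] = True  # WM corner
        with pytest.raises(ROIError, match="outside gray matter"):
            grow_streamline_roi(cluster, slab_tangent, slab.volume)


class TestMeanROIThickness:
    def test_slab_roi_mean(self, slab, slab_thickness):
        roi = slab.volume.gm_mask.copy()
        assert mean_roi_thickness(slab_thickness, roi) == pytest.approx(5.0, abs=0.5)

    def test_single_voxel_roi_exact(self, slab, slab_thickness):
        gm = np.argwhere(slab.volume.gm_mask)
        v = tuple(gm[17])
        roi = np.zeros(slab.volume.shape, dtype=bool)
        roi[v] = True
        assert mean_roi_thickness(slab_thickness, roi) == slab_thickness.thickness[v]

    def test_shell_wedge_within_5pct(self, shell, shell_tangent, shell_thickness):
        r = shell.masks["radius_mm"]
        patch = shell.volume.gm_mask & (np.abs(r - 10.0) < 0.3)
        idx = np.argwhere(patch)[:15]
        cluster = np.zeros(shell.volume.shape, dtype=bool)
        cluster[tuple(idx.T)] = True
        roi = grow_streamline_roi(cluster, shell_tangent, shell.volume)
        m = mean_roi_thickness(shell_thickness, roi)
        assert abs(m - 4.0) / 4.0 < 0.05

    def test_empty_intersection_rejected(self, slab, slab_thickness):
        roi = np.zeros(slab.volume.shape, dtype=bool)
        roi[0, 0, 0] = True  # WM voxel: not valid in the map
        with pytest.raises(ROIError, match="ROI"):
            mean_roi_thickness(slab_thickness, roi)


class TestPearson:
    def test_perfect_correlation(self):
        r = pearson([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        r = pearson([1, 2, 3, 4], [4, 3, 2, 1])
        assert r.r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 1.5, var_x = 1, var_y = 14/6 -> r = 1.5/sqrt(14/6)
        res = pearson([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(0.98198, abs=1e-5)
        assert res.n == 3

    def test_constant_input_rejected(self):
        with pytest.raises(ROIError):
            pearson([1, 1, 1], [1, 2, 3])


class TestPartialCorrelation:
    def test_uncorrelated_control_reduces_to_pearson(self):
        # control orthogonal (in-sample) to both x and y
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([2.0, -2.0, 2.5, -2.5])
        z = np.array([1.0, 1.0, -1.0, -1.0])
        res = partial_correlation(x, y, z)
        ref = pearson(x, y)
        assert res.r == pytest.approx(ref.r, abs=1e-12)

    def test_identical_variables_give_one(self):
        x = [1.0, 2.0, 4.0, 8.0, 9.0]
        z = [1.0, 3.0, 2.0, 5.0, 4.0]
        assert partial_correlation(x, x, z).r == pytest.approx(1.0)

    def test_closed_form_matches_residual_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        z = [1, 1, 2, 2, 3]
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(residual_partial_r(x, y, z), abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        x = [1.0, 2.0, 3.0, 4.0, 5.0, 7.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        z = [1.0, 1.0, 2.0, 2.0, 3.0, 4.0]
        res = partial_correlation(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_formula_residual_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        z = 0.5 * x + rng.normal(size=n)
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(residual_partial_r(x, y, z), abs=1e-10)
        assert -1 <= res.r <= 1
        assert 0 <= res.p <= 1

    def test_constant_control_rejected(self):
        with pytest.raises(ROIError, match="constant"):
            partial_correlation([1, 2, 3, 4], [2, 3, 1, 4], [1, 1, 1, 1])

    def test_collinear_control_rejected(self):
        with pytest.raises(ROIError, match="degenerate|collinear"):
            partial_correlation([1, 2, 3, 4], [2, 3, 1, 4], [2, 4, 6, 8])
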