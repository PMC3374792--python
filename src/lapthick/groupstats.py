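"""Voxelwise group comparison of thickness maps.

Smoothing, the general linear model, cluster extraction, and cohort-level
summary t-tests.  The model per voxel is ordinary least squares on
[intercept, group, age] with planned one-sided contrasts in both
directions (affected > unaffected and affected < unaffected), thresholded
at an uncorrected voxel-level p and grouped into connected clusters —
mirroring the conventional SPM-style two-sample design with a nuisance
covariate.  No multiple-comparison correction is applied by default; an
optional Bonferroni/FDR adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .thickness import ThicknessMap


class DesignError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """One row per subject: intercept, group indicator (affected=1), age."""

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2:
            raise DesignError("design matrix must be 2D")
        if len(self.columns) != self.X.shape[1]:
            raise DesignError("column names do not match design width")
        if self.contrast.shape != (self.X.shape[1],):
            raise DesignError("contrast length must equal the number of columns")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise DesignError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def df(self) -> int:
        return self.n - self.X.shape[1]


def build_design(
    covariates: pd.DataFrame,
    group_col: str = "group",
    affected: str = "ptsd",
    age_col: str | None = "age",
) -> DesignMatrix:
    """Design from a covariate table; contrast targets the group column.

    The group indicator is 1 for the affected group.  Pass
    ``age_col=None`` for the plain two-sample design.
    """
    g = (covariates[group_col].astype(str).str.lower() == affected).astype(float).to_numpy()
    cols = [np.ones(len(covariates)), g]
    names = ["intercept", "group"]
    if age_col is not None:
        if covariates[age_col].isna().any():
            missing = covariates.loc[covariates[age_col].isna()]
            ids = missing.index.tolist()
            if "subject_id" in missing:
                ids = missing["subject_id"].tolist()
            raise DesignError(f"missing {age_col} for subject(s) {ids}")
        cols.append(covariates[age_col].to_numpy(dtype=float))
        names.append(age_col)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X, names, contrast)


@dataclass
class StatMap:
    """Voxelwise t with one-sided p for both planned contrasts.

    ``p_greater`` tests contrast'beta > 0 (affected > unaffected when the
    contrast picks the group column), ``p_less`` the reverse.
    """

    t: np.ndarray
    df: int
    p_greater: np.ndarray
    p_less: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None


@dataclass
class ClusterTable:
    """Connected suprathreshold components with size and peak."""

    table: pd.DataFrame                  # cluster_id, size, peak voxel/mm, peak_t
    members: dict[int, np.ndarray] = field(default_factory=dict)
    label_map: np.ndarray | None = None

    def __len__(self):
        return len(self.table)


def _as_array_mask(m, mask=None, spacing=None):
    if isinstance(m, ThicknessMap):
        return m.thickness, (mask if mask is not None else m.valid), m.spacing
    if mask is None or spacing is None:
        raise ValueError("raw arrays require an explicit mask and spacing")
    return np.asarray(m, dtype=float), mask, spacing


def smooth_map(m, fwhm: float, mask=None, spacing=None) -> np.ndarray:
    """Masked-normalized Gaussian smoothing of a thickness map.

    Convolves ``map*mask`` and ``mask`` with sigma = FWHM / (2 sqrt(2 ln 2))
    per axis (in mm) and divides, which prevents the zero exterior from
    dragging values down at the GM boundary.  Voxels outside the mask are
    NaN in the result.  ``fwhm=0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    arr, msk, h = _as_array_mask(m, mask, spacing)
    if fwhm == 0:
        return np.where(msk, arr, np.nan)
    sigma_vox = [fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / hi for hi in h]
    data = np.where(msk, arr, 0.0)
    num = ndimage.gaussian_filter(data, sigma_vox)
    den = ndimage.gaussian_filter(msk.astype(float), sigma_vox)
    out = np.full(arr.shape, np.nan)
    good = msk & (den > 1e-12)
    out[good] = num[good] / den[good]
    return out


def voxelwise_glm(maps, design: DesignMatrix, mask=None, spacing=None) -> StatMap:
    """Per-voxel OLS fit and contrast t statistic.

    ``maps`` is a list of smoothed maps (arrays or ThicknessMaps, one per
    design row).  The analysis mask is the intersection of the given/valid
    masks with all-finite data; voxels with zero residual variance under a
    nonzero contrast estimate are excluded (t undefined).
    """
    arrays = []
    masks = []
    h = spacing
    for m in maps:
        if isinstance(m, ThicknessMap):
            arrays.append(m.thickness)
            masks.append(m.valid)
            h = m.spacing
        else:
            arrays.append(np.asarray(m, dtype=float))
    if len(arrays) != design.n:
        raise DesignError(
            f"{len(arrays)} maps but design has {design.n} rows"
        )
    if design.n < 3 or design.df < 1:
        raise DesignError("need at least 3 subjects and 1 residual degree of freedom")
    if h is None:
        raise ValueError("spacing required when passing raw arrays")
    stack = np.stack(arrays)                       # (n, X, Y, Z)
    common = np.isfinite(stack).all(axis=0)
    if mask is not None:
        common &= mask
    for mk in masks:
        common &= mk
    X = design.X
    c = design.contrast
    n, p = X.shape
    df = n - p
    Y = stack[:, common]                            # (n, V)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    cvar = float(c @ XtX_inv @ c)
    se = np.sqrt(sigma2 * cvar)
    eff = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, eff / np.where(se > 0, se, 1.0), np.nan)
    finite = np.isfinite(tvals)

    t_map = np.full(common.shape, np.nan)
    pg_map = np.full(common.shape, np.nan)
    pl_map = np.full(common.shape, np.nan)
    idx = np.nonzero(common)
    t_map[idx] = tvals
    pg = stats.t.sf(tvals, df)
    pl = stats.t.cdf(tvals, df)
    pg_map[idx] = pg
    pl_map[idx] = pl
    final_mask = common.copy()
    final_mask[idx] = finite
    t_map[~final_mask] = np.nan
    return StatMap(
        t=t_map, df=df, p_greater=pg_map, p_less=pl_map, mask=final_mask,
        spacing=tuple(h),
    )


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_clusters(
    stat: StatMap,
    alpha: float = 0.001,
    connectivity: int = 18,
    contrast: str = "less",
    affine: np.ndarray | None = None,
    correction: str | None = None,
) -> ClusterTable:
    """Group suprathreshold voxels into connected clusters.

    ``contrast`` selects the planned direction: 'less' uses the one-sided
    p for affected < unaffected, 'greater' the opposite.  Peaks are the
    maximum |t| member, ties broken by smallest linear index.  ``correction``
    optionally Bonferroni- or BH-FDR-adjusts the voxel p values first
    (off by default).
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    if contrast not in ("less", "greater"):
        raise ValueError("contrast must be 'less' or 'greater'")
    p = stat.p_less if contrast == "less" else stat.p_greater
    pv = p.copy()
    if correction is not None:
        inside = stat.mask
        vals = pv[inside]
        m = vals.size
        if correction == "bonferroni":
            vals = np.minimum(vals * m, 1.0)
        elif correction == "fdr":
            order = np.argsort(vals)
            ranked = vals[order] * m / (np.arange(m) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            adj = np.empty_like(vals)
            adj[order] = np.minimum(ranked, 1.0)
            vals = adj
        else:
            raise ValueError("correction must be None, 'bonferroni' or 'fdr'")
        pv[inside] = vals
    supra = stat.mask & (pv < alpha)
    lab, ncl = ndimage.label(supra, structure=_CONNECTIVITY_STRUCTS[connectivity])
    rows = []
    members = {}
    if affine is None:
        affine = np.diag([*stat.spacing, 1.0])
    for cid in range(1, ncl + 1):
        vox = np.argwhere(lab == cid)
        tvals = np.abs(stat.t[tuple(vox.T)])
        lin = np.ravel_multi_index(vox.T, stat.t.shape)
        best = np.lexsort((lin, -tvals))[0]
        peak = vox[best]
        peak_mm = (affine[:3, :3] @ peak + affine[:3, 3])
        rows.append(
            {
                "cluster_id": cid,
                "size": len(vox),
                "peak_x": int(peak[0]), "peak_y": int(peak[1]), "peak_z": int(peak[2]),
                "peak_mm_x": peak_mm[0], "peak_mm_y": peak_mm[1], "peak_mm_z": peak_mm[2],
                "peak_t": float(stat.t[tuple(peak)]),
            }
        )
        members[cid] = vox
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size", "peak_x", "peak_y", "peak_z",
            "peak_mm_x", "peak_mm_y", "peak_mm_z", "peak_t",
        ],
    )
    if len(table):
        table = table.sort_values("size", ascending=False).reset_index(drop=True)
    return ClusterTable(table=table, members=members, label_map=lab)


def demographics_ttest(group_a, group_b):
    """Pooled-variance two-sample t-test for cohort summary variables.

    Returns ``(t, p)`` with two-sided p and df = nA + nB - 2.  Raises on
    zero pooled variance (the statistic is undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
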