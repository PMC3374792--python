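"""Streamline-grown ROIs and severity correlation.

A significant cluster marks only part of the cortical column it lies in;
because thickness is constant along a streamline, every voxel on the
streamlines through the cluster carries the same information.  The ROI
stage therefore grows each cluster along the tangent field to the full
set of streamline voxels between the two interfaces, takes the mean
thickness over that region per subject, and correlates it with symptom
severity — Pearson's partial correlation controlling for age (cortical
thickness declines slowly with age), or plain Pearson when the age effect
is deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .streamlines import trace_batch
from .thickness import TangentField, ThicknessMap
from .volume import TissueVolume


class ROIError(ValueError):
    pass


@dataclass
class ROIMask:
    mask: np.ndarray
    source_cluster_id: int | None = None
    n_cluster_voxels: int = 0
    step_mm: float | None = None


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    controlled: tuple[str, ...] = ()


def grow_streamline_roi(
    cluster: np.ndarray,
    tangent: TangentField,
    vol: TissueVolume,
    step_mm: float | None = None,
    cluster_id: int | None = None,
) -> ROIMask:
    """All GM voxels on streamlines through a cluster, plus the cluster.

    Each cluster voxel's streamline is traced to both interfaces; every GM
    voxel any path's samples fall in (nearest-voxel membership at a
    0.25*min(spacing) step, so no voxel along a path can be skipped) joins
    the ROI.  Deterministic and independent of voxel processing order (the
    ROI is a union).
    """
    cluster = np.asarray(cluster, dtype=bool)
    if cluster.shape != vol.shape:
        raise ROIError("cluster mask shape does not match the volume")
    if not cluster.any():
        raise ROIError("cluster mask is empty")
    if (cluster & ~vol.gm_mask).any():
        raise ROIError("cluster mask extends outside gray matter")
    h = np.asarray(vol.spacing)
    if step_mm is None:
        step_mm = 0.25 * float(h.min())
    starts = np.argwhere(cluster) * h
    roi = cluster.copy()
    for direction in ("up", "down"):
        _, _, visited = trace_batch(
            tangent, vol, starts, direction, step_mm, record_visited=True
        )
        for path in visited:
            ok = ((path >= 0) & (path < np.asarray(vol.shape))).all(axis=1)
            v = path[ok]
            roi[v[:, 0], v[:, 1], v[:, 2]] = True
    roi &= vol.gm_mask
    roi |= cluster
    return ROIMask(
        mask=roi,
        source_cluster_id=cluster_id,
        n_cluster_voxels=int(cluster.sum()),
        step_mm=step_mm,
    )


def mean_roi_thickness(thmap: ThicknessMap, roi: ROIMask | np.ndarray) -> float:
    """Arithmetic mean thickness over the ROI's valid voxels."""
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    sel = mask & thmap.valid & np.isfinite(thmap.thickness)
    if not sel.any():
        raise ROIError("ROI does not intersect the valid thickness map")
    return float(thmap.thickness[sel].mean())


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation; two-sided p via t with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ROIError("pearson needs matched samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ROIError("correlation undefined for a constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p=p, n=n)


def partial_correlation(x, y, control, control_name: str = "age") -> CorrelationResult:
    """First-order partial correlation of x and y controlling one covariate.

    Closed form

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

    which equals the Pearson correlation of the residuals of x and y each
    regressed on the control.  Two-sided p from t = r sqrt((n-3)/(1-r^2))
    with df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    n = x.size
    if n < 4 or y.size != n or z.size != n:
        raise ROIError("partial correlation needs matched samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ROIError("correlation undefined for a constant input")
    if np.ptp(z) == 0:
        raise ROIError("control covariate is constant")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ROIError("control is collinear with an input: partial correlation degenerate")
    r = float((r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 3) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 3))
    return CorrelationResult(r=r, p=p, n=n, controlled=(control_name,))
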