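"""Explicit streamline tracing through the unit tangent field.

Integral curves of the tangent field connect the two cortical interfaces;
their arc length *is* the thickness, so an explicit 4th-order Runge-Kutta
tracer over the trilinearly interpolated field serves as the independent
oracle for the PDE transport solution, and as the engine behind the
sulcus-correction and streamline-ROI stages.

Paths terminate where they cross the cortical boundary — the 0.5-level
set of the interpolated GM boundary field (the voxel-face staircase for a
binary segmentation, sub-voxel where probability maps localize the
interface) — with the final segment clipped to the crossing by bisection.
This is the same interface the Laplace stencil and the length-transport
ghost values use, so tracer and PDE measure the same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .thickness import TangentField
from .volume import CSF, GM, WM, TissueVolume

REACHED_S = "reached_S"            # crossed the outer (GM/CSF) interface
REACHED_SPRIME = "reached_Sprime"  # crossed the inner (GM/WM) interface
LEFT_GRID = "left_grid"
MAX_STEPS = "max_steps"

_REASON_CODES = {0: MAX_STEPS, 1: REACHED_S, 2: REACHED_SPRIME, 3: LEFT_GRID}


@dataclass
class StreamlinePath:
    """One traced path: ordered sub-voxel mm points and its arc length."""

    points: np.ndarray           # (n, 3) mm coordinates
    arc_length: float
    termination: str


def _extended_vectors(tangent: TangentField, vol: TissueVolume, rim: int = 2):
    """Copy each non-GM rim voxel's tangent from its nearest GM voxel.

    Trilinear interpolation near the boundary would otherwise mix in zeros
    and bend paths spuriously just before termination.
    """
    mask = tangent.mask
    vecs = np.where(mask[..., None], tangent.vectors, 0.0)
    ring = ndimage.binary_dilation(mask, iterations=rim) & ~mask
    if ring.any():
        _, idx = ndimage.distance_transform_edt(~mask, return_indices=True)
        src = tuple(i[ring] for i in idx)
        vecs[ring] = tangent.vectors[src]
    return vecs


class _Field:
    """Trilinear interpolators over the tangent and boundary fields."""

    def __init__(self, tangent: TangentField, vol: TissueVolume):
        self.vecs = _extended_vectors(tangent, vol)
        self.h = np.asarray(vol.spacing, dtype=float)
        self.bfield = vol.gm_boundary_field().astype(float)
        self.wm_ind = (vol.labels == WM).astype(float)
        self.csf_ind = (vol.labels == CSF).astype(float)
        self.shape = np.asarray(vol.shape)

    def _coords(self, pos_mm):
        return (pos_mm / self.h).T

    def unit(self, pos_mm: np.ndarray) -> np.ndarray:
        coords = self._coords(pos_mm)
        out = np.empty_like(pos_mm)
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.vecs[..., c], coords, order=1, mode="nearest"
            )
        norm = np.linalg.norm(out, axis=1)
        ok = norm > 1e-6
        out[ok] /= norm[ok, None]
        out[~ok] = 0.0
        return out

    def inside(self, pos_mm: np.ndarray) -> np.ndarray:
        """Interpolated boundary field >= 0.5 and within the grid."""
        coords = self._coords(pos_mm)
        b = ndimage.map_coordinates(self.bfield, coords, order=1, mode="constant")
        in_grid = ((pos_mm >= -0.5 * self.h) &
                   (pos_mm <= (self.shape - 0.5) * self.h)).all(axis=1)
        return (b >= 0.5) & in_grid

    def exit_reason(self, pos_mm: np.ndarray) -> np.ndarray:
        """Classify a boundary crossing: 1 reached S, 2 reached S', 3 left grid."""
        coords = self._coords(pos_mm)
        w = ndimage.map_coordinates(self.wm_ind, coords, order=1, mode="constant")
        c = ndimage.map_coordinates(self.csf_ind, coords, order=1, mode="constant")
        out = np.full(pos_mm.shape[0], 3, dtype=np.int8)
        out[(c >= w) & (c > 0.05)] = 1
        out[(w > c) & (w > 0.05)] = 2
        return out


def trace_batch(
    tangent: TangentField,
    vol: TissueVolume,
    starts_mm: np.ndarray,
    direction: str = "up",
    step_mm: float | None = None,
    max_steps: int = 4000,
    record_visited: bool = False,
):
    """Trace many streamlines at once.

    Parameters
    ----------
    starts_mm : (M, 3) array
        Start points in mm (must lie inside GM).
    direction : 'up' | 'down'
        'up' follows +T toward the CSF surface S, 'down' follows -T toward
        the WM surface S'.
    step_mm : float
        RK4 step; defaults to 0.25 * min(spacing).
    record_visited : bool
        Also return, per path, the ordered unique voxel indices the path
        samples pass through (nearest-voxel membership).

    Returns
    -------
    lengths : (M,) arc lengths in mm
    reasons : list of str termination reasons
    visited : list of (n_i, 3) int arrays (only if ``record_visited``)
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    h = np.asarray(vol.spacing, dtype=float)
    if step_mm is None:
        step_mm = 0.25 * float(h.min())
    sign = 1.0 if direction == "up" else -1.0
    fields = _Field(tangent, vol)

    pos = np.array(starts_mm, dtype=float).reshape(-1, 3)
    M = pos.shape[0]
    vox0 = np.rint(pos / h).astype(int)
    in_grid = ((vox0 >= 0) & (vox0 < np.asarray(vol.shape))).all(axis=1)
    if not in_grid.all():
        raise ValueError("a start point lies outside the grid")
    lab0 = vol.labels[vox0[:, 0], vox0[:, 1], vox0[:, 2]]
    if not (lab0 == GM).all():
        bad = int(np.nonzero(lab0 != GM)[0][0])
        raise ValueError(f"start point {pos[bad]} mm is not inside gray matter")

    lengths = np.zeros(M)
    reason = np.zeros(M, dtype=np.int8)  # 0 = still running / max_steps
    active = np.ones(M, dtype=bool)
    visited: list[list] | None = None
    if record_visited:
        visited = [[tuple(v)] for v in vox0]

    for _ in range(max_steps):
        if not active.any():
            break
        p = pos[active]
        k1 = sign * fields.unit(p)
        k2 = sign * fields.unit(p + 0.5 * step_mm * k1)
        k3 = sign * fields.unit(p + 0.5 * step_mm * k2)
        k4 = sign * fields.unit(p + step_mm * k3)
        disp = (step_mm / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        p_new = p + disp
        seg = np.linalg.norm(disp, axis=1)

        still_in = fields.inside(p_new)
        crossed = ~still_in
        stalled = seg < 1e-9

        idx_active = np.nonzero(active)[0]
        ok = still_in & ~stalled
        adv = idx_active[ok]
        pos[adv] = p_new[ok]
        lengths[adv] += seg[ok]
        if record_visited:
            vv = np.rint(p_new[ok] / h).astype(int)
            for j, i_glob in enumerate(adv):
                t = tuple(vv[j])
                if t != visited[i_glob][-1]:
                    visited[i_glob].append(t)

        if crossed.any():
            ci = np.nonzero(crossed)[0]
            a = p[ci]
            b = p_new[ci]
            lo = np.zeros(len(ci))
            hi = np.ones(len(ci))
            for _bi in range(16):
                mid = 0.5 * (lo + hi)
                pm = a + (b - a) * mid[:, None]
                is_in = fields.inside(pm)
                lo = np.where(is_in, mid, lo)
                hi = np.where(is_in, hi, mid)
            t_cross = 0.5 * (lo + hi)
            g = idx_active[ci]
            lengths[g] += seg[ci] * t_cross
            end = a + (b - a) * t_cross[:, None]
            pos[g] = end
            probe = end + (b - a) * (0.05 / np.maximum(seg[ci], 1e-12))[:, None]
            reason[g] = fields.exit_reason(probe)
            active[g] = False
        if stalled.any():
            g = idx_active[np.nonzero(stalled & ~crossed)[0]]
            reason[g] = 0
            active[g] = False

    reasons = [_REASON_CODES[c] for c in reason]
    if record_visited:
        vis = [np.array(v, dtype=int) for v in visited]
        return lengths, reasons, vis
    return lengths, reasons


def trace_streamline(
    tangent: TangentField,
    vol: TissueVolume,
    start_mm,
    step_mm: float | None = None,
    direction: str = "up",
    max_steps: int = 4000,
) -> StreamlinePath:
    """Trace a single streamline, keeping the full sequence of points."""
    h = np.asarray(vol.spacing, dtype=float)
    if step_mm is None:
        step_mm = 0.25 * float(h.min())
    sign = 1.0 if direction == "up" else -1.0
    fields = _Field(tangent, vol)

    p = np.asarray(start_mm, dtype=float)
    v0 = np.rint(p / h).astype(int)
    if (v0 < 0).any() or (v0 >= np.asarray(vol.shape)).any() or vol.labels[tuple(v0)] != GM:
        raise ValueError(f"start point {p} mm is not inside gray matter")
    pts = [p.copy()]
    length = 0.0
    termination = MAX_STEPS
    for _ in range(max_steps):
        q = p[None, :]
        k1 = sign * fields.unit(q)
        k2 = sign * fields.unit(q + 0.5 * step_mm * k1)
        k3 = sign * fields.unit(q + 0.5 * step_mm * k2)
        k4 = sign * fields.unit(q + step_mm * k3)
        disp = ((step_mm / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4))[0]
        seg = float(np.linalg.norm(disp))
        if seg < 1e-9:
            break
        p_new = p + disp
        if not fields.inside(p_new[None, :])[0]:
            lo, hi = 0.0, 1.0
            for _bi in range(16):
                mid = 0.5 * (lo + hi)
                if fields.inside((p + disp * mid)[None, :])[0]:
                    lo = mid
                else:
                    hi = mid
            t = 0.5 * (lo + hi)
            p_end = p + disp * t
            pts.append(p_end)
            length += seg * t
            probe = (p_end + disp * (0.05 / seg))[None, :]
            termination = _REASON_CODES[int(fields.exit_reason(probe)[0])]
            break
        p = p_new
        pts.append(p.copy())
        length += seg
    return StreamlinePath(np.array(pts), length, termination)


def streamline_thickness(
    tangent: TangentField,
    vol: TissueVolume,
    starts_mm: np.ndarray,
    step_mm: float | None = None,
    max_steps: int = 4000,
):
    """Oracle thickness at each start: up-length + down-length.

    Returns (thickness, up_ok & down_ok) where ok means the trace reached
    the proper interface rather than leaving the grid or stalling.
    """
    up, r_up = trace_batch(tangent, vol, starts_mm, "up", step_mm, max_steps)
    dn, r_dn = trace_batch(tangent, vol, starts_mm, "down", step_mm, max_steps)
    ok = np.array(
        [ru == REACHED_S and rd == REACHED_SPRIME for ru, rd in zip(r_up, r_dn)]
    )
    return up + dn, ok
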