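"""Labeled tissue volumes.

The container for segmented anatomy: a 3D integer label grid
(background / CSF / gray matter / white matter), per-axis voxel spacing in
millimetres, and optional per-tissue probability maps.  The two cortical
boundary surfaces live implicitly in the labels: S (GM/CSF interface, where
the Laplace potential is held at 1) and S' (GM/WM interface, held at 0).

Voxel indices are 0-based; world coordinates in mm come from the affine,
which defaults to ``diag(spacing)`` with the origin at voxel (0,0,0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

BACKGROUND = 0
CSF = 1
GM = 2
WM = 3

LABEL_NAMES = {BACKGROUND: "background", CSF: "csf", GM: "gm", WM: "wm"}

#: 6-connectivity structuring element (faces only).
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class VolumeError(ValueError):
    """Raised for malformed tissue volumes."""


@dataclass
class TissueVolume:
    """A segmented 3D volume with spacing and optional probability maps.

    Parameters
    ----------
    labels : ndarray of int, shape (X, Y, Z)
        Tissue label per voxel: 0 background, 1 CSF, 2 gray matter, 3 white
        matter.
    spacing : tuple of 3 floats
        Voxel edge length per axis, in mm.  Anisotropic spacing is allowed.
    probabilities : dict or None
        Optional per-tissue probability grids keyed ``'csf'``, ``'gm'``,
        ``'wm'``, each the same shape as ``labels`` with values in [0, 1].
    affine : ndarray (4, 4) or None
        Voxel-to-mm transform.  Defaults to ``diag(spacing)``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    probabilities: dict[str, np.ndarray] | None = None
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeError(f"labels must be 3D, got shape {self.labels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive floats, got {self.spacing}")
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, CSF, GM, WM])
        if bad.size:
            idx = np.argwhere(np.isin(self.labels, bad))[0]
            raise VolumeError(
                f"unknown label value(s) {bad.tolist()} (first at voxel {tuple(idx)}); "
                f"expected 0=background, 1=CSF, 2=GM, 3=WM"
            )
        if self.probabilities is not None:
            for key, p in self.probabilities.items():
                p = np.asarray(p, dtype=float)
                if p.shape != self.labels.shape:
                    raise VolumeError(
                        f"probability map '{key}' shape {p.shape} != labels {self.labels.shape}"
                    )
                if p.min() < -1e-9 or p.max() > 1 + 1e-9:
                    raise VolumeError(f"probability map '{key}' outside [0, 1]")
                self.probabilities[key] = p
            total = sum(self.probabilities.values())
            if total.max() > 1 + 1e-6:
                raise VolumeError("tissue probabilities sum to more than 1")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise VolumeError("affine must be 4x4")

    # -- masks ------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels == GM

    @property
    def wm_mask(self) -> np.ndarray:
        return self.labels == WM

    @property
    def csf_mask(self) -> np.ndarray:
        return self.labels == CSF

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (…, 3) to mm coordinates via the affine."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pos @ inv[:3, :3].T + inv[:3, 3]

    def gm_boundary_field(self) -> np.ndarray:
        """GM membership field whose 0.5-level set is the cortical boundary.

        The binary GM indicator, refined by the GM probability map where one
        exists: partial-volume probabilities place the interpolated 0.5
        crossing sub-voxel between centers instead of on the voxel face.
        Values are clamped to agree with the labels (a voxel *labeled* GM
        stays above 0.5 even if its probability dissents, e.g. a
        mis-segmented sulcal sheet), so the field always respects the
        segmentation the solver runs on.  All boundary-sensitive stages —
        the Laplace stencil arms, the length-transport ghost values and
        streamline termination — share this one field, keeping their
        notions of the interface mutually consistent.
        """
        ind = (self.labels == GM).astype(float)
        if self.probabilities is None or "gm" not in self.probabilities:
            return ind
        p = self.probabilities["gm"]
        eps = 1e-3
        return np.where(ind > 0, np.maximum(p, 0.5 + eps), np.minimum(p, 0.5 - eps))

    # -- connectivity ------------------------------------------------------
    def reachable_gm(self) -> tuple[np.ndarray, np.ndarray]:
        """Split GM into voxels reachable from both boundaries and islands.

        A GM voxel is *reachable* when its 6-connected GM component contains
        at least one voxel face-adjacent to WM and at least one face-adjacent
        to CSF; the Laplace problem is well-posed only there.  Returns
        ``(reachable_mask, unreachable_mask)``.
        """
        gm = self.gm_mask
        comp, ncomp = ndimage.label(gm, structure=STRUCT_6)
        if ncomp == 0:
            return np.zeros_like(gm), np.zeros_like(gm)
        near_wm = gm & ndimage.binary_dilation(self.wm_mask, structure=STRUCT_6)
        near_csf = gm & ndimage.binary_dilation(self.csf_mask, structure=STRUCT_6)
        touch_wm = np.zeros(ncomp + 1, dtype=bool)
        touch_csf = np.zeros(ncomp + 1, dtype=bool)
        touch_wm[np.unique(comp[near_wm])] = True
        touch_csf[np.unique(comp[near_csf])] = True
        good = touch_wm & touch_csf
        good[0] = False
        reach = good[comp]
        return reach, gm & ~reach

    def copy(self) -> "TissueVolume":
        probs = None
        if self.probabilities is not None:
            probs = {k: v.copy() for k, v in self.probabilities.items()}
        return TissueVolume(
            self.labels.copy(), self.spacing, probs, self.affine.copy()
        )
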