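"""Buried-sulcus detection and segmentation correction.

Partial-volume effects can erase the thin CSF sheet of a buried sulcus
during segmentation, fusing the opposing gray-matter banks; the fused
column then returns wildly inflated thickness (the streamlines must detour
to the nearest true CSF).  Healthy cortex stays under about 5 mm, so
implausibly thick regions flag candidate fusions:

1. *Detect* — region growing seeded at GM voxels whose thickness exceeds
   the plausibility threshold, spreading through 26-connected suprathreshold
   GM with the growth direction held within a cone around the local tangent
   (streamlines run across the fused banks, so true fusions extend along
   the tangent; isotropic noise blobs do not).
2. *Correct* — along each suspect voxel's streamline, the voxel with the
   lowest GM probability inside the suspect region is the segmentation's
   least-confident call; it is relabeled to its best non-GM tissue (CSF at
   an erased sheet).  One voxel per streamline reopens the sulcus with a
   minimal sheet instead of carving wide channels.
3. *Recompute* thickness on the corrected volume and report before/after.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from .streamlines import trace_batch
from .thickness import TangentField, ThicknessMap, tangent_field, thickness_pipeline
from .volume import CSF, WM, TissueVolume


@dataclass
class SulcusCorrectionReport:
    threshold_mm: float
    n_gm_before: int
    n_gm_after: int
    n_above_before: int
    n_above_after: int
    n_suspect: int
    n_relabeled: int
    suspect_mask: np.ndarray | None = None
    relabeled_mask: np.ndarray | None = None

    @property
    def fraction_above_before(self) -> float:
        return self.n_above_before / max(self.n_gm_before, 1)

    @property
    def fraction_above_after(self) -> float:
        return self.n_above_after / max(self.n_gm_after, 1)

    def to_dict(self) -> dict:
        return {
            "threshold_mm": self.threshold_mm,
            "n_gm_before": self.n_gm_before,
            "n_gm_after": self.n_gm_after,
            "n_above_before": self.n_above_before,
            "n_above_after": self.n_above_after,
            "fraction_above_before": self.fraction_above_before,
            "fraction_above_after": self.fraction_above_after,
            "n_suspect": self.n_suspect,
            "n_relabeled": self.n_relabeled,
        }


_OFFSETS_26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


def detect_suspect_regions(
    thmap: ThicknessMap,
    vol: TissueVolume,
    tangent: TangentField | None = None,
    threshold_mm: float = 5.0,
    cone_degrees: float = 60.0,
) -> np.ndarray:
    """Region-grow implausibly thick GM along the tangent direction.

    Seeds are GM voxels with thickness above ``threshold_mm``; growth
    proceeds through 26-connected GM voxels that are also above threshold,
    and only in directions within ``cone_degrees`` of the local tangent
    (sign-agnostic: a sulcus is crossed in both directions).  Returns the
    union of grown regions as a boolean mask (possibly empty).
    """
    gm = vol.gm_mask
    thick = np.where(np.isfinite(thmap.thickness), thmap.thickness, -np.inf)
    above = gm & thmap.valid & (thick > threshold_mm)
    if not above.any():
        return np.zeros(vol.shape, dtype=bool)

    h = np.asarray(vol.spacing)
    step_dirs = _OFFSETS_26 * h  # mm-space step vectors
    step_dirs = step_dirs / np.linalg.norm(step_dirs, axis=1, keepdims=True)
    cos_min = np.cos(np.deg2rad(cone_degrees))

    grown = np.zeros(vol.shape, dtype=bool)
    grown[above] = True  # every seed belongs to the region
    shape = np.asarray(vol.shape)
    if tangent is None:
        return grown

    visited = above.copy()
    queue = deque(map(tuple, np.argwhere(above)))
    vecs = tangent.vectors
    while queue:
        v = queue.popleft()
        tv = vecs[v]
        for off, d in zip(_OFFSETS_26, step_dirs):
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if not ((0 <= w[0] < shape[0]) and (0 <= w[1] < shape[1]) and (0 <= w[2] < shape[2])):
                continue
            if visited[w] or not above[w]:
                continue
            if abs(float(np.dot(tv, d))) < cos_min:
                continue
            visited[w] = True
            grown[w] = True
            queue.append(w)
    return grown


def correct_segmentation(
    vol: TissueVolume,
    suspect: np.ndarray,
    tangent: TangentField,
    step_mm: float | None = None,
) -> tuple[TissueVolume, np.ndarray]:
    """Reopen fused sulci: relabel the least-GM-probable voxel per streamline.

    For each suspect voxel the streamline is traced both ways; among the
    path voxels inside the suspect mask, the one with minimum GM
    probability (ties: first from the WM end) is relabeled to its highest
    non-GM tissue probability.  Without probability maps a label-only
    fallback relabels the in-mask path midpoint to CSF, with a warning.
    Returns ``(corrected_volume, relabeled_mask)``; the input is untouched
    and relabeling never leaves the suspect mask.
    """
    suspect = np.asarray(suspect, dtype=bool)
    out = vol.copy()
    relabeled = np.zeros(vol.shape, dtype=bool)
    if not suspect.any():
        return out, relabeled

    have_probs = vol.probabilities is not None and "gm" in vol.probabilities
    if not have_probs:
        warnings.warn(
            "volume carries no probability maps; falling back to relabeling "
            "the streamline-midpoint voxel — supply segmentation probability "
            "maps for a principled correction",
            RuntimeWarning,
            stacklevel=2,
        )

    h = np.asarray(vol.spacing)
    if step_mm is None:
        step_mm = 0.25 * float(h.min())
    starts_vox = np.argwhere(suspect)
    starts = starts_vox * h
    _, _, vis_dn = trace_batch(tangent, vol, starts, "down", step_mm, record_visited=True)
    _, _, vis_up = trace_batch(tangent, vol, starts, "up", step_mm, record_visited=True)

    shape = np.asarray(vol.shape)
    gm_prob = vol.probabilities["gm"] if have_probs else None
    targets = set()
    for dn, up in zip(vis_dn, vis_up):
        # ordered path from the WM end to the CSF end; the start voxel sits
        # at the stitch between the reversed down-trace and the up-trace
        path = np.vstack([dn[::-1], up[1:]]) if len(up) > 1 else dn[::-1]
        start_idx = len(dn) - 1
        ok = ((path >= 0) & (path < shape)).all(axis=1)
        keep = np.nonzero(ok)[0]
        path = path[keep]
        inmask = suspect[path[:, 0], path[:, 1], path[:, 2]]
        sel = np.nonzero(inmask)[0]
        path = path[sel]
        if len(path) == 0:
            continue
        orig_idx = keep[sel]
        if have_probs:
            probs = gm_prob[path[:, 0], path[:, 1], path[:, 2]]
            pmin = probs.min()
            # only relabel where the segmentation itself dissents; a path of
            # fully confident GM carries no evidence of an erased sheet
            if pmin >= 0.5:
                continue
            # ties broken toward the seed voxel, so a suspect sheet spreads
            # its reopening over its whole extent instead of one end
            ties = np.nonzero(probs <= pmin + 1e-12)[0]
            k = ties[np.argmin(np.abs(orig_idx[ties] - start_idx))]
            pick = path[int(k)]
        else:
            pick = path[len(path) // 2]
        targets.add(tuple(int(c) for c in pick))

    if not targets:
        return out, relabeled
    tgt = np.array(sorted(targets))
    if have_probs:
        wm_p = vol.probabilities.get("wm", np.zeros(vol.shape))
        csf_p = vol.probabilities.get("csf", np.zeros(vol.shape))
        to_wm = wm_p[tgt[:, 0], tgt[:, 1], tgt[:, 2]] > csf_p[tgt[:, 0], tgt[:, 1], tgt[:, 2]]
        new_label = np.where(to_wm, WM, CSF)
    else:
        new_label = np.full(len(tgt), CSF)
    out.labels[tgt[:, 0], tgt[:, 1], tgt[:, 2]] = new_label
    relabeled[tgt[:, 0], tgt[:, 1], tgt[:, 2]] = True
    if out.probabilities is not None and "gm" in out.probabilities:
        # keep label/probability consistency at relabeled voxels
        for name, lab in (("csf", CSF), ("wm", WM)):
            if name in out.probabilities:
                sel = relabeled & (out.labels == lab)
                out.probabilities[name][sel] = 1.0
                out.probabilities["gm"][sel] = 0.0
    return out, relabeled


def correct_and_recompute(
    vol: TissueVolume,
    config=None,
) -> tuple[ThicknessMap, SulcusCorrectionReport]:
    """Full cycle: thickness -> detect -> correct -> thickness again.

    Runs ``config.sulci_iterations`` detect/correct passes (default 1, the
    conventional single pass) and reports counts from the first and final
    thickness maps.
    """
    from .config import PipelineConfig
    from .laplace import solve_laplace

    cfg = config or PipelineConfig()
    tmap0 = thickness_pipeline(vol, cfg)
    gm0 = vol.gm_mask
    above0 = int(
        (np.where(np.isfinite(tmap0.thickness), tmap0.thickness, -np.inf)
         > cfg.sulci_threshold_mm)[gm0 & tmap0.valid].sum()
    )

    current = vol
    tmap = tmap0
    total_relabeled = 0
    suspect_union = np.zeros(vol.shape, dtype=bool)
    relabeled_union = np.zeros(vol.shape, dtype=bool)
    for _ in range(max(1, cfg.sulci_iterations)):
        fld = solve_laplace(
            current, cfg.laplace_tolerance, cfg.laplace_max_iterations,
            cfg.relaxation_factor,
        )
        tang = tangent_field(fld, current)
        suspect = detect_suspect_regions(
            tmap, current, tang, cfg.sulci_threshold_mm, cfg.sulci_cone_degrees
        )
        suspect_union |= suspect
        if not suspect.any():
            break
        corrected, relab = correct_segmentation(current, suspect, tang)
        total_relabeled += int(relab.sum())
        relabeled_union |= relab
        if not relab.any():
            break
        current = corrected
        tmap = thickness_pipeline(current, cfg)

    gm1 = current.gm_mask
    above1 = int(
        (np.where(np.isfinite(tmap.thickness), tmap.thickness, -np.inf)
         > cfg.sulci_threshold_mm)[gm1 & tmap.valid].sum()
    )
    report = SulcusCorrectionReport(
        threshold_mm=cfg.sulci_threshold_mm,
        n_gm_before=int(gm0.sum()),
        n_gm_after=int(gm1.sum()),
        n_above_before=above0,
        n_above_after=above1,
        n_suspect=int(suspect_union.sum()),
        n_relabeled=total_relabeled,
        suspect_mask=suspect_union,
        relabeled_mask=relabeled_union,
    )
    return tmap, report
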