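"""NIfTI and table I/O for volumes, maps and cohorts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import Cohort
from .thickness import ThicknessMap
from .volume import BACKGROUND, CSF, GM, WM, TissueVolume, VolumeError

_PROB_KEYS = ("csf", "gm", "wm")
_PROB_LABELS = {"csf": CSF, "gm": GM, "wm": WM}


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    if any(v <= 0 for v in z):
        raise VolumeError(f"non-positive voxel spacing {z} in NIfTI header")
    return tuple(float(v) for v in z)


def save_tissue_volume(vol: TissueVolume, path, prob_prefix=None) -> None:
    """Write labels as integer NIfTI; optionally probability maps alongside.

    With ``prob_prefix`` each probability map goes to
    ``<prob_prefix>_<tissue>.nii.gz``.
    """
    img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    if prob_prefix is not None and vol.probabilities is not None:
        for key, p in vol.probabilities.items():
            pimg = nib.Nifti1Image(p.astype(np.float32), vol.affine)
            pimg.header.set_zooms(vol.spacing)
            nib.save(pimg, f"{prob_prefix}_{key}.nii.gz")


def read_tissue_volume(path=None, prob_paths: dict | None = None) -> TissueVolume:
    """Load a segmented volume from a label NIfTI and/or probability maps.

    ``prob_paths`` maps tissue names ('csf', 'gm', 'wm') to NIfTI files on
    the same grid.  When only probability maps are given, labels are their
    per-voxel argmax (background where all probabilities are ~0).  Grid or
    affine mismatches, non-positive spacing and unknown label values raise
    with file context.
    """
    if path is None and not prob_paths:
        raise VolumeError("need a label volume, probability maps, or both")
    labels = None
    spacing = None
    affine = None
    ref_shape = None
    if path is not None:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise VolumeError(f"{path}: expected a 3D label volume, got {data.shape}")
        if not np.allclose(data, np.round(data)):
            raise VolumeError(f"{path}: label volume contains non-integer values")
        labels = np.round(data).astype(np.int8)
        spacing = _spacing_from(img)
        affine = img.affine
        ref_shape = labels.shape
    probs = None
    if prob_paths:
        probs = {}
        for key, p in prob_paths.items():
            if key not in _PROB_KEYS:
                raise VolumeError(f"unknown tissue '{key}' (expected {_PROB_KEYS})")
            pimg = nib.load(str(p))
            pdata = np.asanyarray(pimg.dataobj).astype(float)
            if ref_shape is None:
                ref_shape = pdata.shape
                spacing = _spacing_from(pimg)
                affine = pimg.affine
            elif pdata.shape != ref_shape:
                raise VolumeError(
                    f"{p}: grid {pdata.shape} does not match {ref_shape}"
                )
            elif not np.allclose(pimg.affine, affine, atol=1e-4):
                raise VolumeError(f"{p}: affine does not match the label volume")
            probs[key] = pdata
    if labels is None:
        stack = np.stack([probs.get(k, np.zeros(ref_shape)) for k in _PROB_KEYS])
        arg = np.argmax(stack, axis=0)
        labels = np.array([_PROB_LABELS[k] for k in _PROB_KEYS], dtype=np.int8)[arg]
        labels[stack.sum(axis=0) < 0.5] = BACKGROUND
    try:
        return TissueVolume(labels, spacing, probabilities=probs, affine=affine)
    except VolumeError as e:
        raise VolumeError(f"{path or list(prob_paths.values())[0]}: {e}") from e


def save_map(arr_or_map, path, spacing=None, affine=None) -> None:
    """Write a ThicknessMap (or raw float array) as a float32 NIfTI."""
    if isinstance(arr_or_map, ThicknessMap):
        arr = arr_or_map.thickness
        spacing = arr_or_map.spacing
    else:
        arr = np.asarray(arr_or_map)
        if spacing is None:
            raise ValueError("spacing required for raw arrays")
    if affine is None:
        affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(arr.astype(np.float32), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_map(path) -> ThicknessMap:
    """Load a thickness NIfTI; validity = finite voxels."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).astype(float)
    valid = np.isfinite(arr)
    return ThicknessMap(
        l0=np.full(arr.shape, np.nan), l1=np.full(arr.shape, np.nan),
        thickness=arr, valid=valid, spacing=_spacing_from(img),
        provenance={"source": str(path)},
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort: per-subject maps, covariates CSV, truth mask + JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        fname = f"{s.subject_id}_thickness.nii.gz"
        save_map(s.thickness, out / fname)
        rows.append(
            {"subject_id": s.subject_id, "group": s.group,
             "age": s.age, "severity": s.severity, "thickness_file": fname}
        )
    pd.DataFrame(rows).to_csv(out / "covariates.csv", index=False)
    save_tissue_volume(cohort.phantom.volume, out / "base_seg.nii.gz")
    save_map(
        cohort.patch_mask.astype(np.float32), out / "true_patch.nii.gz",
        spacing=cohort.base_map.spacing,
    )
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=2))
    return out
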