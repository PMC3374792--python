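"""End-to-end pipeline: cohort in, statistics and ROI correlations out."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .groupstats import (
    ClusterTable, StatMap, build_design, smooth_map,
    threshold_clusters, voxelwise_glm,
)
from .io import load_map, read_tissue_volume, save_map
from .laplace import solve_laplace
from .roi import grow_streamline_roi, mean_roi_thickness, partial_correlation, pearson
from .sulci import correct_and_recompute
from .thickness import tangent_field


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    stat: StatMap
    clusters_less: ClusterTable
    clusters_greater: ClusterTable
    correlations: pd.DataFrame
    log: dict = field(default_factory=dict)


def _load_cohort_inputs(cohort_dir: Path, covariates: pd.DataFrame, config):
    """Per-subject thickness maps, computing them from segmentations if given.

    Each covariate row names either a ``thickness_file`` (precomputed map)
    or a ``seg_file`` (label volume, run through the sulcus-corrected
    thickness pipeline).
    """
    maps = []
    logs = []
    for _, row in covariates.iterrows():
        sid = row.get("subject_id", "?")
        if "thickness_file" in row and isinstance(row["thickness_file"], str):
            maps.append(load_map(cohort_dir / row["thickness_file"]))
            logs.append({"subject_id": sid, "source": row["thickness_file"]})
        elif "seg_file" in row and isinstance(row["seg_file"], str):
            vol = read_tissue_volume(cohort_dir / row["seg_file"])
            tmap, report = correct_and_recompute(vol, config)
            maps.append(tmap)
            logs.append(
                {"subject_id": sid, "source": row["seg_file"],
                 "sulci_report": report.to_dict()}
            )
        else:
            raise PipelineError(
                f"subject {sid}: covariates must name a thickness_file or seg_file"
            )
    return maps, logs


def run_full_pipeline(
    cohort_dir,
    covariates_csv=None,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> PipelineResult:
    """Smoothing, GLM, clusters and streamline-ROI severity correlations.

    ``cohort_dir`` holds per-subject inputs plus ``base_seg.nii.gz`` (the
    common-space segmentation used for the tangent field of the ROI stage)
    and a covariates CSV with columns subject_id, group, age, severity and
    a per-subject file column.  Results (stat maps, cluster tables,
    correlations, a JSON log with config and convergence records) land in
    ``out_dir`` when given.
    """
    cohort_dir = Path(cohort_dir)
    cfg = config or PipelineConfig()
    cov_path = Path(covariates_csv) if covariates_csv else cohort_dir / "covariates.csv"
    cov = pd.read_csv(cov_path)
    for col in ("subject_id", "group", "age"):
        if col not in cov.columns:
            raise PipelineError(f"covariates file lacks required column '{col}'")
    if cov["age"].isna().any():
        bad = cov.loc[cov["age"].isna(), "subject_id"].tolist()
        raise PipelineError(f"missing age for subject(s) {bad}")
    counts = cov["group"].str.lower().value_counts()
    if len(counts) != 2 or (counts < 3).any():
        raise PipelineError(
            f"need two groups with at least 3 subjects each, got {counts.to_dict()}"
        )

    maps, subject_logs = _load_cohort_inputs(cohort_dir, cov, cfg)
    design = build_design(cov)

    smoothed = [smooth_map(m, cfg.smoothing_fwhm_mm) for m in maps]
    common = np.logical_and.reduce([m.valid for m in maps])
    stat = voxelwise_glm(smoothed, design, mask=common, spacing=maps[0].spacing)
    cl_less = threshold_clusters(
        stat, cfg.alpha, cfg.cluster_connectivity, "less",
        correction=cfg.multiple_comparison,
    )
    cl_greater = threshold_clusters(
        stat, cfg.alpha, cfg.cluster_connectivity, "greater",
        correction=cfg.multiple_comparison,
    )

    # ROI severity correlation within the affected group, for each cluster
    # of the planned "affected thinner" contrast
    corr_rows = []
    base_seg = cohort_dir / "base_seg.nii.gz"
    if len(cl_less) and base_seg.exists() and "severity" in cov.columns:
        vol = read_tissue_volume(base_seg)
        fld = solve_laplace(
            vol, cfg.laplace_tolerance, cfg.laplace_max_iterations,
            cfg.relaxation_factor,
        )
        tang = tangent_field(fld, vol)
        affected = cov["group"].str.lower() == "ptsd"
        idx = np.nonzero(affected.to_numpy())[0]
        if len(idx) < 4:
            idx = idx[:0]  # partial correlation needs n >= 4
        for cid, vox in cl_less.members.items():
            cluster_mask = np.zeros(vol.shape, dtype=bool)
            cluster_mask[tuple(vox.T)] = True
            cluster_mask &= vol.gm_mask
            if not cluster_mask.any():
                continue
            roi = grow_streamline_roi(cluster_mask, tang, vol, cluster_id=cid)
            means = [mean_roi_thickness(maps[i], roi) for i in idx]
            ages = cov.loc[affected, "age"].to_numpy(dtype=float)
            sev = cov.loc[affected, "severity"].to_numpy(dtype=float)
            pc = partial_correlation(means, sev, ages)
            pr = pearson(means, sev)
            corr_rows.append(
                {"roi_id": cid, "n": pc.n, "roi_voxels": int(roi.mask.sum()),
                 "partial_r": pc.r, "partial_p": pc.p,
                 "pearson_r": pr.r, "pearson_p": pr.p, "controlled": "age"}
            )
    correlations = pd.DataFrame(
        corr_rows,
        columns=["roi_id", "n", "roi_voxels", "partial_r", "partial_p",
                 "pearson_r", "pearson_p", "controlled"],
    )

    from . import __version__

    log = {
        "version": __version__,
        "config": cfg.to_dict(),
        "n_subjects": len(cov),
        "df": stat.df,
        "subjects": subject_logs,
    }
    result = PipelineResult(stat, cl_less, cl_greater, correlations, log)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_map(stat.t, out / "t_map.nii.gz", spacing=stat.spacing)
        save_map(stat.p_less, out / "p_less.nii.gz", spacing=stat.spacing)
        save_map(stat.p_greater, out / "p_greater.nii.gz", spacing=stat.spacing)
        cl_less.table.to_csv(out / "clusters_less.csv", index=False)
        cl_greater.table.to_csv(out / "clusters_greater.csv", index=False)
        correlations.to_csv(out / "roi_correlations.csv", index=False)
        (out / "log.json").write_text(json.dumps(log, indent=2, default=str))
    return result
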