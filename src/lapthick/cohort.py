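"""Synthetic subject cohorts for validating the statistical stages.

Emulates the study design this pipeline targets: two groups of trauma
survivors (one with the disorder, one without), each subject contributing
a thickness map in a common space plus age and a symptom-severity score
(CAPS-like, higher = worse).  Per subject the map is

    base(x) + b_i + beta_age * age_i - effect * patch(x) * affected_i + eps_i(x)

where ``base`` is the PDE thickness map of a shared phantom geometry,
``b_i ~ N(0, subject_sd)`` is a global between-subject offset,
``beta_age`` is the slow age-related thinning (default -0.0016 mm/year,
i.e. 16 um per decade), ``patch`` is a known target region thinned by the
stated effect in the affected group only, and ``eps`` is i.i.d. voxel
noise.  Severity is generated as

    severity_i = intercept + a * m_i + b_age * age_i + N(0, noise_sd)

with ``m_i`` the subject's mean thickness over the target patch and the
coefficient ``a`` solved so the *population* partial correlation between
m and severity given age equals the requested value:

    a = rho * noise_sd / (sigma_m * sqrt(1 - rho^2)),
    sigma_m^2 = subject_sd^2 + voxel_sd^2 / n_patch.

Everything is a pure function of (spec, seed); the true patch mask and all
generating parameters are returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantoms import Phantom, PhantomSpec, make_phantom
from .thickness import ThicknessMap, thickness_pipeline


class CohortError(ValueError):
    pass


def _default_base() -> PhantomSpec:
    return PhantomSpec(
        kind="slab", spacing=(1.0, 1.0, 1.0), shape=(48, 48, 48),
        slab_thickness_mm=4.0,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a simulated two-group cohort."""

    n_per_group: int = 10
    base: PhantomSpec = field(default_factory=_default_base)
    effect_mm: float = 0.5
    patch_radius_mm: float = 8.0
    subject_sd_mm: float = 0.13
    voxel_noise_sd_mm: float = 0.2
    age_range: tuple[float, float] = (25.0, 55.0)
    age_slope_mm_per_year: float = -0.0016
    partial_r: float = -0.75
    severity_noise_sd: float = 8.0
    severity_age_slope: float = 0.8
    severity_intercept: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise CohortError("need at least 2 subjects per group")
        if abs(self.partial_r) >= 1:
            raise CohortError("|partial_r| must be below 1")
        if self.subject_sd_mm < 0 or self.voxel_noise_sd_mm < 0 or self.severity_noise_sd < 0:
            raise CohortError("standard deviations must be non-negative")
        if self.age_range[1] < self.age_range[0]:
            raise CohortError("age range reversed")


@dataclass
class Subject:
    subject_id: str
    group: str                 # 'ptsd' (affected) or 'control'
    age: float
    severity: float
    thickness: ThicknessMap | None = None


@dataclass
class Cohort:
    subjects: list[Subject]
    patch_mask: np.ndarray
    base_map: ThicknessMap
    phantom: Phantom
    spec: CohortSpec
    truth: dict = field(default_factory=dict)


def _patch_mask(phantom: Phantom, radius_mm: float) -> np.ndarray:
    """Ball of the given radius around the GM centroid, intersected with GM."""
    gm = phantom.volume.gm_mask
    h = np.asarray(phantom.volume.spacing)
    idx = np.argwhere(gm)
    center = idx.mean(axis=0) * h
    grids = np.meshgrid(
        *[np.arange(s) * hh for s, hh in zip(phantom.volume.shape, h)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return gm & (d2 <= radius_mm**2)


def _severity_coefficient(spec: CohortSpec, n_patch: int) -> tuple[float, float]:
    """Solve the thickness coefficient from the requested partial correlation."""
    sigma_m = np.sqrt(
        spec.subject_sd_mm**2 + spec.voxel_noise_sd_mm**2 / max(n_patch, 1)
    )
    if sigma_m == 0 and spec.partial_r != 0:
        raise CohortError(
            "requested a nonzero partial correlation but thickness has no "
            "between-subject variability"
        )
    rho = spec.partial_r
    if rho == 0:
        return 0.0, sigma_m
    if spec.severity_noise_sd == 0:
        raise CohortError(
            "severity noise SD of 0 forces |partial r| = 1; infeasible"
        )
    a = rho * spec.severity_noise_sd / (sigma_m * np.sqrt(1 - rho**2))
    return float(a), float(sigma_m)


def _draw_subject_scalars(spec: CohortSpec, rng: np.random.Generator, n: int):
    ages = rng.uniform(*spec.age_range, size=n)
    offsets = rng.normal(0.0, spec.subject_sd_mm, size=n)
    sev_noise = rng.normal(0.0, spec.severity_noise_sd, size=n)
    return ages, offsets, sev_noise


def make_cohort(spec: CohortSpec, base_map: ThicknessMap | None = None) -> Cohort:
    """Generate a full map-level cohort (deterministic under the seed).

    ``base_map`` may pass a precomputed thickness map of ``spec.base`` to
    skip the PDE solve; it must come from the identical phantom spec, so
    the cohort remains a pure function of (spec, seed).
    """
    phantom = make_phantom(spec.base)
    if base_map is None:
        base_map = thickness_pipeline(phantom.volume)
    patch = _patch_mask(phantom, spec.patch_radius_mm)
    n_patch = int(patch.sum())
    if n_patch == 0:
        raise CohortError("target patch does not intersect gray matter")
    a_coef, sigma_m = _severity_coefficient(spec, n_patch)

    rng = np.random.default_rng(spec.seed)
    n_total = 2 * spec.n_per_group
    ages, offsets, sev_noise = _draw_subject_scalars(spec, rng, n_total)
    groups = ["ptsd"] * spec.n_per_group + ["control"] * spec.n_per_group

    base = base_map.thickness
    valid = base_map.valid
    subjects = []
    for i in range(n_total):
        affected = groups[i] == "ptsd"
        arr = base.copy()
        arr[valid] += offsets[i] + spec.age_slope_mm_per_year * ages[i]
        if affected and spec.effect_mm:
            arr[patch & valid] -= spec.effect_mm
        noise = rng.normal(0.0, spec.voxel_noise_sd_mm, size=arr.shape)
        arr[valid] += noise[valid]
        m_i = float(arr[patch & valid].mean())
        severity = (
            spec.severity_intercept
            + a_coef * m_i
            + spec.severity_age_slope * ages[i]
            + sev_noise[i]
        )
        tmap = ThicknessMap(
            l0=np.full(arr.shape, np.nan), l1=np.full(arr.shape, np.nan),
            thickness=np.where(valid, arr, np.nan), valid=valid.copy(),
            spacing=base_map.spacing,
            provenance={"synthetic_subject": i, "seed": spec.seed},
        )
        subjects.append(
            Subject(
                subject_id=f"sub-{i + 1:03d}", group=groups[i],
                age=float(ages[i]), severity=float(severity), thickness=tmap,
            )
        )
    truth = {
        "effect_mm": spec.effect_mm,
        "patch_voxels": n_patch,
        "severity_coefficient": a_coef,
        "sigma_roi_mean_mm": sigma_m,
        "partial_r": spec.partial_r,
        "age_slope_mm_per_year": spec.age_slope_mm_per_year,
    }
    return Cohort(
        subjects=subjects, patch_mask=patch, base_map=base_map,
        phantom=phantom, spec=spec, truth=truth,
    )


def simulate_roi_summaries(
    spec: CohortSpec,
    n_patch: int | None = None,
    base_mean_mm: float | None = None,
    rng: np.random.Generator | None = None,
):
    """Affected-group (ROI mean, age, severity) triples without building maps.

    Samples the same distribution the map route induces for the mean
    thickness over the true patch — base mean + subject offset + age slope
    + effect + averaged voxel noise — so large replicate studies of the
    severity coupling (hundreds of cohorts) run in milliseconds.  ``n_patch``
    and ``base_mean_mm`` default to the values a map-level cohort of this
    spec realizes.

    Returns ``(roi_mean, age, severity)`` arrays of length ``n_per_group``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if n_patch is None or base_mean_mm is None:
        phantom = make_phantom(spec.base)
        patch = _patch_mask(phantom, spec.patch_radius_mm)
        n_patch = int(patch.sum())
        if base_mean_mm is None:
            base_mean_mm = (
                phantom.true_thickness_mm
                if phantom.true_thickness_mm is not None
                else spec.base.slab_thickness_mm
            )
    a_coef, _ = _severity_coefficient(spec, n_patch)
    n = spec.n_per_group
    ages, offsets, sev_noise = _draw_subject_scalars(spec, rng, n)
    mean_noise = rng.normal(0.0, spec.voxel_noise_sd_mm / np.sqrt(n_patch), size=n)
    m = (
        base_mean_mm
        + offsets
        + spec.age_slope_mm_per_year * ages
        - spec.effect_mm
        + mean_noise
    )
    severity = (
        spec.severity_intercept
        + a_coef * m
        + spec.severity_age_slope * ages
        + sev_noise
    )
    return m, ages, severity
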