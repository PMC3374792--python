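"""Analytic phantoms: segmented volumes with known ground-truth thickness.

Every downstream stage (Laplace solve, streamline thickness, sulcus
correction, group statistics) is validated against these generators, which
emulate already-segmented MPRAGE-like volumes at desk scale:

``slab``
    WM half-space, N full GM layers, CSF half-space along z.  Truth N*h:
    the distance between the WM/GM and GM/CSF voxel-face interfaces.
``spherical-shell``
    Concentric spheres; the Laplace solution between them is known in
    closed form, truth R2 - R1.
``buried-sulcus``
    A U-shaped GM ribbon (two banks + fundus) folded around a thin vertical
    CSF sheet that opens into a CSF pool at the top — a sulcus.  The
    *sealed* variant erases the buried lower part of the sheet (relabels it
    GM), emulating the partial-volume segmentation failure that fuses
    opposing banks; the probability maps keep a reduced GM probability on
    the erased sheet, which is what the correction stage exploits.  Truth:
    the bank thickness.
``folded-random``
    A GM ribbon of nominal thickness draped over a smooth random height
    field; no closed-form truth, used for solver-vs-streamline-oracle
    equivalence checks.

All generators are pure functions of their spec (and seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import CSF, GM, WM, TissueVolume

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_slab",
    "make_spherical_shell",
    "make_buried_sulcus",
    "make_folded_random",
    "make_phantom",
]


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry parameters for a phantom volume (all lengths in mm)."""

    kind: str = "slab"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shape: tuple[int, int, int] = (32, 32, 32)
    seed: int = 0
    # slab
    slab_thickness_mm: float = 5.0
    # spherical shell
    shell_r1_mm: float = 8.0
    shell_r2_mm: float = 12.0
    # buried sulcus
    bank_mm: float = 2.0
    gap_mm: float = 1.0
    sulcus_depth_mm: float = 15.0
    seal_depth_mm: float = 12.0
    sealed_gm_probability: float = 0.45
    margin_mm: float = 2.5
    # folded random sheet
    fold_amplitude_mm: float = 3.0
    fold_frequency_per_mm: float = 0.06
    fold_thickness_mm: float = 3.0

    def __post_init__(self):
        if self.kind not in {"slab", "spherical-shell", "buried-sulcus", "folded-random"}:
            raise PhantomError(f"unknown phantom kind {self.kind!r}")
        for name in (
            "slab_thickness_mm", "shell_r1_mm", "shell_r2_mm", "bank_mm",
            "gap_mm", "sulcus_depth_mm", "seal_depth_mm", "margin_mm",
            "fold_thickness_mm",
        ):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")
        if any(h <= 0 for h in self.spacing):
            raise PhantomError("spacing must be positive")
        if self.shell_r2_mm <= self.shell_r1_mm:
            raise PhantomError("shell requires R2 > R1")
        if not 0 < self.sealed_gm_probability < 0.5:
            raise PhantomError("sealed GM probability must be in (0, 0.5) so CSF wins the argmax")

    # Convenience constructors -------------------------------------------
    @staticmethod
    def slab(thickness_mm=5.0, spacing=(1.0, 1.0, 1.0), cross_section=20, seed=0):
        h = spacing[2]
        nz = int(round(thickness_mm / h)) + 8
        return PhantomSpec(
            kind="slab", spacing=tuple(spacing),
            shape=(cross_section, cross_section, nz),
            slab_thickness_mm=thickness_mm, seed=seed,
        )

    @staticmethod
    def shell(r1_mm=8.0, r2_mm=12.0, spacing=(0.5, 0.5, 0.5), seed=0):
        shape = tuple(int(np.ceil(2 * (r2_mm + 3 * h) / h)) | 1 for h in spacing)
        return PhantomSpec(
            kind="spherical-shell", spacing=tuple(spacing), shape=shape,
            shell_r1_mm=r1_mm, shell_r2_mm=r2_mm, seed=seed,
        )

    @staticmethod
    def buried_sulcus(bank_mm=2.0, gap_mm=1.0, sulcus_depth_mm=15.0,
                      seal_depth_mm=12.0, spacing=(0.5, 0.5, 0.5),
                      extrude_mm=8.0, seed=0):
        hx, hy, hz = spacing
        margin = 2.5
        nx = int(round((2 * margin + 2 * bank_mm + gap_mm) / hx)) + 4
        ny = int(round(extrude_mm / hy))
        nz = int(round((margin + bank_mm + sulcus_depth_mm + margin) / hz)) + 4
        return PhantomSpec(
            kind="buried-sulcus", spacing=tuple(spacing), shape=(nx, ny, nz),
            bank_mm=bank_mm, gap_mm=gap_mm, sulcus_depth_mm=sulcus_depth_mm,
            seal_depth_mm=seal_depth_mm, margin_mm=margin, seed=seed,
        )

    @staticmethod
    def folded(thickness_mm=3.0, amplitude_mm=3.0, frequency_per_mm=0.06,
               spacing=(1.0, 1.0, 1.0), extent=32, seed=0):
        hz = spacing[2]
        nz = int(np.ceil((thickness_mm + 2 * amplitude_mm + 8) / hz))
        return PhantomSpec(
            kind="folded-random", spacing=tuple(spacing),
            shape=(extent, extent, nz),
            fold_thickness_mm=thickness_mm, fold_amplitude_mm=amplitude_mm,
            fold_frequency_per_mm=frequency_per_mm, seed=seed,
        )


@dataclass
class Phantom:
    """A generated volume plus the analytic truth of its geometry."""

    volume: TissueVolume
    true_thickness_mm: float | None
    spec: PhantomSpec
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    sealed: bool = False


def make_slab(spec: PhantomSpec) -> Phantom:
    """WM half-space, N full GM layers, CSF half-space along the z axis.

    The requested thickness is rounded to the nearest whole layer count;
    the *realized* truth N*h is returned (distance between the voxel-face
    interfaces, matching the solver's ghost-node convention).
    """
    if spec.kind != "slab":
        raise PhantomError("spec.kind must be 'slab'")
    hz = spec.spacing[2]
    n_layers = max(1, int(round(spec.slab_thickness_mm / hz)))
    nx, ny, nz = spec.shape
    if nz < n_layers + 4:
        raise PhantomError(
            f"grid depth {nz} too small for {n_layers} GM layers plus a "
            f"2-voxel margin on each side"
        )
    z0 = (nz - n_layers) // 2
    labels = np.full(spec.shape, WM, dtype=np.int8)
    labels[:, :, z0 : z0 + n_layers] = GM
    labels[:, :, z0 + n_layers :] = CSF
    vol = TissueVolume(labels, spec.spacing)
    return Phantom(vol, true_thickness_mm=n_layers * hz, spec=spec)


def make_spherical_shell(spec: PhantomSpec) -> Phantom:
    """Concentric-sphere shell: WM core, GM shell [R1, R2), CSF outside.

    Voxel centers are classified by radius with the half-open convention
    ``[R1, R2)`` labeled GM.  Truth R2 - R1.
    """
    if spec.kind != "spherical-shell":
        raise PhantomError("spec.kind must be 'spherical-shell'")
    r1, r2 = spec.shell_r1_mm, spec.shell_r2_mm
    hmax = max(spec.spacing)
    if r1 <= 2 * hmax:
        raise PhantomError(f"R1={r1} must exceed 2*max(spacing)={2*hmax}")
    if r2 - r1 < 2 * hmax:
        raise PhantomError(
            f"shell thickness {r2 - r1} mm is under 2 voxels at spacing {hmax} mm"
        )
    shape = np.asarray(spec.shape)
    h = np.asarray(spec.spacing)
    half_extent = (shape - 1) / 2 * h
    if (half_extent < r2 + 2 * h).any():
        raise PhantomError(
            f"grid {spec.shape} at spacing {spec.spacing} cannot contain "
            f"R2={r2} mm plus a 2-voxel CSF margin"
        )
    center = (shape - 1) / 2
    grids = np.meshgrid(*[(np.arange(s) - c) * hh for s, c, hh in zip(shape, center, h)],
                        indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))
    labels = np.full(spec.shape, CSF, dtype=np.int8)
    labels[r < r1] = WM
    labels[(r >= r1) & (r < r2)] = GM
    # partial-volume probability maps: the fraction of each voxel inside the
    # shell, linearized over one voxel width around each interface — gives
    # the solver sub-voxel interface positions, as a fuzzy segmentation would
    hbar = float(np.mean(h))
    p_in = np.clip(0.5 + (r - r1) / hbar, 0.0, 1.0)
    p_out = np.clip(0.5 + (r2 - r) / hbar, 0.0, 1.0)
    p_gm = p_in * p_out
    p_wm = 1.0 - p_in
    p_csf = 1.0 - p_out
    vol = TissueVolume(
        labels, spec.spacing,
        probabilities={"gm": p_gm, "wm": p_wm, "csf": p_csf},
    )
    ph = Phantom(vol, true_thickness_mm=r2 - r1, spec=spec)
    ph.masks["radius_mm"] = r
    return ph


def make_buried_sulcus(spec: PhantomSpec, sealed: bool = False) -> Phantom:
    """Two GM banks around a thin sulcal CSF sheet opening into a top pool.

    Cross-section (x horizontal, z vertical, extruded along y)::

        z             C C C C C C C    <- CSF pool
        ^             W G c G W        <- banks (G) + open sheet (c)
        |             W G c G W
        |             W G s G W        <- sealed: sheet voxels s relabeled GM
        |             W G s G W           with GM probability ~0.45
        |             W G G G W        <- fundus
        |             W W W W W

    Truth: the bank thickness.  ``masks['sheet']`` is the erased sheet in
    the sealed variant (the correction target); ``masks['bank_core']`` is
    the bank region away from the fundus and pool corners where the true
    thickness is exactly the bank width.
    """
    if spec.kind != "buried-sulcus":
        raise PhantomError("spec.kind must be 'buried-sulcus'")
    hx, hy, hz = spec.spacing
    t = max(1, int(round(spec.bank_mm / hx)))
    g = max(1, int(round(spec.gap_mm / hx)))
    tz = max(1, int(round(spec.bank_mm / hz)))
    d_tot = int(round(spec.sulcus_depth_mm / hz))
    d_seal = int(round(min(spec.seal_depth_mm, spec.sulcus_depth_mm - 2 * hz) / hz))
    mz = max(2, int(round(spec.margin_mm / hz)))
    nx, ny, nz = spec.shape
    span = 2 * t + g
    off = (nx - span) // 2
    z0 = mz + tz                      # sheet bottom (fundus top)
    z_pool = z0 + d_tot               # pool floor
    if off < 2 or nz < z_pool + 2:
        raise PhantomError(
            f"grid {spec.shape} too small for sulcus geometry "
            f"(needs x span {span}+4, z span {z_pool}+2)"
        )

    labels = np.full(spec.shape, WM, dtype=np.int8)
    labels[:, :, z_pool:] = CSF
    xs = np.arange(nx)
    left = (xs >= off) & (xs < off + t)
    gap = (xs >= off + t) & (xs < off + t + g)
    right = (xs >= off + t + g) & (xs < off + span)
    # fundus: full-span GM below the sheet
    labels[left | gap | right, :, mz:z0] = GM
    # banks + open sheet
    labels[left | right, :, z0:z_pool] = GM
    labels[gap, :, z0:z_pool] = CSF

    probs = {
        "csf": (labels == CSF).astype(float),
        "gm": (labels == GM).astype(float),
        "wm": (labels == WM).astype(float),
    }
    sheet = np.zeros(spec.shape, dtype=bool)
    if sealed:
        sheet[np.ix_(gap.nonzero()[0], np.arange(ny), np.arange(z0, z0 + d_seal))] = True
        labels[sheet] = GM
        probs["gm"][sheet] = spec.sealed_gm_probability
        probs["csf"][sheet] = 1.0 - spec.sealed_gm_probability
        probs["wm"][sheet] = 0.0

    bank_core = np.zeros(spec.shape, dtype=bool)
    zlo = z0 + tz
    zhi = z_pool - tz
    bank_core[np.ix_((left | right).nonzero()[0], np.arange(ny), np.arange(zlo, zhi))] = True

    vol = TissueVolume(labels, spec.spacing, probabilities=probs)
    ph = Phantom(vol, true_thickness_mm=t * hx, spec=spec, sealed=sealed)
    ph.masks["sheet"] = sheet
    ph.masks["bank_core"] = bank_core
    fused = np.zeros(spec.shape, dtype=bool)
    if sealed:
        fused[np.ix_((left | gap | right).nonzero()[0], np.arange(ny),
                     np.arange(z0, z0 + d_seal))] = True
        fused &= labels == GM
    ph.masks["fused"] = fused
    return ph


def make_folded_random(spec: PhantomSpec) -> Phantom:
    """GM sheet of nominal thickness draped over a smooth random surface.

    The WM/GM interface is a seeded sum of sinusoids; the GM/CSF interface
    is its vertical offset by the nominal thickness.  Because the offset is
    vertical, the streamline thickness varies smoothly with local slope;
    there is no scalar truth, and this phantom is used for PDE-vs-tracing
    equivalence only.
    """
    if spec.kind != "folded-random":
        raise PhantomError("spec.kind must be 'folded-random'")
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    hx, hy, hz = spec.spacing
    x = np.arange(nx)[:, None] * hx
    y = np.arange(ny)[None, :] * hy
    f = np.zeros((nx, ny))
    for _ in range(3):
        fx = spec.fold_frequency_per_mm * rng.uniform(0.5, 1.5)
        fy = spec.fold_frequency_per_mm * rng.uniform(0.5, 1.5)
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        amp = spec.fold_amplitude_mm * rng.uniform(0.3, 1.0) / 3
        f += amp * np.sin(2 * np.pi * fx * x + px) * np.sin(2 * np.pi * fy * y + py)
    thick = spec.fold_thickness_mm
    zmid = (nz - 1) * hz / 2
    base = zmid - thick / 2 + f
    lo = 2.5 * hz
    hi = (nz - 3.5) * hz - thick
    base = np.clip(base, lo, hi)
    z = np.arange(nz)[None, None, :] * hz
    labels = np.full(spec.shape, WM, dtype=np.int8)
    labels[z >= base[:, :, None]] = GM
    labels[z >= (base + thick)[:, :, None]] = CSF
    # partial-volume maps linearized over one voxel around each surface,
    # so the interpolated 0.5-crossings sit on the analytic surfaces
    p_in = np.clip(0.5 + (z - base[:, :, None]) / hz, 0.0, 1.0)
    p_out = np.clip(0.5 + ((base + thick)[:, :, None] - z) / hz, 0.0, 1.0)
    vol = TissueVolume(
        labels, spec.spacing,
        probabilities={"gm": p_in * p_out, "wm": 1.0 - p_in, "csf": 1.0 - p_out},
    )
    return Phantom(vol, true_thickness_mm=None, spec=spec)


_MAKERS = {
    "slab": make_slab,
    "spherical-shell": make_spherical_shell,
    "folded-random": make_folded_random,
}


def make_phantom(spec: PhantomSpec, sealed: bool = False) -> Phantom:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "buried-sulcus":
        return make_buried_sulcus(spec, sealed=sealed)
    return _MAKERS[spec.kind](spec)
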