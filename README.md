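# lapthick — voxel-based cortical thickness by the Laplacian streamline method

Cortical thickness — the distance across the gray-matter (GM) sheet from the
white-matter (WM) interface to the pial (GM/CSF) interface — is a sensitive
morphological marker: it thins with aging and in disorders where volumetry
sees nothing. Measuring it in a segmented MRI volume is ill-posed until you
say *which* point on one surface corresponds to which point on the other.

The Laplacian method answers this with a potential field: solve

```
∇²ψ = 0   in gray matter,   ψ = 0 on the WM interface S′,   ψ = 1 on the CSF interface S.
```

The normalized gradient **T** = ∇ψ/‖∇ψ‖ defines nested correspondence
streamlines between the two surfaces, and thickness at a voxel is the arc
length of the streamline through it. Rather than tracing every streamline,
the arc lengths solve a pair of first-order transport PDEs (Yezzi–Prince):

```
 T·∇L₀ = 1,  L₀ = 0 on S′        (length from the WM side)
−T·∇L₁ = 1,  L₁ = 0 on S         (length to the CSF side)
thickness = L₀ + L₁              (constant along each streamline)
```

`lapthick` implements this pipeline for segmented volumes (NIfTI labels
and/or tissue probability maps), plus the stages a group study needs:

- **Laplace solver** — red-black SOR, 7-point stencil with Shortley–Weller
  unequal arms; interfaces live on voxel faces, refined sub-voxel where
  probability maps localize them. Anisotropic spacing supported.
- **Thickness** — upwind transport solve for L₀/L₁, and an independent
  4th-order Runge–Kutta streamline tracer used as a cross-check oracle.
- **Sulcus correction** — partial-volume effects can erase the thin CSF
  sheet of a buried sulcus, fusing opposing banks into implausibly thick
  "cortex" (> 5 mm). Suspicious regions are found by tangent-guided region
  growing, the least-GM-probable voxel per streamline is relabeled to CSF,
  and thickness is recomputed.
- **Group statistics** — masked-normalized Gaussian smoothing (FWHM 8 mm),
  voxelwise GLM (two groups + age covariate), planned one-sided contrasts at
  uncorrected p < 0.001, connected-cluster tables.
- **ROI analysis** — clusters are grown along streamlines to the full
  cortical column; mean ROI thickness is correlated with symptom severity by
  Pearson's partial correlation controlling age.
- **Phantoms & cohorts** — slab, spherical shell, partially buried sulcus
  and folded-sheet geometries with exact analytic truths, and a two-group
  cohort simulator with a known thinning patch and a known
  thickness–severity coupling, so every stage is validated end to end
  without any external data.

## Worked example

Generate a 5 mm slab phantom (WM | 5 GM layers | CSF at 1 mm spacing) and
measure it:

```bash
$ lapthick phantom --kind slab --out slab.nii.gz
wrote slab.nii.gz (true thickness: 5.0 mm)
$ lapthick thickness --input slab.nii.gz --out thick.nii.gz
wrote thick.nii.gz: mean 5.000 mm over 2000 GM voxels
```

The mean is exactly the ground truth: for a slab the discrete problem is
solved without error.

Now a mis-segmented buried sulcus: two 2 mm GM banks around a 1 mm CSF
sheet whose buried portion has been erased (relabeled GM), fusing the banks:

```bash
$ lapthick phantom --kind buried-sulcus --sealed --spacing 0.5 --out sulc.nii.gz
wrote sulc.nii.gz (true thickness: 2.0 mm)
$ lapthick sulci-correct --input sulc.nii.gz --out corrected.nii.gz --report report.json
relabeled 736 voxels; GM>5mm 69.5% -> 0.0%
```

Before correction 69.5% of GM voxels read above the 5 mm plausibility
ceiling (streamlines in the fused column must detour to the sulcus opening);
one detect/correct/recompute pass reopens the sulcal sheet (736 relabeled
voxels, Dice 0.98 against the true erased sheet) and restores the bank
thickness to 2.00 mm.

A simulated group study, end to end:

```bash
$ lapthick simulate-cohort --n-per-group 10 --effect 0.5 --seed 1 --out cohort/
$ lapthick run-all --cohort cohort/ --out results/
```

writes t/p maps, a cluster table (the 0.5 mm thinning patch comes back as
the largest affected<unaffected cluster, Dice ≈ 0.94 against the true
patch), and per-cluster streamline-ROI severity correlations.

Everything is importable as a library too — `solve_laplace`,
`thickness_pipeline`, `correct_and_recompute`, `voxelwise_glm`,
`partial_correlation`, `make_cohort`, … — see the module docstrings.

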