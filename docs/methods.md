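# Methods

This note documents the model, the numerics, the synthetic data, and the
design choices behind `lapthick`, in the order the pipeline runs.

## The thickness model

Thickness is defined through the Laplace boundary-value problem on the
gray-matter domain: ψ = 0 on the GM/WM interface S′, ψ = 1 on the GM/CSF
interface S, ∇²ψ = 0 between them. The level sets of ψ form a nested family
of surfaces sweeping from S′ to S; the unit tangent field T = ∇ψ/‖∇ψ‖
(oriented WM → CSF, the direction of increasing ψ) is orthogonal to all of
them, and its integral curves (streamlines) define a one-to-one
correspondence between the two interfaces. Thickness at a point is the arc
length of its streamline. The arc lengths are obtained from the transport
pair T·∇L₀ = 1 (L₀ = 0 on S′) and −T·∇L₁ = 1 (L₁ = 0 on S); thickness
L₀ + L₁ is constant along each streamline by construction, so the whole
cortical column between a pair of corresponding surface points reports one
number.

Assumptions worth stating: the segmentation is trusted (thickness is a
property of the *labeled* GM sheet, which is why mis-segmented sulci must be
repaired before measuring); the domain is a topological sheet with both
boundaries present (GM islands touching only one tissue are flagged
unreachable and excluded); all computations are in mm via the voxel spacing
or NIfTI affine.

## Where the boundary lives (one convention everywhere)

All boundary-sensitive stages share a single *GM boundary field* B: the
binary GM label indicator, refined by the GM probability map where one
exists, and clamped to agree with the labels (a voxel labeled GM stays
above 0.5 even if its probability dissents — deliberate, so that a fused
sulcal sheet the segmentation labeled GM is traversed, not treated as
boundary). The cortical boundary is the 0.5-level set of the trilinear
interpolation of B: the voxel-face staircase for a binary segmentation,
sub-voxel between centers when partial-volume probabilities localize it.

Three consumers, one geometry:

1. **Laplace stencil** — 7-point finite differences with Shortley–Weller
   unequal arms: an interior link has length h, a link to a Dirichlet (WM or
   CSF) neighbor has the length of the B = 0.5 crossing
   x\* = h(q−0.5)/(q−p) (q, p the B values at the two centers), clipped to
   [0.05h, 1.45h], defaulting to h/2 (the face). Per-axis weights
   w = 2/(h_side(h_left+h_right)) handle anisotropic spacing exactly.
   Background neighbors mirror (zero flux).
2. **Transport ghosts** — a Dirichlet upwind neighbor contributes the ghost
   value x\* − h, which puts L = 0 exactly on the interface. An N-layer slab
   therefore returns N·h exactly, and the potential at layer k is
   (k−½)/N.
3. **Streamline termination** — a traced path ends where interpolated B
   crosses 0.5 (bisection refines the final segment to the crossing).

Keeping these consistent is what makes the PDE thickness and the explicit
tracer agree to a fraction of a voxel; with boundary values at WM/CSF voxel
*centers* instead, the shell phantom's potential error is an order of
magnitude larger and slab truth becomes (N+1)·h.

## Numerics

**Laplace solver.** Red-black successive over-relaxation, default ω = 1.9,
residual tolerance 1e−6 (the largest change a plain Gauss–Seidel step would
still make, in ψ units), cap 10 000 iterations. Convergence is governed by
the sheet thickness, not the grid: the cortex is everywhere a few voxels
from a Dirichlet boundary, and the 64³-scale phantoms converge in one to two
hundred sweeps. Non-convergence warns and is recorded in the provenance,
never silently accepted.

**Tangent field.** Central differences of ψ in mm (one-sided at grid
edges), normalized. Voxels with ‖∇ψ‖ < 1e−8 are flagged degenerate and
filled with the normalized mean of their non-degenerate 6-neighbors,
iterated inward; an unfillable pocket raises. Degenerate pockets occur at
sealed sulci (flat-ψ ridges), which the sulcus module needs traversable.

**Length transport.** First-order upwind: per axis the neighbor the
characteristic arrives from (sign of the tangent component) contributes
c·L with c = |T_axis|/h_axis, so L = (1 + Σc·L_upwind)/Σc. The fixed point
is reached by synchronous (Jacobi-style) vectorized iterations — values
propagate one voxel per sweep along characteristics, and the stopping rule
is a maximum change of 1e−3 mm. Sweeping Gauss–Seidel orderings would reach
the same fixed point with fewer iterations; the synchronous form was chosen
because it vectorizes cleanly in numpy, is trivially deterministic, and the
sheet is thin enough that the iteration count stays in the low hundreds.

**Ridge sinks.** In nearly enclosed GM pockets (e.g. the partially reopened
sulcus leaves a small GM plug surrounded by CSF) the tangent field can form
an interior ridge that streamlines flow *into*: those characteristics never
reach a boundary and their length is genuinely unbounded. The solver caps
the iteration (at 4× the grid's physical extent), cuts at-cap voxels out of
their neighbors' stencils so the divergence cannot contaminate voxels with
an escape route, transitively flags any voxel the majority of whose upwind
weight drains into flagged territory, and re-solves cleanly without them.
Flagged voxels are excluded from the validity mask (NaN thickness) — the
honest answer for a point whose streamline has no endpoint. Clean phantoms
have zero sinks.

**Streamline tracer.** Classical RK4 on the trilinearly interpolated,
re-normalized tangent field; default step 0.25·min(h); tangents are
extended two voxels past GM (nearest-GM copy) so interpolation near the
boundary does not mix in zeros. The tracer exists as the *independent
oracle* for the transport solve (same field, entirely different
discretization) and as the engine for sulcus correction and ROI growth.
Step size and tolerances are implementation choices, documented here
because no standard values exist.

## Sulcus detection and correction

Cortex is thinner than about 5 mm; a voxel reading thicker than that is
either a transport artifact or a fused sulcus. Detection seeds at
suprathreshold GM voxels (default 5 mm, configurable) and region-grows
through 26-connected suprathreshold GM, accepting a step only within 60° of
the local tangent line (sign-agnostic): fused columns extend along
streamlines; isotropic blobs do not. Correction traces each suspect voxel's
streamline both ways, takes the in-suspect-region path, and relabels the
voxel of minimum GM probability to its best non-GM tissue — one voxel per
streamline, reopening the sulcus with a minimal sheet rather than carving
channels. Two guards: a path whose minimum GM probability is ≥ 0.5 carries
no evidence of an erased sheet and is skipped; probability ties are broken
toward the seed voxel, which spreads the reopening over the sheet's whole
extent instead of piling relabels at one end. Without probability maps a
label-only fallback relabels the path midpoint, with a warning. One
detect/correct/recompute cycle is the default (an iteration count is
exposed); on the sealed phantom a second pass relabels nothing.

## Group statistics and ROI analysis

Smoothing is masked-normalized: Gaussian-filter map·mask and mask
separately (σ = FWHM/(2√(2 ln 2)) per axis in mm) and divide, so boundary
voxels are not dragged toward zero. Default FWHM 8 mm.

The voxelwise model is OLS on [intercept, group, age]:
t = cᵀβ̂ / √(σ̂² cᵀ(XᵀX)⁻¹c), σ̂² = RSS/(n − rank X), with one-sided p for
both planned directions (affected thinner / thicker). Without the age
column this reduces *exactly* to the pooled two-sample t (asserted to
1e−10 in tests). Suprathreshold voxels (default uncorrected p < 0.001,
following the convention of small-sample exploratory studies) are grouped
by 18-connectivity (configurable 6/26); peaks are maximum |t|, ties to the
smallest linear index. No multiple-comparison correction by default;
Bonferroni and BH-FDR are available behind a flag.

Because thickness is constant along a streamline, every voxel of a
cortical column carries the cluster's information; the ROI stage therefore
grows each cluster along the tangent field (tracing both directions at
0.25·min(h) sampling, marking nearest voxels — no voxel on a path can be
skipped at that step) and takes the mean thickness over the full column
region. Severity association uses the first-order partial correlation
controlling age, r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)), with
two-sided p from t = r√((n−3)/(1−r²)) on n−3 df — identical to
correlating the age-residualized variables, which the tests assert to
1e−10. Plain Pearson (age ignored) is also reported. The bare-cluster
alternative to the full-column ROI is available by passing the cluster mask
directly to `mean_roi_thickness`.

## Synthetic data: what it emulates, what it does not

**Phantoms.** Slab (exact truth N·h), spherical shell (closed-form
harmonic potential; truth R2−R1; half-open [R1, R2) labeling), folded
random sheet (smooth seeded height field; no scalar truth — used only for
PDE-vs-tracer equivalence), and the buried sulcus: a U-shaped GM ribbon
(two 2 mm banks + fundus) around a 1 mm CSF sheet opening into a top CSF
pool. A *fully* sealed sulcus would leave the fused GM with no CSF boundary
at all (ill-posed), so the sealed variant erases only the buried lower
part of the sheet — which is also what partial-volume failure does to a
real sulcus: the deep portion seals first. Erased voxels keep a reduced GM
probability (0.45, a free parameter — real segmenters' error modes are not
quantified) so the probability maps dissent exactly where the correction
must act. Shell and folded phantoms carry linearized partial-volume
probability maps whose interpolated 0.5-crossings sit on the analytic
surfaces; the slab's staircase already coincides with voxel faces.

**Cohorts.** Two groups of 10 (the scale of single-site disaster-survivor
studies), each subject a thickness map in a common space:
base(x) + b_i + β_age·age_i − effect·patch(x)·affected_i + ε_i(x), with
between-subject SD 0.13 mm (the between-subject spread of whole-cortex
means reported for cohorts of this kind), voxel noise SD 0.2 mm
(segmentation jitter), ages uniform on 25–55 years, age slope
−0.0016 mm/year (≈16 µm per decade, the canonical aging rate), effect
0.5 mm in an 8 mm-radius patch, on a 4 mm slab base at 48³ (a desk-scale
stand-in for 256×256×176 acquisitions). Severity is generated as
intercept + a·(patch mean) + b·age + noise with a solved from the requested
partial correlation (default −0.75) given the noise SD (8, CAPS-like
units): published studies report only the empirical r, never a generative
model, so the coupling form is a design choice. A summary fast path draws
(ROI mean, age, severity) from the same distribution without building maps,
for replicate studies of the estimator; its distributional agreement with
the map route is itself tested.

What passing these tests shows: the solver, transport, correction and
statistics are correct on geometry with known truth and data drawn from the
stated model. What they do not show: robustness to real segmentation error
beyond the modeled modes, registration error (inputs are assumed already in
a common space), non-Gaussian noise, or cortical geometry more convoluted
than the phantom families.

## Problem sizes and determinism

Defaults were chosen so the full validation (test suite plus the
acceptance script) runs in well under a minute of compute: 48³ cohort
grids, ~55³ shell at 0.5 mm, a few thousand traced streamlines where
subsampling is used (full GM where the margin warrants determinism). All
PDE stages are deterministic; all simulation randomness flows through
explicit integer seeds.

## Known limitations

- First-order upwind transport underestimates lengths by O(h) along
  oblique characteristics (shell mean 3.90 mm vs 4.0 truth at h = 0.5);
  a second-order scheme was prototyped and did not improve the
  PDE-vs-tracer agreement enough to justify its stability caveats.
- The tangent-cone region growing and the one-voxel-per-streamline
  correction operationalize a procedure the neuroimaging literature
  describes only loosely; the 60° cone, 26-connectivity and the 5 mm
  ceiling are configurable defaults, not identities.
- Whether the voxel threshold is applied one- or two-sided per planned
  contrast varies across the field; here it is one-sided per contrast,
  with both contrasts always computed.
- Ridge-sink voxels are reported, not repaired: a GM pocket whose
  streamlines cannot reach both boundaries has no defined thickness under
  this model.
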