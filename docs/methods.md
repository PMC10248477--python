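# Methods

This note documents the models, numerical choices and known limitations of
`fontanflow`: what each stage assumes, why the defaults are what they are,
and what the synthetic phantoms do and do not establish about real data.

## Scope and data model

The pipeline operates on a three-component velocity field sampled on a
regular voxel grid together with an integer segmentation of the total
cavopulmonary connection (SVC, conduit, LPA, RPA, junction). Velocities are
held in m/s; grid spacing and positions in mm; voxel index (i,j,k) maps to
the center position origin + (i,j,k)·spacing. Time-resolved inputs are
reduced by per-voxel arithmetic averaging before any quantification —
all downstream analysis is of the steady, time-averaged field, matching the
steady treatment of the paired CFD modality. Blood is Newtonian with
ρ = 1060 kg/m³ and μ = 0.0035 Pa·s (defaults of `FluidProperties`;
overridable). On-disk formats are NIfTI-1 for fields and masks (either one
file per component or a single multi-component volume; cm/s inputs are
converted on load), CSV for CFD point clouds, and CSV/JSON for reports.

Upstream steps that produce these inputs — DICOM conversion, phase-offset
and aliasing correction, manual segmentation, surface smoothing, and any CFD
solver — are outside the package's scope. CFD results arrive either already
gridded or as scattered points, which are resampled by inverse-distance
weighting (k = 16 nearest neighbors within a user radius, power 2; voxels
with no neighbor in radius are flagged uncovered). Unstructured-mesh cell
volumes are not imported: fine-grid voxel integration (default 0.4 mm)
stands in for cell-wise integrals, which makes grid resolution — the
experimentally relevant variable — explicit.

## Energetics

Kinetic energy density ½ρ|u|² and the laminar viscous dissipation function

φ_VD = μ[2(∂u_x/∂x)² + 2(∂u_y/∂y)² + 2(∂u_z/∂z)²
        + (∂u_y/∂x + ∂u_x/∂y)² + (∂u_z/∂y + ∂u_y/∂z)²
        + (∂u_x/∂z + ∂u_z/∂x)²]

are integrated voxel-wise over the segmented lumen (totals reported in mJ
and mW). No turbulent or Reynolds-stress contribution is modelled. The
velocity gradient uses central differences where both axis neighbors lie
inside the mask and one-sided differences at the wall; a voxel with no
masked neighbor along some axis is flagged invalid and excluded from the
integral. This stencil family is exact on linear fields (so uniform flow
and rigid rotation dissipate exactly zero — a symmetry the dissipation
function must honor) and never differences across the wall into zero-padded
background, which would manufacture spurious shear. Global metrics
integrate over the full segmentation including the junction; any label
subset can be selected instead.

Accuracy on the voxelized Poiseuille phantom (R = 7 mm, U = 0.08 m/s,
L = 40 mm) at 0.4 mm spacing: KE within 0.01% of (2/3)ρπR²U²L, VD within
3.4% of 8πμU²L, plane flow rate within 0.2% of πR²U. VD converges from
below at clinical resolutions because wall shear is under-resolved: the
same tube evaluated at 2.0 mm recovers only about half the analytic
dissipation. That resolution sensitivity is a property of the estimator on
coarse data, not a defect — quantifying it across modalities is one purpose
of the package.

## Cut planes

Cross-sections are sampled on a regular in-plane lattice (default pitch =
min spacing / 4) with trilinear velocity interpolation; a sample belongs to
the lumen when the trilinearly interpolated region indicator is ≥ 0.5
(midpoint rule — stated explicitly so diameters are reproducible). Flow
rate is the signed sum Σ(u·n)dA over lumen samples; effective diameter is
that of the area-equivalent circle. By default a region's plane passes
through its voxel centroid with the principal axis of its voxel cloud as
normal, oriented along the mean regional velocity; planes can be pinned
per region (origin + normal) in the run configuration. Halving the lattice
pitch changes tube flow rate by <1%; lumen areas carry a half-pitch rim
uncertainty that matters only when a region is a few voxels across.

## Streamline tracing and flow distribution

Pulmonary flow distribution is computed by steady streamline tracing of the
time-averaged field (not time-resolved pathlines): 4th-order Runge-Kutta in
arc length, trilinear interpolation, default step = min spacing / 4, max
10,000 steps, stagnation cutoff 1e-4 m/s. With these defaults a circular
orbit in a rigid-rotation field closes to well under 0.5% radius drift per
revolution. A trace is classified at its first crossing of an outlet
cutting plane inside that outlet's lumen; traces that leave the mask,
stagnate, or exhaust the step budget count as "missing" and are excluded
from the percentage denominator but reported as a missing fraction — on
clean phantoms this fraction is below 1%, while noisy coarse fields lose
markedly more traces, which is the diagnostic's purpose.

Seeding is flux-weighted by default (inlet lattice points drawn with
probability ∝ |u·n|, with sub-pitch jitter), with seeds allocated to the
two inlets proportionally to inlet flow magnitude, so pooled
"total to LPA/RPA" percentages are flow-representative. Area-uniform
seeding and count-weighted pooling are available; the pooling rule for the
published per-case tables is not recoverable from the tables themselves, so
it remains configurable.

## Comparison statistics

Regression direction is fixed as x = MRI, y = CFD, and Bland-Altman
differences as CFD − MRI: with these conventions the packaged reference
tables reproduce their published summary rows and biases exactly (e.g. the
kinetic-energy bias −0.03 mJ and the SVC→LPA distribution bias +6.0%).
All SDs are sample SDs (n−1). Pearson r carries a two-sided p from the
t distribution on n−2 degrees of freedom; p < 0.05 is annotated, never used
to drop data. The OLS identity mean(y) = slope·mean(x) + intercept and the
bias identity bias = mean(y) − mean(x) hold to machine precision and are
asserted in the tests. Reported correlation coefficients for such cohorts
are sensitive to the rounding of tabulated per-case values, so r is
reported but not treated as a reference quantity.

## Synthetic phantoms

`poiseuille_tube` voxelizes u(r) = 2U(1 − r²/R²) with closed-form truth
(Q = πR²U, Vmax = 2U, KE = (2/3)ρπR²U²L, VD = 8πμU²L). The tube axis is
placed mid-voxel so the even profile is sampled symmetrically about the
wall, keeping the wall-shear voxelization error consistent across grid
refinements (VD at 0.4 vs 0.8 mm differs by ~1%).

`tcpc_cross_phantom` builds a planar cross — conduit entering from below,
SVC from above, LPA/RPA exiting left/right — from a streamfunction:
u = ∇×(0, χ, 0) with

χ = (1 − β)·P_conduit + β·(q_LPA − P_SVC),   β = P_LPA / q_LPA,

where P_branch is the branch's cumulative transverse Poiseuille profile and
q the per-slice flux. Velocities are produced by the same central
differences used by the discrete divergence, and mixed central differences
commute, so the field is divergence-free to machine precision on interior
lumen voxels (measured ~1e-14 1/s against a 1e-3 1/s requirement). The
construction reproduces exact Poiseuille far fields in all four branches and
honors the prescribed outlet flux split (plane fluxes within 2% at 1 mm
spacing). An iterative pressure-projection cleanup was considered and
rejected: the streamfunction form is exact, symmetric under the inlet-
swapping mirror (so equal inflows provably split each inlet by the outlet
flux ratio — the basis for the per-inlet ground truth), and has no
convergence failure mode. Its cost is one constraint: because u_y = 0 makes
every y-slice an independent 2D flow, per-slice mass balance forces all four
branches to share one radius. Junction energetics have no closed form, so
cross-phantom truth covers flows, splits and Vmax only.

`degrade_to_mri` emulates the acquisition chain the comparison assumes:
box-average downsampling by an integer factor to the acquired voxel size
(default 2.0 mm isotropic), majority-vote relabelling of coarse voxels at
least half inside the lumen, then additive independent Gaussian noise per
component inside the coarse lumen. The default noise sd of 0.01 m/s follows
phase-contrast noise scaling σ ≈ √2·venc/(π·SNR) for venc 0.4–0.8 m/s at
contrast-enhanced SNR ≈ 20–30. Downsampling to the 2.0 mm acquisition
target never increased VD on any clean phantom tested (from 0.4, 0.5 or
1.0 mm); at near-unity factors (e.g. 0.4→0.8 mm) wall partial-volume
relabelling can perturb the discrete VD a few percent in either direction,
so no monotonicity is claimed there.

`make_synthetic_cohort` draws paired fine (0.4 mm) / degraded (2.0 mm +
noise) cross cases: common radius 4.5–7.0 mm (the 8–14 mm regional diameter
range of Fontan anatomy), equal SVC/conduit inflow of 0.15–0.30 m/s, LPA
flow fraction 0.35–0.65. The velocity scale is anchored so the cohort's
energetics land inside the ranges a real Fontan cohort exhibits (global
Vmax ≈ 0.4–0.8 m/s, fine-grid VD ≈ 0.2–0.8 mW): the common-radius
constraint means a single case cannot combine a slow wide conduit with
faster narrow pulmonary arteries, and anchoring to the slowest region
instead would push the emulated MRI into a noise-dominated dissipation
regime that measured Fontan cohorts do not show. In this regime the central
resolution effect is robust: fine-grid VD exceeds the degraded-field VD in
every generated case (worst-corner ratio ≈ 1.2, typically ≈ 1.7).

What the phantoms do not emulate: pulsatility (all analysis is of the
time-averaged field), non-Newtonian rheology, wall motion, k-space /
partial-volume MRI physics, venc-dependent noise scaling, segmentation
error, and realistic junction geometry (offset, flaring, curvature).
Passing phantom tests therefore validates the estimators and their
resolution/noise response, not the clinical values of any particular
patient anatomy.

## Determinism and problem sizes

Every stochastic component (seeding, noise, cohort specs) flows from an
explicit integer seed through `numpy.random.default_rng`; rerunning any
pipeline stage with the same inputs, configuration and seed yields
byte-identical reports. Default analysis sizes — 10-case synthetic cohorts,
20 mm branches, 10,000 traced seeds — keep a full verification run within a
couple of minutes on a single CPU while leaving the statistical tolerances
(binomial error of a 50% split at 5,000 classified traces ≈ 0.7%) well
inside the asserted bounds.

## Known limitations

- Binary voxel masks make small-vessel diameters and wall shear jagged;
  there is no sub-voxel surface model.
- VD at 2.0 mm resolution is a systematic underestimate (by design it
  reports what the data support, not a resolution-corrected value).
- The missing-trace fraction of real 4D flow data depends on acquisition
  noise and segmentation quality; the phantom pipeline demonstrates its
  direction (degradation loses traces), not its clinical magnitude.
- Per-inlet flow splits on asymmetric-inflow phantoms have no closed form;
  ground truth is only asserted for equal inflows (mirror symmetry) and for
  pooled splits (prescribed fluxes).
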