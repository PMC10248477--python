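# fontanflow

Hemodynamic quantification and modality comparison for the Fontan
circulation (total cavopulmonary connection, TCPC).

After the Fontan procedure, systemic venous blood flows passively into the
pulmonary arteries through the superior vena cava (SVC) and an extracardiac
conduit. Two questions dominate the clinical assessment of this circulation:
how much mechanical energy the connection wastes, and how flow from each
inlet distributes between the left and right pulmonary arteries (LPA/RPA).
Both can be measured from 4D flow MRI velocity fields or from CFD built on
MRI-derived boundary conditions — and the two modalities famously disagree
where spatial resolution and velocity noise matter. `fontanflow` implements
the full quantification pipeline plus the agreement statistics needed to
compare modalities, and ships analytic flow phantoms so every stage is
verifiable against closed forms without patient data.

## What it computes

For a segmented voxel velocity field **u** (regions: SVC, conduit, LPA, RPA,
junction), with blood density ρ = 1060 kg/m³ and viscosity μ = 0.0035 Pa·s:

- **Kinetic energy**: φ_KE = ½ρ(u_x² + u_y² + u_z²) per voxel;
  KE = Σ φ_KE ΔV over the segmented lumen (mJ).
- **Viscous dissipation** (laminar dissipation function):
  φ_VD = μ[2(∂u_x/∂x)² + 2(∂u_y/∂y)² + 2(∂u_z/∂z)²
  + (∂u_y/∂x + ∂u_x/∂y)² + (∂u_z/∂y + ∂u_y/∂z)²
  + (∂u_x/∂z + ∂u_z/∂x)²]; VD = Σ φ_VD ΔV (mW). Gradients use central
  differences inside the mask and one-sided differences at the wall.
- **Cut-plane metrics**: flow rate Q = Σ (u·n) dA and effective diameter
  D = 2√(A/π) on an oriented cross-section through each region.
- **Pulmonary flow distribution** by streamline tracing (RK4, trilinear
  interpolation): PFD_{A,B} = N_{A,B}/(N_{A,LPA} + N_{A,RPA}) · 100 for
  inlet A and outlet B, plus the missing-trace fraction as a data-quality
  diagnostic.
- **Modality agreement**: ordinary least squares of CFD on MRI, Pearson r,
  and Bland-Altman bias ± SD with 1.96·SD limits of agreement
  (differences taken as CFD − MRI); cohort mean ± SD tables.

A reference cohort of 29 Fontan patients (per-case Vmax/KE/VD, flow
distribution, and regional metrics for both modalities) is packaged as CSV
so the statistics layer runs with no field data
(`fontanflow.load_reference_cohort("energetics" | "pfd" | "regional")`).

The synthetic-data module generates divergence-free phantoms with known
ground truth: a Poiseuille tube (closed-form Q, Vmax, KE, VD) and a
four-branch TCPC cross built from a blended streamfunction (exactly
solenoidal; prescribed outlet flux split), plus the MRI degradation operator
(box-average downsampling to 2.0 mm voxels + Gaussian velocity noise).

## Worked example

```python
import fontanflow as ff

# a TCPC cross phantom: equal inflows, 40:60 LPA:RPA outflow split
field, mask, truth = ff.tcpc_cross_phantom(
    radius_mm=6.0, branch_length_mm=20.0, spacing_mm=1.0,
    velocities={"svc": 0.10, "conduit": 0.10, "lpa": 0.08, "rpa": 0.12})

summary = ff.regional_summary(field, mask)
g = summary.global_
print(f"global: Vmax {g.vmax_m_s:.2f} m/s, KE {g.ke_mJ:.3f} mJ, VD {g.vd_mW:.3f} mW")

inlets  = {r: ff.extract_plane(field, mask, r) for r in ("svc", "conduit")}
outlets = {r: ff.extract_plane(field, mask, r) for r in ("lpa", "rpa")}
pfd = ff.trace_pulmonary_distribution(field, mask, inlets, outlets,
                                      n_seeds=10000, rng_seed=1)
for src in ("svc", "conduit"):
    print(f"PFD {src} -> LPA {pfd.pfd_pct[src]['lpa']:.1f}%")
print(f"total -> LPA {pfd.total_pct['lpa']:.1f}%")
```

prints

```
global: Vmax 0.24 m/s, KE 0.075 mJ, VD 0.070 mW
PFD svc -> LPA 41.1%
PFD conduit -> LPA 40.6%
total -> LPA 40.8%
```

The traced distribution (40.8% of total flow to the LPA, ~0.5% of traces
missing) recovers the prescribed 40% outlet flux split; Vmax is twice the
branch mean velocity as expected for parabolic profiles, and KE/VD are the
volume integrals above. On the Poiseuille tube at 0.4 mm spacing the same
estimators land within 1% (KE), 4% (VD) and 1% (Q) of the closed forms.

The same pipeline runs from the shell: `fontanflow phantom | quantify |
trace | compare | cohort` (see `fontanflow --help`). `compare` is a
stats-only mode for cohort CSVs with `metric__mri` / `metric__cfd` columns.

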