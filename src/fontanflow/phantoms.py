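"""Analytic, divergence-free flow phantoms with closed-form ground truth.

Two geometries are provided:

* ``poiseuille_tube`` — a straight circular tube with the parabolic profile
  u(r) = 2U(1 - r^2/R^2).  Closed forms: Q = pi R^2 U, Vmax = 2U,
  KE = (2/3) rho pi R^2 U^2 L, VD = 8 pi mu U^2 L.
* ``tcpc_cross_phantom`` — a desk-scale total cavopulmonary connection:
  two vertical inlets (conduit from below, SVC from above) and two
  horizontal outlets (LPA to -x, RPA to +x) meeting at a cross junction.

The cross field is built from a streamfunction: u = curl (0, chi, 0) with
chi blended from per-branch cumulative Poiseuille profiles,

    chi = (1 - beta) * P_conduit + beta * (q_lpa - P_svc),
    beta = (cumulative LPA slice profile) / (LPA slice flux),

which reproduces the exact Poiseuille profile in every branch far field and
is exactly divergence-free: velocities are obtained with the same central
differences used by the discrete divergence, and mixed central differences
commute, so div u vanishes to machine precision on interior lumen voxels.
Because each y-slice carries an independent 2D flow (u_y = 0), per-slice
mass balance requires all four branches to share one radius; the
straight-tube phantom has no such restriction.

The MRI degradation operator emulates the acquisition chain assumed by the
comparison pipeline: box-average downsampling to the acquired voxel size
(2.0 mm isotropic by default) followed by additive Gaussian velocity noise
inside the lumen.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import (CONDUIT, JUNCTION, LPA, RPA, SVC, SegmentationMask,
                   VelocityField)
from .errors import SpecError
from . import field_io

#: default acquired voxel size of the emulated MRI, mm
MRI_SPACING_MM = 2.0
#: default fine "CFD-like" grid spacing, mm
CFD_SPACING_MM = 0.4
#: default per-component velocity noise sd, m/s (phase-contrast noise for
#: venc 0.4-0.8 m/s at contrast-enhanced SNR ~ 20-30)
MRI_NOISE_SD = 0.01


@dataclass
class PhantomSpec:
    """Specification of a synthetic flow phantom."""

    kind: str                      # "tube" | "tcpc-cross"
    radius_mm: float
    length_mm: float               # tube length / branch length
    spacing_mm: float
    velocities: dict[str, float]   # mean velocity per branch, m/s
    noise_sd: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("tube", "tcpc-cross"):
            raise SpecError(f"unknown phantom kind {self.kind!r}")
        if self.radius_mm <= 2.0 * self.spacing_mm:
            raise SpecError(
                f"lumen unresolvable: radius {self.radius_mm} mm must exceed "
                f"twice the spacing {self.spacing_mm} mm")
        if self.kind == "tcpc-cross":
            q_in = self.velocities.get("svc", 0) + self.velocities.get("conduit", 0)
            q_out = self.velocities.get("lpa", 0) + self.velocities.get("rpa", 0)
            if abs(q_in - q_out) > 1e-9 * max(abs(q_in), 1e-30):
                raise SpecError(
                    f"unbalanced flows: inflow {q_in} != outflow {q_out} "
                    "(common radius: mean velocities must balance)")


@dataclass
class PhantomTruth:
    """Closed-form ground truth of a phantom.

    ``ke_total_mJ``/``vd_total_mW`` are None for the cross phantom (the
    junction has no closed form); per-branch flow rates and — when the two
    inflows are equal, by mirror symmetry — per-inlet outlet splits are exact.
    """

    ke_total_mJ: float | None
    vd_total_mW: float | None
    q_L_min: dict[str, float]
    splits_pct: dict[str, dict[str, float]] | None
    vmax_m_s: float


def _sym_axis(extent_mm: float, spacing_mm: float) -> np.ndarray:
    """Voxel-center coordinates symmetric about 0 (0 is a voxel center)."""
    half = int(np.ceil(extent_mm / spacing_mm))
    return (np.arange(2 * half + 1) - half) * spacing_mm


def poiseuille_tube(radius_mm: float = 7.0, mean_velocity: float = 0.08,
                    length_mm: float = 40.0, spacing_mm: float = CFD_SPACING_MM,
                    label: int = CONDUIT, margin_voxels: int = 2
                    ) -> tuple[VelocityField, SegmentationMask, PhantomTruth]:
    """Straight tube along z with the parabolic Poiseuille profile."""
    spec = PhantomSpec(kind="tube", radius_mm=radius_mm, length_mm=length_mm,
                       spacing_mm=spacing_mm,
                       velocities={"tube": mean_velocity})
    h = spacing_mm
    # tube axis passes mid-voxel (offset h/2): samples the even profile
    # symmetrically about the wall and keeps the wall-shear voxelization
    # error consistent across grid refinements
    xy = _sym_axis(radius_mm + margin_voxels * h, h) + h / 2.0
    nz = max(1, int(round(length_mm / h)))
    X, Y = np.meshgrid(xy, xy, indexing="ij")
    r2 = X**2 + Y**2
    inside = r2 <= radius_mm**2
    uz = np.where(inside, 2 * mean_velocity * (1 - r2 / radius_mm**2), 0.0)
    dims = (len(xy), len(xy), nz)
    u = np.zeros((3,) + dims)
    u[2] = uz[:, :, None]
    labels = np.zeros(dims, np.int16)
    labels[inside, :] = label

    origin = np.array([xy[0], xy[0], 0.0])
    field = VelocityField(u, spacing=[h, h, h], origin=origin)
    mask = SegmentationMask(labels, spacing=[h, h, h], origin=origin)

    from .core import BLOOD
    R = radius_mm * 1e-3
    L = length_mm * 1e-3
    U = mean_velocity
    truth = PhantomTruth(
        ke_total_mJ=(2.0 / 3.0) * BLOOD.density * np.pi * R**2 * U**2 * L * 1e3,
        vd_total_mW=8.0 * np.pi * BLOOD.viscosity * U**2 * L * 1e3,
        q_L_min={"tube": np.pi * R**2 * U * 6e4},
        splits_pct=None,
        vmax_m_s=2 * U)
    return field, mask, truth


def _cum_profile(t: np.ndarray, w: np.ndarray, R: float, U: float
                 ) -> np.ndarray:
    """Cumulative transverse integral of the clipped Poiseuille profile.

    Integral over t' in (-inf, t] of 2U(1 - (t'^2 + w^2)/R^2)_+ at offset w;
    SI units throughout.
    """
    a2 = np.maximum(R**2 - w**2, 0.0)
    a = np.sqrt(a2)
    tc = np.clip(t, -a, a)
    prim = (a2 / R**2) * tc - tc**3 / (3.0 * R**2)
    prim_lo = -((a2 / R**2) * a - a**3 / (3.0 * R**2))
    return 2.0 * U * (prim - prim_lo)


def _slice_flux(w: np.ndarray, R: float, U: float) -> np.ndarray:
    """Total slice flux q(w) = (8/3) U (R^2 - w^2)^{3/2} / R^2 (clipped)."""
    return (8.0 / 3.0) * U * np.maximum(R**2 - w**2, 0.0) ** 1.5 / R**2


def tcpc_cross_phantom(radius_mm: float = 6.0, branch_length_mm: float = 20.0,
                       spacing_mm: float = 1.0,
                       velocities: dict[str, float] | None = None,
                       noise_sd: float = 0.0, rng_seed: int | None = None,
                       margin_voxels: int = 3
                       ) -> tuple[VelocityField, SegmentationMask, PhantomTruth]:
    """Cross-junction TCPC phantom with exactly solenoidal velocity field.

    ``velocities`` gives the mean velocity (m/s) of each branch
    (svc, conduit, lpa, rpa); inflow and outflow must balance.  All branches
    share ``radius_mm``.  Optional Gaussian noise emulates measurement noise
    on the clean field (usually left at 0; use :func:`degrade_to_mri` for the
    full MRI emulation).
    """
    if velocities is None:
        velocities = {"svc": 0.1, "conduit": 0.1, "lpa": 0.1, "rpa": 0.1}
    spec = PhantomSpec(kind="tcpc-cross", radius_mm=radius_mm,
                       length_mm=branch_length_mm, spacing_mm=spacing_mm,
                       velocities=dict(velocities), noise_sd=noise_sd,
                       rng_seed=rng_seed)
    h = spacing_mm
    R = radius_mm
    Lb = branch_length_mm
    U_c, U_s = velocities["conduit"], velocities["svc"]
    U_l, U_r = velocities["lpa"], velocities["rpa"]

    ext = Lb + R + margin_voxels * h
    x = _sym_axis(ext, h)
    y = _sym_axis(R + margin_voxels * h, h)
    z = _sym_axis(ext, h)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    mm = 1e-3
    Rm = R * mm
    P_c = _cum_profile(X * mm, Y * mm, Rm, U_c)
    P_s = _cum_profile(X * mm, Y * mm, Rm, U_s)
    P_l = _cum_profile(Z * mm, Y * mm, Rm, U_l)
    q_l = _slice_flux(Y * mm, Rm, U_l)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(q_l > 0, P_l / np.where(q_l > 0, q_l, 1.0), 0.0)
    chi = (1.0 - beta) * P_c + beta * (q_l - P_s)

    hm = h * mm
    ux = -np.gradient(chi, hm, axis=2)
    uz = np.gradient(chi, hm, axis=0)
    u = np.stack([ux, np.zeros_like(ux), uz])

    vert = (X**2 + Y**2 <= R**2) & (np.abs(Z) <= Lb + R)
    horiz = (Y**2 + Z**2 <= R**2) & (np.abs(X) <= Lb + R)
    lumen = vert | horiz
    labels = np.zeros(lumen.shape, np.int16)
    labels[vert & (Z < -R)] = CONDUIT
    labels[vert & (Z > R)] = SVC
    labels[horiz & (X < -R)] = LPA
    labels[horiz & (X > R)] = RPA
    labels[lumen & (labels == 0)] = JUNCTION
    u[:, ~lumen] = 0.0

    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        u[:, lumen] += rng.normal(0.0, noise_sd, size=(3, int(lumen.sum())))

    origin = np.array([x[0], y[0], z[0]])
    field = VelocityField(u, spacing=[h, h, h], origin=origin)
    mask = SegmentationMask(labels, spacing=[h, h, h], origin=origin)

    area = np.pi * Rm**2
    q = {name: area * velocities[name] * 6e4
         for name in ("svc", "conduit", "lpa", "rpa")}
    if abs(U_c - U_s) <= 1e-12 * max(U_c, 1e-30):
        # mirror symmetry in z: both inlets split like the outlet flux ratio
        lpa_pct = 100.0 * U_l / (U_l + U_r)
        splits = {inlet: {"lpa": lpa_pct, "rpa": 100.0 - lpa_pct}
                  for inlet in ("svc", "conduit")}
    else:
        splits = None
    truth = PhantomTruth(ke_total_mJ=None, vd_total_mW=None, q_L_min=q,
                         splits_pct=splits,
                         vmax_m_s=2 * max(velocities.values()))
    return field, mask, truth


def divergence(field: VelocityField, mask: SegmentationMask
               ) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference divergence (1/s) and the interior-voxel indicator.

    Interior voxels are lumen voxels whose six axis neighbors are all inside
    the lumen (the divergence stencil never reaches the clipped background).
    """
    u = field.u3
    h = field.spacing_m
    div = sum(np.gradient(u[a], h[a], axis=a) for a in range(3))
    lum = mask.lumen
    interior = lum.copy()
    for a in range(3):
        interior &= np.roll(lum, 1, axis=a) & np.roll(lum, -1, axis=a)
    for a in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[a] = edge
            interior[tuple(sl)] = False
    return div, interior


# ---------------------------------------------------------------------------
# MRI degradation
# ---------------------------------------------------------------------------

def degrade_to_mri(field: VelocityField, mask: SegmentationMask,
                   target_spacing_mm: float = MRI_SPACING_MM,
                   noise_sd: float = MRI_NOISE_SD,
                   rng_seed: int | None = None
                   ) -> tuple[VelocityField, SegmentationMask]:
    """Downsample to the acquired voxel size and add velocity noise.

    Each component is box-averaged over ``f^3`` blocks where ``f`` is the
    (integer) ratio of target to source spacing; the coarse lumen consists of
    blocks at least half inside the fine lumen, labelled by the majority fine
    label.  Independent Gaussian noise of sd ``noise_sd`` (m/s) is then added
    per component inside the coarse lumen.  Reproducible for a fixed seed.
    """
    src = float(field.spacing[0])
    if not np.allclose(field.spacing, src):
        raise SpecError("degradation requires isotropic source spacing")
    ratio = target_spacing_mm / src
    f = int(round(ratio))
    if f < 1 or abs(ratio - f) > 1e-8:
        raise SpecError(
            f"target spacing {target_spacing_mm} mm is not an integer "
            f"multiple of source spacing {src} mm")
    if f == 1 and noise_sd == 0:
        return field, mask

    dims = np.array(field.dims)
    nd = (dims // f) * f
    crop = tuple(slice(0, n) for n in nd)
    u = field.u3[(slice(None),) + crop]
    labels = mask.labels[crop]
    cd = tuple(nd // f)

    def blocks(a):
        return a.reshape(cd[0], f, cd[1], f, cd[2], f)

    u_coarse = np.stack([
        blocks(u[c]).mean(axis=(1, 3, 5)) for c in range(3)])
    frac_in = blocks((labels > 0).astype(float)).mean(axis=(1, 3, 5))
    lumen_c = frac_in >= 0.5

    lab_blocks = blocks(labels).transpose(0, 2, 4, 1, 3, 5).reshape(*cd, f**3)
    labels_c = np.zeros(cd, np.int16)
    idx = np.argwhere(lumen_c)
    for i, j, k in idx:
        vals = lab_blocks[i, j, k]
        vals = vals[vals > 0]
        labels_c[i, j, k] = np.bincount(vals).argmax()

    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        u_coarse[:, lumen_c] += rng.normal(
            0.0, noise_sd, size=(3, int(lumen_c.sum())))
    u_coarse[:, ~lumen_c] = 0.0

    origin_c = field.origin + (f - 1) / 2.0 * field.spacing
    spacing_c = field.spacing * f
    return (VelocityField(u_coarse, spacing=spacing_c, origin=origin_c),
            SegmentationMask(labels_c, spacing=spacing_c, origin=origin_c))


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCase:
    """A paired fine ("CFD-like") and degraded ("MRI-like") synthetic case."""

    case_id: str
    spec: PhantomSpec
    truth: PhantomTruth
    cfd: tuple[VelocityField, SegmentationMask]
    mri: tuple[VelocityField, SegmentationMask]


def make_synthetic_cohort(n_cases: int, rng_seed: int | None = None,
                          out_dir=None,
                          fine_spacing_mm: float = CFD_SPACING_MM,
                          mri_spacing_mm: float = MRI_SPACING_MM,
                          noise_sd: float = MRI_NOISE_SD,
                          branch_length_mm: float = 20.0
                          ) -> list[SyntheticCase]:
    """Generate paired fine/degraded TCPC cross cases with known truth.

    Specs are randomized to land the cohort's energetics inside the ranges a
    Fontan cohort exhibits: common branch radius 4.5-7.0 mm (regional
    diameters 8-14 mm), inlet mean velocities 0.15-0.30 m/s with equal
    SVC/conduit inflow (giving peak velocities of roughly 0.4-0.8 m/s and
    fine-grid dissipation of roughly 0.2-0.8 mW), and an LPA flow fraction
    of 0.35-0.65.  The velocity scale is anchored to the cohort-level
    energetics rather than to the slowest region because all branches share
    one radius, so a single case cannot reproduce the conduit-vs-branch
    velocity heterogeneity of real anatomy.  With ``out_dir`` set, fields,
    masks and a truth manifest are also written per case.
    """
    if n_cases < 1:
        raise SpecError("need at least one case")
    rng = np.random.default_rng(rng_seed)
    cases = []
    for i in range(n_cases):
        radius = rng.uniform(4.5, 7.0)
        u_in = rng.uniform(0.15, 0.30)
        lpa_frac = rng.uniform(0.35, 0.65)
        vel = {"svc": u_in, "conduit": u_in,
               "lpa": 2 * u_in * lpa_frac, "rpa": 2 * u_in * (1 - lpa_frac)}
        noise_seed = int(rng.integers(0, 2**31 - 1))
        f_field, f_mask, truth = tcpc_cross_phantom(
            radius_mm=radius, branch_length_mm=branch_length_mm,
            spacing_mm=fine_spacing_mm, velocities=vel)
        m_field, m_mask = degrade_to_mri(
            f_field, f_mask, target_spacing_mm=mri_spacing_mm,
            noise_sd=noise_sd, rng_seed=noise_seed)
        spec = PhantomSpec(kind="tcpc-cross", radius_mm=radius,
                           length_mm=branch_length_mm,
                           spacing_mm=fine_spacing_mm, velocities=vel,
                           noise_sd=noise_sd, rng_seed=noise_seed)
        cases.append(SyntheticCase(case_id=f"case{i + 1:03d}", spec=spec,
                                   truth=truth, cfd=(f_field, f_mask),
                                   mri=(m_field, m_mask)))

    if out_dir is not None:
        out_dir = Path(out_dir)
        for case in cases:
            cdir = out_dir / case.case_id
            field_io.save_velocity_field(*case.cfd, cdir, stem="cfd")
            field_io.save_velocity_field(*case.mri, cdir, stem="mri")
            manifest = {"spec": dataclasses.asdict(case.spec),
                        "truth": dataclasses.asdict(case.truth)}
            with open(cdir / "truth.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
    return cases
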