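import numpy as np
import pytest

import fontanflow as ff
from fontanflow.core import BLOOD
from fontanflow.errors import DomainError, GeometryError
from fontanflow.quantify import PlaneSpec

from conftest import uniform_field


def linear_field(a=2.0, shape=(8, 8, 8), spacing=1.0):
    """ux = a * x (a in 1/s); single-label mask over the whole block."""
    x_m = np.arange(shape[0])[:, None, None] * spacing * 1e-3
    u = np.zeros((3,) + shape)
    u[0] = np.broadcast_to(a * x_m, shape)
    field = ff.VelocityField(u, spacing=[spacing] * 3)
    mask = ff.SegmentationMask(np.full(shape, ff.CONDUIT, np.int16),
                               spacing=[spacing] * 3)
    return field, mask


def rotation_field(omega=1.0, shape=(12, 12, 6), spacing=1.0):
    """Rigid rotation u = (-w y, w x, 0) about the grid center."""
    idx = np.indices(shape).astype(float)
    c = (np.array(shape) - 1) / 2
    x = (idx[0] - c[0]) * spacing * 1e-3
    y = (idx[1] - c[1]) * spacing * 1e-3
    u = np.stack([-omega * y, omega * x, np.zeros(shape)])
    field = ff.VelocityField(u, spacing=[spacing] * 3)
    mask = ff.SegmentationMask(np.full(shape, ff.CONDUIT, np.int16),
                               spacing=[spacing] * 3)
    return field, mask


class TestVelocityStatistics:
    def test_constant_field(self):
        field, mask = uniform_field(u=(0.3, 0, 0))
        vmax, vmean = ff.velocity_statistics(field, mask)
        assert vmax == pytest.approx(0.3)
        assert vmean == pytest.approx(0.3)

    def test_two_voxel_arithmetic(self):
        u = np.zeros((3, 2, 1, 1))
        u[0, 0] = 0.1
        u[0, 1] = 0.5
        field = ff.VelocityField(u, spacing=[1, 1, 1])
        mask = ff.SegmentationMask(np.full((2, 1, 1), 2, np.int16),
                                   spacing=[1, 1, 1])
        vmax, vmean = ff.velocity_statistics(field, mask)
        assert vmax == pytest.approx(0.5)
        assert vmean == pytest.approx(0.3)

    def test_poiseuille_mean_is_bulk_velocity(self, tube):
        # area average of 2U(1 - r^2/R^2) over the disc is U
        field, mask, truth = tube
        vmax, vmean = ff.velocity_statistics(field, mask)
        assert vmax == pytest.approx(truth.vmax_m_s, rel=0.02)
        # slow near-wall voxels bias the mean low at R/h ~ 9
        assert vmean == pytest.approx(0.08, rel=0.04)

    def test_empty_selection_raises(self):
        field, mask = uniform_field()
        with pytest.raises(DomainError):
            ff.velocity_statistics(field, mask, labels="lpa")


class TestVelocityGradient:
    def test_linear_field_exact_everywhere(self):
        field, mask = linear_field(a=2.0)
        grad = ff.velocity_gradient(field, mask)
        assert grad.valid.all()
        np.testing.assert_allclose(grad.d[0, 0], 2.0, atol=1e-10)
        np.testing.assert_allclose(grad.d[1], 0.0, atol=1e-12)

    def test_rigid_rotation_exact(self):
        field, mask = rotation_field(omega=1.0)
        grad = ff.velocity_gradient(field, mask)
        np.testing.assert_allclose(grad.d[0, 1], -1.0, atol=1e-10)
        np.testing.assert_allclose(grad.d[1, 0], 1.0, atol=1e-10)
        for i in range(3):
            np.testing.assert_allclose(grad.d[i, i], 0.0, atol=1e-12)

    def test_matches_per_voxel_stencil_oracle(self):
        # independent brute-force evaluation of the same stencil rules on a
        # random smooth field with an irregular mask
        rng = np.random.default_rng(10)
        shape = (7, 6, 5)
        u = rng.normal(0, 0.1, size=(3,) + shape)
        labels = (rng.random(shape) < 0.8).astype(np.int16) * ff.CONDUIT
        spacing = 1.5
        field = ff.VelocityField(u, spacing=[spacing] * 3)
        mask = ff.SegmentationMask(labels, spacing=[spacing] * 3)
        grad = ff.velocity_gradient(field, mask)

        m = labels > 0
        h = spacing * 1e-3
        for i in range(3):
            for j in range(3):
                for p in np.argwhere(m):
                    pp, pm = p.copy(), p.copy()
                    pp[j] += 1
                    pm[j] -= 1
                    has_p = pp[j] < shape[j] and m[tuple(pp)]
                    has_m = pm[j] >= 0 and m[tuple(pm)]
                    if has_p and has_m:
                        exp = (u[i][tuple(pp)] - u[i][tuple(pm)]) / (2 * h)
                    elif has_p:
                        exp = (u[i][tuple(pp)] - u[i][tuple(p)]) / h
                    elif has_m:
                        exp = (u[i][tuple(p)] - u[i][tuple(pm)]) / h
                    else:
                        assert not grad.valid[tuple(p)]
                        continue
                    assert grad.d[i, j][tuple(p)] == pytest.approx(exp)


class TestKineticEnergy:
    def test_uniform_field_closed_form(self):
        # 1 m/s over 1 cm^3 at rho=1060 -> 0.5 * 1060 * 1e-6 J = 0.53 mJ
        field, mask = uniform_field(shape=(10, 10, 10), u=(1.0, 0, 0),
                                    spacing=1.0)
        ke, _ = ff.kinetic_energy(field, mask)
        assert ke == pytest.approx(0.53, rel=1e-12)

    def test_zero_field_is_zero(self):
        field, mask = uniform_field(u=(0, 0, 0))
        ke, _ = ff.kinetic_energy(field, mask)
        assert ke == 0.0

    def test_quadratic_scaling_and_additivity(self, cross):
        field, mask, _ = cross
        ke1, _ = ff.kinetic_energy(field, mask)
        scaled = ff.VelocityField(3.0 * field.u, spacing=field.spacing,
                                  origin=field.origin)
        ke9, _ = ff.kinetic_energy(scaled, mask)
        assert ke9 == pytest.approx(9 * ke1, rel=1e-12)
        parts = sum(ff.kinetic_energy(field, mask, lab)[0]
                    for lab in ("svc", "conduit", "lpa", "rpa", "junction"))
        assert parts == pytest.approx(ke1, rel=1e-12)

    def test_poiseuille_matches_closed_form(self, tube):
        field, mask, truth = tube
        ke, ke_map = ff.kinetic_energy(field, mask)
        assert ke == pytest.approx(truth.ke_total_mJ, rel=0.03)
        assert (ke_map.values >= 0).all()


class TestViscousDissipation:
    def test_uniform_flow_dissipates_nothing(self):
        field, mask = uniform_field(u=(0.4, -0.1, 0.2))
        grad = ff.velocity_gradient(field, mask)
        vd, _ = ff.viscous_dissipation(grad, mask)
        assert vd == 0.0

    def test_rigid_rotation_dissipates_nothing(self):
        # shear terms cancel exactly: duy/dx + dux/dy = w - w = 0
        field, mask = rotation_field(omega=1.0)
        grad = ff.velocity_gradient(field, mask)
        vd, _ = ff.viscous_dissipation(grad, mask)
        assert vd == pytest.approx(0.0, abs=1e-18)

    def test_poiseuille_matches_closed_form(self, tube):
        field, mask, truth = tube
        grad = ff.velocity_gradient(field, mask)
        vd, _ = ff.viscous_dissipation(grad, mask)
        assert vd == pytest.approx(truth.vd_total_mW, rel=0.05)

    def test_quadratic_scaling(self, tube):
        field, mask, _ = tube
        grad = ff.velocity_gradient(field, mask)
        vd1, _ = ff.viscous_dissipation(grad, mask)
        scaled = ff.VelocityField(2.0 * field.u, spacing=field.spacing,
                                  origin=field.origin)
        vd4, _ = ff.viscous_dissipation(ff.velocity_gradient(scaled, mask),
                                        mask)
        assert vd4 == pytest.approx(4 * vd1, rel=1e-12)

    def test_grid_refinement_below_five_percent(self):
        f1, m1, _ = ff.poiseuille_tube(spacing_mm=0.4)
        f2, m2, _ = ff.poiseuille_tube(spacing_mm=0.8)
        vd1, _ = ff.viscous_dissipation(ff.velocity_gradient(f1, m1), m1)
        vd2, _ = ff.viscous_dissipation(ff.velocity_gradient(f2, m2), m2)
        assert abs(vd1 - vd2) / vd1 < 0.05

    def test_resolution_loss_decreases_vd(self):
        f1, m1, _ = ff.poiseuille_tube(spacing_mm=0.4)
        f2, m2 = ff.degrade_to_mri(f1, m1, 2.0, noise_sd=0.0)
        vd1, _ = ff.viscous_dissipation(ff.velocity_gradient(f1, m1), m1)
        vd2, _ = ff.viscous_dissipation(ff.velocity_gradient(f2, m2), m2)
        assert vd2 < vd1


class TestCrossSections:
    def test_lumen_area_matches_circle(self, tube):
        field, mask, _ = tube
        section = ff.extract_plane(field, mask, "conduit")
        assert section.lumen_area_m2 == pytest.approx(
            np.pi * 0.007**2, rel=0.05)

    def test_plane_outside_mask_raises(self, tube):
        field, mask, _ = tube
        spec = PlaneSpec(origin_mm=[0.0, 0.0, -50.0], normal=[0, 0, 1])
        with pytest.raises(GeometryError):
            ff.extract_plane(field, mask, "conduit", spec)

    def test_pitch_refinement_changes_flow_rate_below_one_percent(self, tube):
        field, mask, _ = tube
        q = []
        for frac in (4, 8):
            pitch = float(mask.spacing.min()) / frac
            sec = ff.extract_plane(field, mask, "conduit", pitch_mm=pitch)
            q.append(ff.plane_flow_rate(sec).m3_per_s)
        assert abs(q[1] - q[0]) / abs(q[0]) < 0.01

    def test_uniform_axial_flow_rate(self):
        # 0.1 m/s through 1 cm^2 -> 1e-5 m^3/s = 0.6 L/min
        field, mask = uniform_field(shape=(12, 12, 12), u=(0, 0, 0.1),
                                    spacing=1.0)
        mask.labels[:] = 0
        mask.labels[1:11, 1:11, :] = ff.CONDUIT  # 10 x 10 mm lumen
        spec = PlaneSpec(origin_mm=[5.5, 5.5, 6.0], normal=[0, 0, 1])
        sec = ff.extract_plane(field, mask, "conduit", spec)
        # lumen boundary falls on the 0.5-indicator contour, so the sampled
        # area carries a half-pitch rim: compare at lattice precision
        q = ff.plane_flow_rate(sec)
        assert q.m3_per_s == pytest.approx(1e-5, rel=0.05)
        assert q.L_per_min == pytest.approx(0.6, rel=0.05)

    def test_poiseuille_flux_and_normal_antisymmetry(self, tube):
        field, mask, truth = tube
        sec = ff.extract_plane(field, mask, "conduit")
        q = ff.plane_flow_rate(sec)
        assert q.L_per_min == pytest.approx(truth.q_L_min["tube"], rel=0.05)
        import dataclasses
        flipped = dataclasses.replace(sec, normal=-sec.normal)
        assert ff.plane_flow_rate(flipped).m3_per_s == -q.m3_per_s

    def test_effective_diameter_circle(self, tube):
        field, mask, _ = tube
        sec = ff.extract_plane(field, mask, "conduit")
        assert ff.effective_diameter(sec) == pytest.approx(14.0, rel=0.03)

    def test_effective_diameter_ellipse(self):
        # semi-axes a=6, b=3 mm -> D = 2 sqrt(ab) = 2 sqrt(18)
        shape = (40, 40, 10)
        idx = np.indices(shape).astype(float)
        x = (idx[0] - 19.5) * 0.5
        y = (idx[1] - 19.5) * 0.5
        inside = (x / 6) ** 2 + (y / 3) ** 2 <= 1.0
        labels = np.where(inside, ff.CONDUIT, 0).astype(np.int16)
        u = np.zeros((3,) + shape)
        u[2][inside] = 0.1
        field = ff.VelocityField(u, spacing=[0.5] * 3)
        mask = ff.SegmentationMask(labels, spacing=[0.5] * 3)
        spec = PlaneSpec(origin_mm=[19.5 * 0.5, 19.5 * 0.5, 2.5],
                         normal=[0, 0, 1])
        sec = ff.extract_plane(field, mask, "conduit", spec)
        assert ff.effective_diameter(sec) == pytest.approx(
            2 * np.sqrt(6 * 3), rel=0.03)


class TestRegionalSummary:
    def test_missing_region_is_reported_by_name(self, tube):
        field, mask, _ = tube
        with pytest.raises(DomainError, match="svc"):
            ff.regional_summary(field, mask)

    def test_global_ke_is_sum_of_regional(self, cross):
        field, mask, _ = cross
        summary = ff.regional_summary(field, mask)
        regional = sum(r.ke_mJ for r in summary.regions.values())
        junction, _ = ff.kinetic_energy(field, mask, "junction")
        assert summary.global_.ke_mJ == pytest.approx(regional + junction,
                                                      rel=1e-12)

    def test_uniform_field_has_equal_regional_vmean(self, cross):
        _, mask, _ = cross
        u = np.zeros((3,) + mask.dims)
        u[:] = np.array([0.1, 0.0, 0.05])[:, None, None, None]
        field = ff.VelocityField(u, spacing=mask.spacing, origin=mask.origin)
        summary = ff.regional_summary(field, mask)
        vmeans = [r.vmean_m_s for r in summary.regions.values()]
        np.testing.assert_allclose(vmeans, vmeans[0], rtol=1e-12)

    def test_cross_plane_flows_match_prescription(self, cross):
        field, mask, truth = cross
        summary = ff.regional_summary(field, mask)
        for region in ("svc", "conduit", "lpa", "rpa"):
            assert abs(summary.regions[region].q_L_min) == pytest.approx(
                truth.q_L_min[region], rel=0.05)
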