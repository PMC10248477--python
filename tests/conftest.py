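import numpy as np
import pytest

import fontanflow as ff


@pytest.fixture(scope="session")
def tube():
    """Poiseuille tube phantom, moderately resolved (R/h ~ 9)."""
    field, mask, truth = ff.poiseuille_tube(
        radius_mm=7.0, mean_velocity=0.08, length_mm=40.0, spacing_mm=0.8)
    return field, mask, truth


@pytest.fixture(scope="session")
def cross():
    """Symmetric TCPC cross phantom at 1 mm spacing."""
    return ff.tcpc_cross_phantom(
        radius_mm=6.0, branch_length_mm=20.0, spacing_mm=1.0,
        velocities={"svc": 0.1, "conduit": 0.1, "lpa": 0.1, "rpa": 0.1})


@pytest.fixture(scope="session")
def cross_sections(cross):
    field, mask, _ = cross
    inlets = {r: ff.extract_plane(field, mask, r) for r in ("svc", "conduit")}
    outlets = {r: ff.extract_plane(field, mask, r) for r in ("lpa", "rpa")}
    return inlets, outlets


@pytest.fixture(scope="session")
def energetics_table():
    return ff.load_reference_cohort("energetics")


@pytest.fixture(scope="session")
def pfd_table():
    return ff.load_reference_cohort("pfd")


@pytest.fixture(scope="session")
def regional_table():
    return ff.load_reference_cohort("regional")


def uniform_field(shape=(8, 8, 8), u=(0.3, 0.0, 0.0), spacing=2.0,
                  label=ff.CONDUIT):
    """Constant-velocity block fully covered by a single-label mask."""
    arr = np.zeros((3,) + shape)
    for c in range(3):
        arr[c] = u[c]
    field = ff.VelocityField(arr, spacing=[spacing] * 3)
    mask = ff.SegmentationMask(np.full(shape, label, np.int16),
                               spacing=[spacing] * 3)
    return field, mask
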