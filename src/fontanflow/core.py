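"""Core containers for voxel-grid velocity fields and segmentation masks.

A :class:`VelocityField` holds a (possibly time-resolved) three-component
velocity volume on a regular grid together with its spacing and origin.  A
:class:`SegmentationMask` holds integer region labels on the same grid and
defines both the integration domain for the energetic metrics and the
inlet/outlet topology of the total cavopulmonary connection (TCPC).

Conventions
-----------
* Velocities are stored in m/s; grid spacing and origin in mm.
* ``u`` has shape ``(n_frames, 3, nx, ny, nz)``; component order is
  (ux, uy, uz) along the grid axes.
* Voxel index ``(i, j, k)`` maps to the physical position
  ``origin + (i, j, k) * spacing`` (voxel centers).
* Region labels: 0 background, 1 SVC, 2 conduit, 3 LPA, 4 RPA, 5 junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

BACKGROUND = 0
SVC = 1
CONDUIT = 2
LPA = 3
RPA = 4
JUNCTION = 5

#: region name -> label
REGION_LABELS = {"svc": SVC, "conduit": CONDUIT, "lpa": LPA, "rpa": RPA,
                 "junction": JUNCTION}
#: label -> region name
REGION_NAMES = {v: k for k, v in REGION_LABELS.items()}
#: the four vessel regions required for a valid Fontan case
VESSEL_LABELS = (SVC, CONDUIT, LPA, RPA)
#: inlets and outlets of the TCPC
INLETS = ("svc", "conduit")
OUTLETS = ("lpa", "rpa")


@dataclass(frozen=True)
class FluidProperties:
    """Blood model: density in kg/m^3 and dynamic viscosity in Pa*s.

    Defaults are the Newtonian blood values 1060 kg/m^3 and 0.0035 Pa*s.
    """

    density: float = 1060.0
    viscosity: float = 0.0035

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be strictly positive")


BLOOD = FluidProperties()


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name} must have 3 components")
    return v


@dataclass
class VelocityField:
    """Three-component velocity volume on a regular grid.

    Parameters
    ----------
    u:
        Velocity array, m/s.  Accepted shapes: ``(3, nx, ny, nz)`` (a single
        frame) or ``(n_frames, 3, nx, ny, nz)``.
    spacing, origin:
        Grid spacing and position of the center of voxel (0,0,0), both in mm.
    allow_nan:
        Permit NaN values (used for fields that are undefined outside the
        segmentation); by default all values must be finite.
    """

    u: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    allow_nan: bool = False

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim == 4:
            self.u = self.u[None]
        if self.u.ndim != 5 or self.u.shape[1] != 3:
            raise ValueError(
                "u must have shape (3, nx, ny, nz) or (n_frames, 3, nx, ny, nz)"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise GeometryError("spacing must be strictly positive on all axes")
        if not self.allow_nan and not np.all(np.isfinite(self.u)):
            raise ValueError("velocity field contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.u.shape[2:5]

    @property
    def u3(self) -> np.ndarray:
        """The (3, nx, ny, nz) velocity array of a single-frame field."""
        if self.n_frames != 1:
            raise ValueError("field is time-resolved; time-average it first")
        return self.u[0]

    @property
    def spacing_m(self) -> np.ndarray:
        return self.spacing * 1e-3

    @property
    def voxel_volume_m3(self) -> float:
        return float(np.prod(self.spacing_m))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert world coordinates (mm) to fractional voxel indices."""
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing


@dataclass
class SegmentationMask:
    """Integer region labels on the grid of a paired :class:`VelocityField`."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D integer array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise GeometryError("spacing must be strictly positive on all axes")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def lumen(self) -> np.ndarray:
        """Boolean array of all segmented voxels (labels != 0)."""
        return self.labels != BACKGROUND

    def region(self, labels) -> np.ndarray:
        """Boolean indicator for a label, a region name, or a set of either."""
        sel = _resolve_labels(labels)
        return np.isin(self.labels, sel)

    def region_voxel_count(self, labels) -> int:
        return int(self.region(labels).sum())

    def present_labels(self) -> set[int]:
        return set(np.unique(self.labels).tolist()) - {BACKGROUND}

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing


def _resolve_labels(labels) -> list[int]:
    """Normalize a label spec (int, name, or iterable of both) to label ints."""
    if labels is None:
        return sorted(REGION_NAMES)
    if isinstance(labels, (int, np.integer)):
        return [int(labels)]
    if isinstance(labels, str):
        return [REGION_LABELS[labels.lower()]]
    return [l if isinstance(l, (int, np.integer)) else REGION_LABELS[l.lower()]
            for l in labels]


def check_geometry(field: VelocityField, mask: SegmentationMask,
                   rtol: float = 1e-5) -> None:
    """Raise :class:`GeometryError` unless field and mask share a grid."""
    if field.dims != mask.dims:
        raise GeometryError(
            f"grid dims mismatch: field {field.dims} vs mask {mask.dims}")
    if not np.allclose(field.spacing, mask.spacing, rtol=rtol, atol=0):
        raise GeometryError(
            f"spacing mismatch: field {field.spacing} vs mask {mask.spacing}")
    if not np.allclose(field.origin, mask.origin, rtol=rtol, atol=1e-3):
        raise GeometryError(
            f"origin mismatch: field {field.origin} vs mask {mask.origin}")
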