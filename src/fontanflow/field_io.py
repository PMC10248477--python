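"""Reading, writing, time-averaging and resampling of velocity fields.

On-disk conventions
-------------------
Velocity volumes are NIfTI-1, either one 3D/4D file per component (the 4th
axis, when present, is time) or a single file whose last axis holds the three
components.  Segmentation masks are integer NIfTI-1 volumes on the same grid.
CFD point clouds are CSV with columns x,y,z (mm) and vx,vy,vz.  Per-case
results are written as a region-wise CSV plus a JSON document with the full
record (including the pulmonary-flow-distribution matrix).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import SegmentationMask, VelocityField, check_geometry
from .errors import FormatError, GeometryError, InputError

_UNIT_SCALE = {"m/s": 1.0, "cm/s": 0.01, "mm/s": 0.001}


def _grid_from_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3].copy()
    return spacing, origin


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _load_volume(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"velocity/mask file not found: {path}")
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    return np.asanyarray(img.dataobj), spacing, origin


def load_velocity_field(velocity_paths, mask_path, unit: str = "m/s"
                        ) -> tuple[VelocityField, SegmentationMask]:
    """Load a velocity field and its segmentation mask from NIfTI files.

    Parameters
    ----------
    velocity_paths:
        Either a single path (one volume with the velocity component as last
        axis: ``(nx,ny,nz,3)`` or ``(nx,ny,nz,nt,3)``) or a sequence of three
        paths, one per component, each 3D or 4D (4th axis = time).
    mask_path:
        Integer label volume on the same grid.
    unit:
        Unit of the on-disk velocity values ("m/s", "cm/s" or "mm/s");
        values are converted to m/s in memory.
    """
    if unit not in _UNIT_SCALE:
        raise FormatError(f"unknown velocity unit {unit!r}")
    scale = _UNIT_SCALE[unit]

    if isinstance(velocity_paths, (str, Path)):
        data, spacing, origin = _load_volume(velocity_paths)
        if data.ndim == 4 and data.shape[3] == 3:
            u = np.moveaxis(data, 3, 0)[None]           # (1, 3, nx, ny, nz)
        elif data.ndim == 5 and data.shape[4] == 3:
            u = np.moveaxis(data, (3, 4), (0, 1))       # (nt, 3, nx, ny, nz)
        else:
            raise FormatError(
                "single-file velocity volume must end in a 3-component axis; "
                f"got shape {data.shape}")
    else:
        paths = list(velocity_paths)
        if len(paths) != 3:
            raise FormatError(
                f"expected 3 component volumes, got {len(paths)}")
        comps, spacing, origin = [], None, None
        for p in paths:
            data, sp, og = _load_volume(p)
            if spacing is None:
                spacing, origin = sp, og
            elif not (np.allclose(sp, spacing) and np.allclose(og, origin)):
                raise GeometryError(f"component grids disagree at {p}")
            if data.ndim == 3:
                data = data[..., None]
            if data.ndim != 4:
                raise FormatError(f"component volume {p} must be 3D or 4D")
            comps.append(np.moveaxis(data, 3, 0))       # (nt, nx, ny, nz)
        shapes = {c.shape for c in comps}
        if len(shapes) != 1:
            raise GeometryError(f"component shapes disagree: {shapes}")
        u = np.stack(comps, axis=1)                     # (nt, 3, nx, ny, nz)

    field = VelocityField(u * scale, spacing=spacing, origin=origin)
    labels, msp, mog = _load_volume(mask_path)
    mask = SegmentationMask(np.rint(labels).astype(np.int16),
                            spacing=msp, origin=mog)
    check_geometry(field, mask)
    return field, mask


def save_velocity_field(field: VelocityField, mask: SegmentationMask,
                        out_dir, stem: str = "case") -> dict[str, Path]:
    """Write field + mask as NIfTI (one file per component, float32).

    Returns the mapping of output kind to path; the inverse of
    :func:`load_velocity_field` up to float32 precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(field.spacing, field.origin)
    paths: dict[str, Path] = {}
    for c, suffix in enumerate(("vx", "vy", "vz")):
        data = np.moveaxis(field.u[:, c], 0, 3).astype(np.float32)
        if data.shape[3] == 1:
            data = data[..., 0]
        p = out_dir / f"{stem}_{suffix}.nii.gz"
        nib.save(nib.Nifti1Image(data, aff), str(p))
        paths[suffix] = p
    mp = out_dir / f"{stem}_mask.nii.gz"
    mask_aff = _affine(mask.spacing, mask.origin)
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), mask_aff), str(mp))
    paths["mask"] = mp
    return paths


def time_average(field: VelocityField) -> VelocityField:
    """Per-voxel arithmetic mean over frames; idempotent and linear."""
    return VelocityField(field.u.mean(axis=0, keepdims=True),
                         spacing=field.spacing.copy(),
                         origin=field.origin.copy(),
                         allow_nan=field.allow_nan)


def load_point_cloud_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a CFD point cloud CSV with columns x,y,z (mm), vx,vy,vz (m/s)."""
    df = pd.read_csv(path)
    required = ["x", "y", "z", "vx", "vy", "vz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"point cloud CSV missing columns: {missing}")
    return df[["x", "y", "z"]].to_numpy(float), df[["vx", "vy", "vz"]].to_numpy(float)


def resample_point_cloud(points_mm: np.ndarray, velocities: np.ndarray,
                         spacing, origin, dims, radius_mm: float,
                         k: int = 16, power: float = 2.0
                         ) -> tuple[VelocityField, np.ndarray]:
    """Inverse-distance-weighted resampling of scattered velocities to a grid.

    For each voxel center, up to ``k`` nearest points within ``radius_mm``
    contribute with weight ``1/d**power``; a point coincident with the center
    is copied exactly.  Voxels with no point in radius are marked outside the
    covered domain (zero velocity) in the returned boolean coverage array.

    Returns ``(field, covered)`` where ``covered`` has shape ``dims``.
    """
    points_mm = np.asarray(points_mm, float)
    velocities = np.asarray(velocities, float)
    if points_mm.ndim != 2 or points_mm.shape[0] == 0:
        raise InputError("point cloud is empty")
    if points_mm.shape != velocities.shape:
        raise InputError("points and velocities must have matching shapes")
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    if np.any(spacing <= 0):
        raise GeometryError("target spacing must be strictly positive")
    dims = tuple(int(d) for d in dims)

    idx = np.indices(dims).reshape(3, -1).T
    centers = origin + idx * spacing
    tree = cKDTree(points_mm)
    kq = min(k, len(points_mm))
    dist, nbr = tree.query(centers, k=kq, distance_upper_bound=radius_mm)
    dist = np.atleast_2d(dist.T).T
    nbr = np.atleast_2d(nbr.T).T
    valid = np.isfinite(dist)
    covered = valid.any(axis=1)

    u = np.zeros((centers.shape[0], 3))
    exact = valid & (dist < 1e-9)
    has_exact = exact.any(axis=1)
    if has_exact.any():
        first = np.argmax(exact, axis=1)
        rows = np.where(has_exact)[0]
        u[rows] = velocities[nbr[rows, first[rows]]]
    rest = covered & ~has_exact
    if rest.any():
        w = np.where(valid, 1.0 / np.maximum(dist, 1e-12) ** power, 0.0)
        nbr_safe = np.where(valid, nbr, 0)
        vals = velocities[nbr_safe] * w[..., None]
        u[rest] = vals[rest].sum(axis=1) / w[rest].sum(axis=1, keepdims=True)

    field = VelocityField(np.moveaxis(u.reshape(dims + (3,)), 3, 0),
                          spacing=spacing, origin=origin)
    return field, covered.reshape(dims)


# ---------------------------------------------------------------------------
# per-case result reports
# ---------------------------------------------------------------------------

_REGION_COLUMNS = ["region", "vmax_m_s", "vmean_m_s", "ke_mJ", "vd_mW",
                   "q_L_min", "diameter_mm"]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_case_outputs(results: dict, out_dir) -> dict[str, Path]:
    """Write a per-case report: region-metric CSV + full JSON record.

    ``results`` is a mapping with keys ``case_id``, ``summary`` (a
    ``HemodynamicSummary`` or its dict form) and optionally ``pfd`` (a
    ``PFDResult`` or dict).  Column order and row order are deterministic so
    repeated runs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise FontanFlowIOError(str(exc)) from exc
    record = _to_jsonable(results)

    pfd = record.get("pfd")
    if pfd is not None and pfd.get("seeded_total", 0) == 0:
        pfd["missing_fraction_overall"] = 1.0

    rows = []
    summary = record.get("summary", {})
    for region in sorted(summary.get("regions", {})):
        r = summary["regions"][region]
        rows.append([region] + [r.get(c) for c in _REGION_COLUMNS[1:]])
    g = summary.get("global_") or summary.get("global") or {}
    if g:
        rows.append(["global", g.get("vmax_m_s"), g.get("vmean_m_s"),
                     g.get("ke_mJ"), g.get("vd_mW"), None, None])
    df = pd.DataFrame(rows, columns=_REGION_COLUMNS)

    case_id = record.get("case_id", "case")
    csv_path = out_dir / f"{case_id}_regions.csv"
    json_path = out_dir / f"{case_id}_results.json"
    df.to_csv(csv_path, index=False, float_format="%.10g", lineterminator="\n")
    with open(json_path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"csv": csv_path, "json": json_path}


def read_case_outputs(out_dir, case_id: str) -> dict:
    """Load the JSON record written by :func:`write_case_outputs`."""
    with open(Path(out_dir) / f"{case_id}_results.json") as fh:
        return json.load(fh)


class FontanFlowIOError(FormatError):
    """Unwritable output location."""
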