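"""NIfTI volume I/O and acquisition-geometry extraction.

Voxel sizes come from the header zooms.  The B0 direction is derived from
the direction-cosine matrix under the convention that B0 lies along the
scanner z-axis: o is the third row of the rotation part of the affine
(normalized per column by the zooms).  Both can be overridden explicitly;
every derived geometry is logged, never silently defaulted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from .dipole import AcquisitionGeometry, ContractError

logger = logging.getLogger("adaptqsm")


@dataclass
class VolumeRecord:
    """A loaded volume with its affine, derived geometry and provenance."""

    values: np.ndarray
    affine: np.ndarray
    geometry: AcquisitionGeometry
    path: Optional[str] = None
    checksum: Optional[str] = None
    description: str = ""


def geometry_from_affine(affine: np.ndarray) -> AcquisitionGeometry:
    """Voxel size and B0 direction from a NIfTI affine.

    Raises on singular affines.  B0 is the scanner z-axis expressed in image
    axes: the third row of the rotation matrix obtained by normalizing the
    affine's columns.
    """
    R = np.asarray(affine, dtype=float)[:3, :3]
    zooms = np.linalg.norm(R, axis=0)
    if np.any(zooms <= 0) or abs(np.linalg.det(R)) < 1e-12:
        raise ContractError("singular affine: cannot derive acquisition geometry")
    rot = R / zooms
    o = rot[2, :]
    return AcquisitionGeometry(tuple(zooms), tuple(o))


def affine_from_geometry(geometry: AcquisitionGeometry) -> np.ndarray:
    """Affine whose rotation part encodes the B0 direction.

    Completes the unit B0 vector to a right-handed orthonormal basis whose
    third row is o, so ``geometry_from_affine`` recovers both voxel size
    and orientation exactly.
    """
    o = np.asarray(geometry.b0_direction)
    e = np.array([1.0, 0.0, 0.0]) if abs(o[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    r1 = np.cross(e, o)
    r1 /= np.linalg.norm(r1)
    r2 = np.cross(o, r1)
    R = np.stack([r1, r2, o])
    affine = np.eye(4)
    affine[:3, :3] = R @ np.diag(geometry.voxel_size)
    return affine


def read_volume(
    path,
    voxel_size: Optional[Sequence[float]] = None,
    b0_direction: Optional[Sequence[float]] = None,
) -> VolumeRecord:
    """Load a 3D NIfTI volume and resolve its acquisition geometry.

    Explicit ``voxel_size`` / ``b0_direction`` override the header-derived
    values; whichever source is used is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj)
    if values.ndim != 3:
        raise ContractError(f"expected a 3D volume, got shape {values.shape}")
    header_geom = geometry_from_affine(img.affine)
    v = tuple(voxel_size) if voxel_size is not None else header_geom.voxel_size
    o = tuple(b0_direction) if b0_direction is not None else header_geom.b0_direction
    geometry = AcquisitionGeometry(v, o)
    src_v = "override" if voxel_size is not None else "header"
    src_o = "override" if b0_direction is not None else "header"
    logger.info(
        "loaded %s: voxel size %s (%s), B0 direction %s (%s)",
        path.name, np.round(geometry.voxel_size, 4), src_v,
        np.round(geometry.b0_direction, 4), src_o,
    )
    checksum = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    descrip = ""
    try:
        descrip = img.header["descrip"].item().decode(errors="replace")
    except Exception:
        pass
    return VolumeRecord(
        values=np.asarray(values, dtype=np.float64),
        affine=np.asarray(img.affine, dtype=float),
        geometry=geometry,
        path=str(path),
        checksum=checksum,
        description=descrip,
    )


def write_volume(
    values: np.ndarray,
    path,
    geometry: Optional[AcquisitionGeometry] = None,
    affine: Optional[np.ndarray] = None,
    description: str = "ppm",
) -> None:
    """Write a 3D volume as NIfTI; round trips preserve values and geometry.

    Without an explicit affine, a diagonal affine from the geometry's voxel
    size is used (axial convention).  The unit (ppm) goes in the header
    description field.
    """
    values = np.asarray(values)
    if values.ndim != 3:
        raise ContractError(f"expected a 3D volume, got shape {values.shape}")
    if affine is None:
        if geometry is not None:
            affine = affine_from_geometry(geometry)
        else:
            affine = np.eye(4)
    img = nib.Nifti1Image(values.astype(np.float64), np.asarray(affine, dtype=float))
    img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
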