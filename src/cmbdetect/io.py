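"""Volume and table I/O, grid and coordinate conventions.

All volumes are 3D scalar grids carried as :class:`VoxelVolume`: a data array,
per-axis voxel spacing in mm, and a 4x4 affine mapping 0-based voxel indices to
world coordinates in mm (the NIfTI convention).  Axis 2 is the through-plane
(slice) axis throughout the package.  World mm is authoritative wherever
physical distances matter (lesion matching, slab thickness, RST radii).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelVolume",
    "CandidateTable",
    "VolumeFormatError",
    "AffineError",
    "OutOfGridError",
    "read_volume",
    "write_volume",
    "read_mask",
    "voxel_to_world",
    "world_to_voxel",
    "write_candidates",
    "read_candidates",
    "read_ground_truth",
    "write_ground_truth",
]


class VolumeFormatError(ValueError):
    """The file on disk is not a 3D scalar volume."""


class AffineError(ValueError):
    """The grid-to-world affine is singular or inconsistent with the spacing."""


class OutOfGridError(IndexError):
    """A voxel index lies outside the volume grid."""


@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data : ndarray
        3D array of intensities (arbitrary units) or mask values.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    affine : ndarray, optional
        4x4 voxel-index -> world-mm transform.  Defaults to the diagonal
        affine built from ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"not a 3D volume: shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise AffineError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise AffineError("affine is not invertible")
        col_norms = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(col_norms, self.spacing, rtol=1e-6):
            raise AffineError(
                f"affine column norms {col_norms} inconsistent with spacing {self.spacing}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "VoxelVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing
        )


@dataclass
class PlanarPatch:
    """A 2D in-plane image patch with its in-plane spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise VolumeFormatError(f"not a 2D patch: shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


def read_volume(path: str | os.PathLike) -> VoxelVolume:
    """Read a NIfTI-1 file into a :class:`VoxelVolume`.

    Intensities are returned exactly as stored (no scaling beyond the NIfTI
    scl slope/intercept applied by nibabel's array proxy); spacing comes from
    the header.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"not a 3D volume: {path} has shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(volume: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a :class:`VoxelVolume` as NIfTI-1 (.nii or .nii.gz)."""
    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> VoxelVolume:
    """Read a brain mask; any nonzero voxel counts as inside."""
    vol = read_volume(path)
    return VoxelVolume(
        data=(np.asarray(vol.data) != 0), spacing=vol.spacing, affine=vol.affine
    )


def voxel_to_world(
    volume: VoxelVolume, index: tuple[int, int, int]
) -> tuple[float, float, float]:
    """Map a 0-based voxel index to world mm through the volume's affine."""
    idx = np.asarray(index, dtype=float)
    if idx.shape != (3,):
        raise ValueError(f"index must be a triple, got {index}")
    if np.any(idx < 0) or np.any(idx > np.asarray(volume.shape) - 1):
        raise OutOfGridError(f"index {index} outside grid {volume.shape}")
    out = volume.affine @ np.append(idx, 1.0)
    return (float(out[0]), float(out[1]), float(out[2]))


def world_to_voxel(
    volume: VoxelVolume, world: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Inverse of :func:`voxel_to_world`; returns fractional voxel coordinates."""
    inv = np.linalg.inv(volume.affine)
    out = inv @ np.append(np.asarray(world, dtype=float), 1.0)
    return (float(out[0]), float(out[1]), float(out[2]))


_CANDIDATE_COLUMNS = ["id", "i", "j", "k", "x_mm", "y_mm", "z_mm", "s3d", "s2d", "status"]


@dataclass
class CandidateTable:
    """Candidates plus the provenance needed to reproduce them."""

    candidates: list  # list[detect.Candidate]
    provenance: str = ""
    params_used: dict = field(default_factory=dict)


def write_candidates(table: CandidateTable, path: str | os.PathLike) -> None:
    """Write a candidate table as CSV.

    An absent 2D score (stage 2 skipped) is stored as an empty field and read
    back as absent.
    """
    rows = []
    for c in table.candidates:
        rows.append(
            {
                "id": c.id,
                "i": c.voxel_index[0],
                "j": c.voxel_index[1],
                "k": c.voxel_index[2],
                "x_mm": c.world_mm[0],
                "y_mm": c.world_mm[1],
                "z_mm": c.world_mm[2],
                "s3d": c.s3d,
                "s2d": "" if c.s2d is None else c.s2d,
                "status": c.status,
            }
        )
    df = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write candidate CSV to {path}: {exc}") from exc


def read_candidates(path: str | os.PathLike) -> CandidateTable:
    """Read back a candidate CSV written by :func:`write_candidates`."""
    from .detect import Candidate  # local import to avoid a cycle

    df = pd.read_csv(path, dtype={"id": str, "status": str})
    candidates = []
    for _, row in df.iterrows():
        s2d = row["s2d"]
        candidates.append(
            Candidate(
                id=str(row["id"]),
                voxel_index=(int(row["i"]), int(row["j"]), int(row["k"])),
                world_mm=(float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
                s3d=float(row["s3d"]),
                s2d=None if pd.isna(s2d) else float(s2d),
                status=str(row["status"]),
            )
        )
    return CandidateTable(candidates=candidates, provenance=str(path))


def read_ground_truth(path: str | os.PathLike):
    """Read a ground-truth lesion CSV with columns (id, x_mm, y_mm, z_mm, label)."""
    from .evaluate import GroundTruthEntry

    df = pd.read_csv(path, dtype={"id": str, "label": str})
    entries = []
    for _, row in df.iterrows():
        entries.append(
            GroundTruthEntry(
                id=str(row["id"]),
                world_mm=(float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
                label=str(row["label"]),
            )
        )
    return entries


def write_ground_truth(entries, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "id": e.id,
                "x_mm": e.world_mm[0],
                "y_mm": e.world_mm[1],
                "z_mm": e.world_mm[2],
                "label": e.label,
            }
            for e in entries
        ],
        columns=["id", "x_mm", "y_mm", "z_mm", "label"],
    )
    df.to_csv(path, index=False)
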