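"""Stage 1: threshold the 3D symmetry map and reduce to candidate locations.

Voxels inside the brain mask whose radial symmetry value exceeds the stage-1
threshold are potential microbleed locations.  The suprathreshold set is
reduced to its local maxima (the standard blob-detector reduction): a voxel
is a candidate when no neighbour in its connectivity neighbourhood has a
higher value, with plateau ties resolved to the lexicographically smallest
voxel.  Because the local-max set of a fixed map does not depend on the
threshold, raising the threshold can only remove candidates -- candidate
counts and sensitivity are monotone in the threshold by construction, and
threshold sweeps can be evaluated exactly from cached candidate scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import VoxelVolume, voxel_to_world
from .rst import SymmetryMap

__all__ = [
    "Candidate",
    "DetectionParams",
    "GridMismatchError",
    "find_candidates",
]

STATUS_PENDING = "pending"
STATUS_PASSED = "passed_2d"
STATUS_REJECTED = "rejected_2d"


class GridMismatchError(ValueError):
    """Map and mask are not on the same grid."""


@dataclass
class Candidate:
    """One detected potential-microbleed location."""

    id: str
    voxel_index: tuple[int, int, int]
    world_mm: tuple[float, float, float]
    s3d: float
    s2d: float | None = None
    status: str = STATUS_PENDING


@dataclass(frozen=True)
class DetectionParams:
    """Stage thresholds and the local-maximum neighbourhood.

    ``t2d == 0`` disables the 2D rescoring stage entirely.  ``connectivity``
    (6, 18 or 26) defines which voxels count as neighbours when deciding
    whether a voxel is a local maximum; 26 is conservative on anisotropic
    grids, merging near-coincident peaks across thick slices.
    """

    t3d: float = 1.0
    t2d: float = 0.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.t3d <= 0:
            raise ValueError("t3d must be > 0")
        if self.t2d < 0:
            raise ValueError("t2d must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def find_candidates(
    symmetry_map: SymmetryMap,
    mask: VoxelVolume,
    params: DetectionParams,
    volume: VoxelVolume | None = None,
) -> list[Candidate]:
    """Candidates = in-mask local maxima of the map with value above ``t3d``.

    Equal-valued plateaus yield a single candidate at the plateau's
    lexicographically smallest voxel.  Candidates are returned sorted by
    descending symmetry value (ties by ascending index).  World coordinates
    use the affine of ``volume`` when given, else the mask's.
    """
    values = symmetry_map.values
    if values.shape != mask.data.shape:
        raise GridMismatchError(
            f"map grid {values.shape} != mask grid {mask.data.shape}"
        )
    geometry = volume if volume is not None else mask
    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_RANK[params.connectivity]
    )
    neighbourhood_max = ndimage.maximum_filter(
        values, footprint=structure, mode="nearest"
    )
    is_peak = (values >= neighbourhood_max) & (values > params.t3d)
    is_peak &= np.asarray(mask.data) != 0
    if not is_peak.any():
        return []

    # adjacent peak voxels are equal-valued plateaus: keep one per plateau
    plateau_labels, n_plateaus = ndimage.label(is_peak, structure=structure)
    reps = ndimage.maximum_position(
        values, labels=plateau_labels, index=range(1, n_plateaus + 1)
    )

    candidates = []
    for rep in reps:
        index = tuple(int(v) for v in rep)
        candidates.append(
            Candidate(
                id="",
                voxel_index=index,
                world_mm=voxel_to_world(geometry, index),
                s3d=float(values[index]),
                status=STATUS_PENDING,
            )
        )
    candidates.sort(key=lambda c: (-c.s3d, c.voxel_index))
    for rank, cand in enumerate(candidates):
        cand.id = f"c{rank:04d}"
    return candidates
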