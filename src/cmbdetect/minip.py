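"""Stage 2: minimum-intensity-projection rescoring of stage-1 candidates.

A human rater distinguishes microbleeds from vessels on a minimum intensity
projection (minIP): projected across a 12-mm slab, a dark sphere stays a
compact round spot while a vessel running through the slab smears into an
elongated streak.  This stage automates that check.  For each candidate a
12-mm transversal minIP patch is built around the candidate, the 2D radial
symmetry transform is computed on it with the same settings as the 3D stage,
and candidates whose 2D symmetry value does not exceed the stage-2 threshold
are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .detect import STATUS_PASSED, STATUS_REJECTED, Candidate
from .io import OutOfGridError, PlanarPatch, VoxelVolume
from .rst import RSTParams, rst, rst_value_at

__all__ = ["MinIPSpec", "extract_minip_patch", "score_candidate_2d", "filter_candidates"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MinIPSpec:
    """Geometry of the minIP rescoring patch.

    slab_thickness_mm : total slab height; axial slices whose centres lie
        within half this distance of the candidate's slice are projected.
    roi_halfwidth_mm : in-plane half-width of the square region of interest,
        wide enough to hold the largest voting radius plus smoothing support.
    halo_voxels : half-width of the neighbourhood from which the candidate's
        2D score is read (stage-1 and minIP peaks can shift by a voxel).
    """

    slab_thickness_mm: float = 12.0
    roi_halfwidth_mm: float = 12.0
    halo_voxels: int = 1

    def __post_init__(self) -> None:
        if self.slab_thickness_mm <= 0:
            raise ValueError("slab_thickness_mm must be > 0")
        if self.roi_halfwidth_mm <= 0:
            raise ValueError("roi_halfwidth_mm must be > 0")
        if self.halo_voxels < 0:
            raise ValueError("halo_voxels must be >= 0")


def extract_minip_patch(
    volume: VoxelVolume, candidate: Candidate, spec: MinIPSpec = MinIPSpec()
) -> tuple[PlanarPatch, tuple[int, int]]:
    """Build the candidate's transversal minIP patch.

    Returns the 2D patch (inheriting the in-plane spacing) together with the
    candidate's position inside it.  Slices are selected by the physical
    distance of their centres from the candidate's slice (at most half the
    slab thickness); the window is clipped at volume boundaries, always
    keeping at least the candidate's own slice.
    """
    i0, j0, k0 = candidate.voxel_index
    shape = volume.shape
    if not all(0 <= v < s for v, s in zip((i0, j0, k0), shape)):
        raise OutOfGridError(
            f"candidate index {candidate.voxel_index} outside grid {shape}"
        )
    sx, sy, sz = volume.spacing
    half_slices = int(np.floor((spec.slab_thickness_mm / 2.0) / sz))
    k_lo = max(0, k0 - half_slices)
    k_hi = min(shape[2], k0 + half_slices + 1)

    hw_i = int(round(spec.roi_halfwidth_mm / sx))
    hw_j = int(round(spec.roi_halfwidth_mm / sy))
    i_lo, i_hi = max(0, i0 - hw_i), min(shape[0], i0 + hw_i + 1)
    j_lo, j_hi = max(0, j0 - hw_j), min(shape[1], j0 + hw_j + 1)

    block = np.asarray(volume.data, dtype=float)[i_lo:i_hi, j_lo:j_hi, k_lo:k_hi]
    patch = PlanarPatch(data=block.min(axis=2), spacing=(sx, sy))
    return patch, (i0 - i_lo, j0 - j_lo)


def score_candidate_2d(
    volume: VoxelVolume,
    candidate: Candidate,
    rst_params: RSTParams,
    spec: MinIPSpec = MinIPSpec(),
) -> float:
    """2D radial symmetry value of the candidate on its minIP patch."""
    patch, center = extract_minip_patch(volume, candidate, spec)
    symmetry = rst(patch, rst_params)
    return rst_value_at(symmetry, center, spec.halo_voxels)


def filter_candidates(
    volume: VoxelVolume,
    candidates: list[Candidate],
    rst_params: RSTParams,
    spec: MinIPSpec = MinIPSpec(),
    t2d: float = 0.0,
) -> list[Candidate]:
    """Rescore candidates on minIP patches; mark each passed or rejected.

    With ``t2d == 0`` the 2D stage is not computed at all: every candidate
    passes unmodified (2D score left unset).  Otherwise a candidate passes
    iff its 2D symmetry value strictly exceeds ``t2d``.  Per-candidate
    failures are logged and recorded as rejections; the batch never aborts.
    Returns new candidate objects; callers filter on status.
    """
    out = []
    for cand in candidates:
        if t2d == 0:
            out.append(replace(cand, status=STATUS_PASSED))
            continue
        try:
            s2d = score_candidate_2d(volume, cand, rst_params, spec)
        except Exception:  # pragma: no cover - defensive per-candidate guard
            logger.exception("2D rescoring failed for candidate %s; rejecting", cand.id)
            out.append(replace(cand, status=STATUS_REJECTED))
            continue
        status = STATUS_PASSED if s2d > t2d else STATUS_REJECTED
        out.append(replace(cand, s2d=s2d, status=status))
    return out
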