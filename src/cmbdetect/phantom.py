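"""Synthetic T2*-like phantoms with exact ground truth.

The generator emulates the structures that drive the detection problem on
susceptibility-weighted brain MRI: hypointense spheres (microbleed
analogues), hypointense curvilinear tubes (vessel analogues, the dominant
false-positive source), hypointense planes (fissure mimics), a smoothly
textured background (standing in for anatomical intensity variation), and
additive Gaussian acquisition noise -- on an anisotropic grid with slices
thicker than the in-plane spacing, as in multi-slice T2* protocols.

Lesions darken the background *multiplicatively* with a smooth error-function
edge profile about one voxel wide, mimicking the blooming / partial-volume
edges of real susceptibility hypointensities; hard-edged lesions would make
gradient-voting detection unrealistically easy.  Overlapping lesions compose
by taking the darkest factor.

Everything is a pure function of the spec and seed, so cohorts regenerate
bit-identically and tests need no stored image data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .evaluate import GroundTruthEntry
from .io import VoxelVolume

__all__ = [
    "SphereSpec",
    "TubeSpec",
    "PlaneSpec",
    "PhantomSpec",
    "PhantomOutput",
    "LesionOutsideGridError",
    "generate",
    "standard_cohort",
]

DEFINITE_DIAMETER_MM = 3.0  # spheres at least this wide are labelled definite


class LesionOutsideGridError(ValueError):
    """A lesion centre or control point lies outside the phantom grid."""


@dataclass(frozen=True)
class SphereSpec:
    center_mm: tuple[float, float, float]
    diameter_mm: float
    depth: float  # fractional intensity drop at the centre, in (0, 1]


@dataclass(frozen=True)
class TubeSpec:
    polyline_mm: tuple[tuple[float, float, float], ...]
    radius_mm: float
    depth: float


@dataclass(frozen=True)
class PlaneSpec:
    origin_mm: tuple[float, float, float]
    normal: tuple[float, float, float]
    thickness_mm: float
    depth: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom participant.

    The background has three compartments, mirroring the intensity structure
    the percentile normalization relies on in real T2*-weighted brain images:
    a bright parenchyma bulk with mild smooth anatomical variation
    (``texture_amplitude`` sd, ``texture_scale_mm`` correlation length), a
    dark-structure compartment occupying roughly the bottom decile of the
    histogram (CSF spaces, sulci and basal dark tissue -- the reason the 6th
    percentile falls well below normal parenchyma), and additive Gaussian
    acquisition noise.
    """

    extents: tuple[int, int, int] = (96, 96, 40)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    background_mean: float = 200.0
    noise_sigma: float = 8.0
    texture_amplitude: float = 12.0  # sd of the smooth anatomy variation
    texture_scale_mm: float = 20.0
    dark_structure_scale_mm: float = 8.0  # correlation length of CSF-like structures
    dark_structure_onset_sd: float = 1.0  # field level (in sd) where darkening starts
    dark_structure_depth: float = 0.6  # maximum fractional intensity drop
    spheres: tuple[SphereSpec, ...] = ()
    tubes: tuple[TubeSpec, ...] = ()
    planes: tuple[PlaneSpec, ...] = ()
    mask_margin_mm: float = 3.0
    seed: int = 0


@dataclass
class PhantomOutput:
    volume: VoxelVolume
    mask: VoxelVolume
    truth: list[GroundTruthEntry] = field(default_factory=list)
    spec: "PhantomSpec | None" = None


def _world_grids(spec: PhantomSpec):
    axes = [
        np.arange(spec.extents[a]) * spec.spacing_mm[a] for a in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _field_max_mm(spec: PhantomSpec) -> tuple[float, float, float]:
    return tuple(
        (spec.extents[a] - 1) * spec.spacing_mm[a] for a in range(3)
    )


def _check_inside(point, spec: PhantomSpec, what: str) -> None:
    hi = _field_max_mm(spec)
    for a in range(3):
        if not (0.0 <= point[a] <= hi[a]):
            raise LesionOutsideGridError(
                f"{what} at {tuple(point)} mm outside grid extent {hi} mm"
            )


def _edge_profile(distance_mm: np.ndarray, boundary_mm: float, width_mm: float):
    """Smooth indicator: ~1 inside the boundary, ~0 outside, erf transition."""
    return 0.5 * (1.0 - erf((distance_mm - boundary_mm) / width_mm))


def _smooth_unit_field(rng, extents, spacing, scale_mm):
    """Seeded smooth random field, normalized to unit variance."""
    f = gaussian_filter(
        rng.standard_normal(extents), sigma=[scale_mm / s for s in spacing]
    )
    sd = f.std()
    return f / sd if sd > 0 else f


def _field_rngs(seed: int):
    """Independent, reproducible streams for anatomy, dark structures, noise."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def dark_structure_field(spec: PhantomSpec) -> np.ndarray:
    """The unit-variance field whose negative tail becomes CSF-like darkness.

    Exposed so cohort generation can place lesions in parenchyma (where the
    field is not in its dark tail) before rendering; uses the same seeded
    stream as :func:`generate`.
    """
    _, rng_dark, _ = _field_rngs(spec.seed)
    return _smooth_unit_field(rng_dark, spec.extents, spec.spacing_mm, spec.dark_structure_scale_mm)


def _segment_distance(px, py, pz, a, b):
    """Distance from every grid point to the segment a-b (all in mm)."""
    ab = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    denom = float(ab @ ab)
    dx, dy, dz = px - a[0], py - a[1], pz - a[2]
    if denom == 0.0:
        return np.sqrt(dx * dx + dy * dy + dz * dz)
    t = np.clip((dx * ab[0] + dy * ab[1] + dz * ab[2]) / denom, 0.0, 1.0)
    cx, cy, cz = dx - t * ab[0], dy - t * ab[1], dz - t * ab[2]
    return np.sqrt(cx * cx + cy * cy + cz * cz)


def generate(spec: PhantomSpec) -> PhantomOutput:
    """Render a phantom: textured noisy background with dark lesions.

    Deterministic given ``spec`` (including its seed).  The truth list holds
    one entry per sphere -- tubes and planes are decoys and never appear in
    it -- labelled ``definite`` when the diameter reaches 3 mm, ``possible``
    below that, mirroring the rating convention that confidence drops with
    lesion size.
    """
    rng_anat, rng_dark, rng_noise = _field_rngs(spec.seed)
    px, py, pz = _world_grids(spec)
    edge_w = float(min(spec.spacing_mm))  # ~1 voxel transition width

    # multiplicative darkening factor; lesions compose by minimum
    factor = np.ones(spec.extents, dtype=float)

    for sphere in spec.spheres:
        _check_inside(sphere.center_mm, spec, "sphere centre")
        if not (0.0 < sphere.depth <= 1.0) or sphere.diameter_mm <= 0:
            raise ValueError(f"invalid sphere {sphere}")
        c = sphere.center_mm
        r = np.sqrt((px - c[0]) ** 2 + (py - c[1]) ** 2 + (pz - c[2]) ** 2)
        prof = _edge_profile(r, sphere.diameter_mm / 2.0, edge_w)
        factor = np.minimum(factor, 1.0 - sphere.depth * prof)

    for tube in spec.tubes:
        if len(tube.polyline_mm) < 2 or tube.radius_mm <= 0:
            raise ValueError(f"invalid tube {tube}")
        for p in tube.polyline_mm:
            _check_inside(p, spec, "tube control point")
        dist = np.full(spec.extents, np.inf)
        for a, b in zip(tube.polyline_mm, tube.polyline_mm[1:]):
            dist = np.minimum(dist, _segment_distance(px, py, pz, a, b))
        prof = _edge_profile(dist, tube.radius_mm, edge_w)
        factor = np.minimum(factor, 1.0 - tube.depth * prof)

    for plane in spec.planes:
        _check_inside(plane.origin_mm, spec, "plane origin")
        n = np.asarray(plane.normal, dtype=float)
        n = n / np.linalg.norm(n)
        d = np.abs(
            (px - plane.origin_mm[0]) * n[0]
            + (py - plane.origin_mm[1]) * n[1]
            + (pz - plane.origin_mm[2]) * n[2]
        )
        prof = _edge_profile(d, plane.thickness_mm / 2.0, edge_w)
        factor = np.minimum(factor, 1.0 - plane.depth * prof)

    anatomy = spec.texture_amplitude * _smooth_unit_field(
        rng_anat, spec.extents, spec.spacing_mm, spec.texture_scale_mm
    )
    dark = _smooth_unit_field(
        rng_dark, spec.extents, spec.spacing_mm, spec.dark_structure_scale_mm
    )
    # negative tail of the dark field ramps into CSF-like hypointensity,
    # putting roughly the bottom decile of the histogram well below tissue
    darkness = spec.dark_structure_depth * np.clip(
        -dark - spec.dark_structure_onset_sd, 0.0, 1.0
    )
    background = (spec.background_mean + anatomy) * (1.0 - darkness)
    volume_data = background * factor + rng_noise.normal(
        0.0, spec.noise_sigma, size=spec.extents
    )

    mask_data = np.ones(spec.extents, dtype=bool)
    margin_vox = [
        int(math.ceil(spec.mask_margin_mm / s)) for s in spec.spacing_mm
    ]
    for a, m in enumerate(margin_vox):
        if m > 0:
            sl = [slice(None)] * 3
            sl[a] = slice(0, m)
            mask_data[tuple(sl)] = False
            sl[a] = slice(spec.extents[a] - m, spec.extents[a])
            mask_data[tuple(sl)] = False

    affine = np.diag(list(spec.spacing_mm) + [1.0])
    volume = VoxelVolume(volume_data, spec.spacing_mm, affine)
    mask = VoxelVolume(mask_data, spec.spacing_mm, affine)

    truth = [
        GroundTruthEntry(
            id=f"sphere{i:03d}",
            world_mm=s.center_mm,
            label="definite" if s.diameter_mm >= DEFINITE_DIAMETER_MM else "possible",
        )
        for i, s in enumerate(spec.spheres)
    ]
    return PhantomOutput(volume=volume, mask=mask, truth=truth, spec=spec)


def _random_point(rng, lo, hi):
    return tuple(float(rng.uniform(lo[a], hi[a])) for a in range(3))


def _wiggly_tube(rng, lo, hi, keepout_xy, keepout_mm):
    """A tilted, wiggly, mostly through-plane polyline avoiding sphere columns.

    Tubes drift in-plane as they traverse slices (vessels are rarely exactly
    perpendicular to the slab), so a 12-mm minIP smears them into streaks.
    """
    drift_angle = rng.uniform(0, 2 * np.pi)
    drift_total = rng.uniform(30.0, 60.0)  # in-plane travel over the z extent, mm
    z_extent = hi[2] - lo[2]
    for _ in range(100):
        x = rng.uniform(lo[0], hi[0])
        y = rng.uniform(lo[1], hi[1])
        n_knots = 6
        zs = np.linspace(lo[2], hi[2], n_knots)
        pts = []
        for z in zs:
            frac = (z - lo[2]) / z_extent
            pts.append(
                (
                    float(np.clip(x + frac * drift_total * np.cos(drift_angle)
                                  + rng.normal(0, 1.0), lo[0], hi[0])),
                    float(np.clip(y + frac * drift_total * np.sin(drift_angle)
                                  + rng.normal(0, 1.0), lo[1], hi[1])),
                    float(z),
                )
            )
        ok = all(
            (p[0] - cx) ** 2 + (p[1] - cy) ** 2 >= keepout_mm**2
            for p in pts
            for cx, cy in keepout_xy
        )
        if ok:
            break
    return tuple(pts)


def standard_cohort(n_participants: int, seed: int) -> list[PhantomOutput]:
    """Reproducible cohort of phantoms mirroring a memory-clinic population.

    About 53% of participants carry at least one microbleed analogue; those
    that do get a right-skewed count (1 plus a geometric tail), with sphere
    diameters uniform on [2, 10] mm and intensity depths uniform on
    [0.5, 0.9].  Every participant gets 3-8 vessel-like tubes and 1-2
    fissure-like planes as decoys.  All placement is seeded.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    base = PhantomSpec()
    hi_all = _field_max_mm(base)
    lo = tuple(base.mask_margin_mm + 6.0 for _ in range(3))
    hi = tuple(hi_all[a] - base.mask_margin_mm - 6.0 for a in range(3))

    cohort = []
    for part in range(n_participants):
        participant_seed = int(rng.integers(0, 2**31 - 1))
        field_spec = PhantomSpec(seed=participant_seed)
        dark = dark_structure_field(field_spec)
        rng_anat, _, _ = _field_rngs(participant_seed)
        anatomy = _smooth_unit_field(
            rng_anat, base.extents, base.spacing_mm, base.texture_scale_mm
        )

        def in_parenchyma(c):
            idx = tuple(
                int(round(c[a] / base.spacing_mm[a])) for a in range(3)
            )
            return dark[idx] > -0.5 and anatomy[idx] > -1.0

        has_spheres = rng.uniform() < 0.53
        spheres = []
        centers_xy = []
        if has_spheres:
            count = 1 + rng.geometric(0.5) - 1  # 1 + geometric tail starting at 0
            for _ in range(count):
                for _ in range(200):
                    c = _random_point(rng, lo, hi)
                    if in_parenchyma(c) and all(
                        (c[0] - e[0]) ** 2 + (c[1] - e[1]) ** 2 + (c[2] - e[2]) ** 2
                        >= 14.0**2
                        for e in (s.center_mm for s in spheres)
                    ):
                        break
                spheres.append(
                    SphereSpec(
                        center_mm=c,
                        diameter_mm=float(rng.uniform(2.0, 10.0)),
                        depth=float(rng.uniform(0.5, 0.9)),
                    )
                )
                centers_xy.append((c[0], c[1]))

        tubes = []
        for _ in range(int(rng.integers(3, 9))):
            poly = _wiggly_tube(rng, lo, hi, centers_xy, keepout_mm=10.0)
            tubes.append(
                TubeSpec(
                    polyline_mm=poly,
                    radius_mm=float(rng.uniform(0.6, 1.6)),
                    depth=float(rng.uniform(0.5, 0.9)),
                )
            )

        planes = []
        for _ in range(int(rng.integers(1, 3))):
            for _ in range(50):
                ox = rng.uniform(lo[0], hi[0])
                if all(abs(ox - cx) >= 10.0 for cx, _ in centers_xy):
                    break
            theta = rng.uniform(-0.3, 0.3)
            planes.append(
                PlaneSpec(
                    origin_mm=(float(ox), float((lo[1] + hi[1]) / 2), float((lo[2] + hi[2]) / 2)),
                    normal=(float(np.cos(theta)), float(np.sin(theta)), 0.0),
                    thickness_mm=float(rng.uniform(1.0, 2.5)),
                    depth=float(rng.uniform(0.4, 0.8)),
                )
            )

        spec = PhantomSpec(
            spheres=tuple(spheres),
            tubes=tuple(tubes),
            planes=tuple(planes),
            seed=participant_seed,
        )
        cohort.append(generate(spec))
    return cohort
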