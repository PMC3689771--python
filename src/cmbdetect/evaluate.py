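"""Evaluation: ground-truth matching, FROC analysis, tiered screening.

Detection performance is summarised the free-response ROC way: each
operating point (a stage-1/stage-2 threshold pair) yields a cohort
sensitivity and a mean number of candidate marks per participant that a
human rater would have to censor.  Because both pipeline stages are pure
threshold operations on per-voxel and per-candidate symmetry values, the
exhaustive threshold grid is evaluated from cached scores: the 3D transform
runs once per participant and every 2D rescoring is memoized by voxel
location, which is exactly equivalent to recomputing the pipeline at each
grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detect import (
    STATUS_PASSED,
    Candidate,
    DetectionParams,
    find_candidates,
)
from .io import VoxelVolume
from .minip import MinIPSpec, score_candidate_2d
from .normalize import NormalizationSpec, range_normalize
from .rst import RSTParams, rst

__all__ = [
    "GroundTruthEntry",
    "MatchResult",
    "FROCPoint",
    "ParticipantPipeline",
    "match",
    "froc_grid",
    "pareto_frontier",
    "tiered_screen",
    "froc_to_dataframe",
    "plot_froc",
    "DEFAULT_T3D_VALUES",
    "DEFAULT_T2D_VALUES",
]

# the printed exhaustive search lattice: 6 x 7 = 42 operating points
DEFAULT_T3D_VALUES = tuple(np.arange(0.5, 3.0 + 1e-9, 0.5))
DEFAULT_T2D_VALUES = tuple(np.arange(0.0, 3.0 + 1e-9, 0.5))

DEFAULT_MATCH_TOL_MM = 5.0


@dataclass(frozen=True)
class GroundTruthEntry:
    """A reference lesion with a rating-confidence label."""

    id: str
    world_mm: tuple[float, float, float]
    label: str  # 'definite' or 'possible'

    def __post_init__(self) -> None:
        if self.label not in ("definite", "possible"):
            raise ValueError(f"label must be definite|possible, got {self.label!r}")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else 0.0


@dataclass(frozen=True)
class FROCPoint:
    """One operating point of the two-threshold lattice."""

    t3d: float
    t2d: float
    sensitivity: float
    mean_candidates_per_participant: float
    tp: int
    fp: int
    fn: int


def match(
    candidates: list[Candidate],
    truth: list[GroundTruthEntry],
    tol_mm: float = DEFAULT_MATCH_TOL_MM,
    scope: str = "all",
) -> MatchResult:
    """One-to-one greedy matching of candidates to reference lesions.

    Admissible pairs are those within ``tol_mm`` Euclidean world distance;
    pairs are claimed in ascending distance order, each candidate and each
    lesion at most once.  Unmatched candidates count as false positives,
    unmatched lesions as false negatives.  ``scope='definite_only'``
    restricts the reference list to definite lesions.
    """
    if tol_mm <= 0:
        raise ValueError("tol_mm must be > 0")
    if scope not in ("all", "definite_only"):
        raise ValueError(f"unknown scope {scope!r}")
    truth_used = [t for t in truth if scope == "all" or t.label == "definite"]

    admissible = []
    for ci, cand in enumerate(candidates):
        for ti, ref in enumerate(truth_used):
            d = float(
                np.linalg.norm(np.asarray(cand.world_mm) - np.asarray(ref.world_mm))
            )
            if d <= tol_mm:
                admissible.append((d, ci, ti))
    # deterministic tie-break on indices after distance
    admissible.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, ci, ti in admissible:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        pairs.append((candidates[ci].id, truth_used[ti].id))
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(candidates) - tp, fn=len(truth_used) - tp, pairs=pairs
    )


class ParticipantPipeline:
    """Cached per-participant pipeline state for grid evaluation.

    Normalizes once, runs the 3D transform once, and memoizes stage-1
    clustering per threshold and stage-2 scores per peak voxel.  Because
    thresholding cached values is exactly what a fresh pipeline run does,
    grid points evaluated here coincide with direct recomputation.
    """

    def __init__(
        self,
        volume: VoxelVolume,
        mask: VoxelVolume,
        truth: list[GroundTruthEntry],
        rst_params: RSTParams = RSTParams(),
        norm_spec: NormalizationSpec = NormalizationSpec(),
        minip_spec: MinIPSpec = MinIPSpec(),
        connectivity: int = 26,
    ) -> None:
        self.mask = mask
        self.truth = truth
        self.rst_params = rst_params
        self.minip_spec = minip_spec
        self.connectivity = connectivity
        self.normalized = range_normalize(volume, mask, norm_spec)
        self.symmetry = rst(self.normalized, rst_params)
        self._stage1: dict[float, list[Candidate]] = {}
        self._s2d: dict[tuple[int, int, int], float] = {}

    def stage1_candidates(self, t3d: float) -> list[Candidate]:
        key = round(float(t3d), 9)
        if key not in self._stage1:
            params = DetectionParams(t3d=float(t3d), t2d=0.0, connectivity=self.connectivity)
            self._stage1[key] = find_candidates(
                self.symmetry, self.mask, params, volume=self.normalized
            )
        return self._stage1[key]

    def s2d_at(self, voxel_index: tuple[int, int, int]) -> float:
        if voxel_index not in self._s2d:
            probe = Candidate(
                id="probe", voxel_index=voxel_index, world_mm=(0.0, 0.0, 0.0), s3d=0.0
            )
            self._s2d[voxel_index] = score_candidate_2d(
                self.normalized, probe, self.rst_params, self.minip_spec
            )
        return self._s2d[voxel_index]

    def passed_candidates(self, t3d: float, t2d: float) -> list[Candidate]:
        """Candidates surviving both stages at the given thresholds."""
        out = []
        for cand in self.stage1_candidates(t3d):
            if t2d == 0:
                out.append(replace(cand, status=STATUS_PASSED))
                continue
            s2d = self.s2d_at(cand.voxel_index)
            if s2d > t2d:
                out.append(replace(cand, s2d=s2d, status=STATUS_PASSED))
        return out


def _as_pipelines(cohort, rst_params, norm_spec, minip_spec, connectivity):
    pipelines = []
    for entry in cohort:
        if isinstance(entry, ParticipantPipeline):
            pipelines.append(entry)
            continue
        volume, mask, truth = entry
        pipelines.append(
            ParticipantPipeline(
                volume, mask, truth, rst_params, norm_spec, minip_spec, connectivity
            )
        )
    return pipelines


def froc_grid(
    cohort,
    rst_params: RSTParams = RSTParams(),
    t3d_values=DEFAULT_T3D_VALUES,
    t2d_values=DEFAULT_T2D_VALUES,
    tol_mm: float = DEFAULT_MATCH_TOL_MM,
    scope: str = "all",
    norm_spec: NormalizationSpec = NormalizationSpec(),
    minip_spec: MinIPSpec = MinIPSpec(),
    connectivity: int = 26,
) -> list[FROCPoint]:
    """Evaluate every threshold combination on the cohort.

    ``cohort`` is a list of ``(volume, mask, truth)`` triples or prebuilt
    :class:`ParticipantPipeline` objects.  Returns
    ``len(t3d_values) * len(t2d_values)`` points, cohort-pooled.
    """
    if not cohort or not len(t3d_values) or not len(t2d_values):
        raise ValueError("cohort and threshold lists must be nonempty")
    pipelines = _as_pipelines(cohort, rst_params, norm_spec, minip_spec, connectivity)
    points = []
    for t3d in t3d_values:
        for t2d in t2d_values:
            tp = fp = fn = n_cand = 0
            for p in pipelines:
                passed = p.passed_candidates(float(t3d), float(t2d))
                result = match(passed, p.truth, tol_mm=tol_mm, scope=scope)
                tp += result.tp
                fp += result.fp
                fn += result.fn
                n_cand += len(passed)
            total = tp + fn
            points.append(
                FROCPoint(
                    t3d=float(t3d),
                    t2d=float(t2d),
                    sensitivity=tp / total if total else 0.0,
                    mean_candidates_per_participant=n_cand / len(pipelines),
                    tp=tp,
                    fp=fp,
                    fn=fn,
                )
            )
    return points


def pareto_frontier(points: list[FROCPoint]) -> list[FROCPoint]:
    """Operating points not dominated in (sensitivity up, candidate burden down).

    A point is dominated when another has at least its sensitivity and at
    most its candidate burden, strictly better in one.  Exact ties on both
    axes keep the point with the lexicographically larger (t3d, t2d).
    Returned sorted by ascending candidate burden.
    """
    if not points:
        raise ValueError("need at least one point")
    kept = []
    for p in points:
        dominated = False
        for q in points:
            if q is p:
                continue
            better_eq = (
                q.sensitivity >= p.sensitivity
                and q.mean_candidates_per_participant
                <= p.mean_candidates_per_participant
            )
            strict = (
                q.sensitivity > p.sensitivity
                or q.mean_candidates_per_participant
                < p.mean_candidates_per_participant
            )
            if better_eq and strict:
                dominated = True
                break
            if (
                q.sensitivity == p.sensitivity
                and q.mean_candidates_per_participant
                == p.mean_candidates_per_participant
                and (q.t3d, q.t2d) > (p.t3d, p.t2d)
            ):
                dominated = True
                break
        if not dominated:
            kept.append(p)
    kept.sort(key=lambda p: (p.mean_candidates_per_participant, -p.sensitivity))
    return kept


def tiered_screen(
    cohort,
    rst_params: RSTParams = RSTParams(),
    setting_a: tuple[float, float] = (2.0, 2.0),
    setting_c: tuple[float, float] = (0.5, 0.5),
    tol_mm: float = DEFAULT_MATCH_TOL_MM,
    scope: str = "all",
    norm_spec: NormalizationSpec = NormalizationSpec(),
    minip_spec: MinIPSpec = MinIPSpec(),
    connectivity: int = 26,
):
    """Two-tier screening: triage at a strict setting, rescan positives permissively.

    Every participant is screened at setting A; only participants with at
    least one stage-A candidate are re-run at the more sensitive setting C.
    Participants with no stage-A candidates contribute their lesions to the
    false negatives.  Returns ``(per_participant, cohort_match)`` where each
    per-participant record holds the candidate list and which setting
    produced it.
    """
    a3, a2 = setting_a
    c3, c2 = setting_c
    if a3 < c3 or a2 < c2:
        raise ValueError(
            f"setting A {setting_a} must be at least as strict as C {setting_c}"
        )
    pipelines = _as_pipelines(cohort, rst_params, norm_spec, minip_spec, connectivity)
    per_participant = []
    tp = fp = fn = 0
    for i, p in enumerate(pipelines):
        at_a = p.passed_candidates(a3, a2)
        if at_a:
            final = p.passed_candidates(c3, c2)
            setting = "C"
        else:
            final = []
            setting = "A"
        result = match(final, p.truth, tol_mm=tol_mm, scope=scope)
        tp += result.tp
        fp += result.fp
        fn += result.fn
        per_participant.append(
            {
                "participant": i,
                "setting": setting,
                "n_candidates_a": len(at_a),
                "candidates": final,
                "match": result,
            }
        )
    return per_participant, MatchResult(tp=tp, fp=fp, fn=fn)


def froc_to_dataframe(points: list[FROCPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "t3d": p.t3d,
                "t2d": p.t2d,
                "sensitivity": p.sensitivity,
                "mean_candidates": p.mean_candidates_per_participant,
                "tp": p.tp,
                "fp": p.fp,
                "fn": p.fn,
            }
            for p in points
        ]
    )


def plot_froc(points: list[FROCPoint], frontier: list[FROCPoint] | None = None, path=None):
    """FROC curve: sensitivity vs mean candidate marks per participant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(
        [p.mean_candidates_per_participant for p in points],
        [p.sensitivity for p in points],
        s=18,
        label="threshold combinations",
    )
    if frontier:
        ax.plot(
            [p.mean_candidates_per_participant for p in frontier],
            [p.sensitivity for p in frontier],
            "k-",
            lw=1.2,
            label="optimal frontier",
        )
    ax.set_xlabel("Mean candidate locations per participant")
    ax.set_ylabel("Sensitivity")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
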