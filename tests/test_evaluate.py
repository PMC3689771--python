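import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmbdetect import (
    Candidate,
    FROCPoint,
    GroundTruthEntry,
    ParticipantPipeline,
    PhantomSpec,
    SphereSpec,
    TubeSpec,
    froc_grid,
    generate,
    match,
    pareto_frontier,
    tiered_screen,
)
from cmbdetect.evaluate import DEFAULT_T2D_VALUES, DEFAULT_T3D_VALUES
from cmbdetect.minip import filter_candidates
from cmbdetect.pipeline import PipelineConfig, run_pipeline

from .oracles import brute_force_frontier


def _cand(cid, world):
    return Candidate(cid, (0, 0, 0), world, 1.0)


def _truth(tid, world, label="definite"):
    return GroundTruthEntry(tid, world, label)


class TestMatch:
    def test_no_candidates_all_truth_missed(self):
        truths = [_truth(f"g{i}", (float(i * 20), 0.0, 0.0)) for i in range(3)]
        r = match([], truths)
        assert (r.tp, r.fp, r.fn) == (0, 0, 3)
        assert r.sensitivity == 0.0

    def test_perfect_detector(self):
        truths = [_truth(f"g{i}", (float(i * 20), 0.0, 0.0)) for i in range(4)]
        cands = [_cand(f"c{i}", t.world_mm) for i, t in enumerate(truths)]
        r = match(cands, truths)
        assert (r.tp, r.fp, r.fn) == (4, 0, 0)
        assert r.sensitivity == 1.0

    def test_one_candidate_between_two_truths_matches_once(self):
        truths = [_truth("g0", (0.0, 0.0, 0.0)), _truth("g1", (6.0, 0.0, 0.0))]
        cands = [_cand("c0", (3.0, 0.0, 0.0))]
        r = match(cands, truths, tol_mm=5.0)
        # maximal one-to-one set has size 1: enumerate both admissible
        # matchings {(c0,g0)}, {(c0,g1)} -- either way tp=1, fn=1
        assert (r.tp, r.fp, r.fn) == (1, 0, 1)
        assert len(r.pairs) == 1

    def test_greedy_prefers_closer_pair(self):
        truths = [_truth("g0", (0.0, 0.0, 0.0)), _truth("g1", (4.0, 0.0, 0.0))]
        cands = [_cand("c0", (1.0, 0.0, 0.0)), _cand("c1", (3.9, 0.0, 0.0))]
        r = match(cands, truths, tol_mm=5.0)
        assert ("c0", "g0") in r.pairs
        assert ("c1", "g1") in r.pairs

    def test_result_invariant_to_truth_permutation(self):
        rng = np.random.default_rng(14)
        truths = [
            _truth(f"g{i}", tuple(rng.uniform(0, 50, 3))) for i in range(6)
        ]
        cands = [_cand(f"c{i}", tuple(rng.uniform(0, 50, 3))) for i in range(8)]
        r1 = match(cands, truths)
        r2 = match(cands, list(reversed(truths)))
        assert (r1.tp, r1.fp, r1.fn) == (r2.tp, r2.fp, r2.fn)
        assert sorted(r1.pairs) == sorted(r2.pairs)

    def test_definite_only_scope(self):
        truths = [
            _truth("g0", (0.0, 0.0, 0.0), "definite"),
            _truth("g1", (30.0, 0.0, 0.0), "possible"),
        ]
        r = match([], truths, scope="definite_only")
        assert r.fn == 1

    def test_counts_are_consistent(self):
        rng = np.random.default_rng(15)
        truths = [_truth(f"g{i}", tuple(rng.uniform(0, 30, 3))) for i in range(5)]
        cands = [_cand(f"c{i}", tuple(rng.uniform(0, 30, 3))) for i in range(7)]
        r = match(cands, truths)
        assert r.tp + r.fn == len(truths)
        assert r.tp + r.fp == len(cands)
        assert r.tp == len(r.pairs)
        assert len({c for c, _ in r.pairs}) == len(r.pairs)
        assert len({g for _, g in r.pairs}) == len(r.pairs)


class TestParetoFrontier:
    def _pt(self, t3d, t2d, sens, cands):
        return FROCPoint(t3d, t2d, sens, cands, 0, 0, 0)

    def test_single_point_is_its_own_frontier(self):
        p = self._pt(1.0, 1.0, 0.5, 10.0)
        assert pareto_frontier([p]) == [p]

    def test_dominated_point_removed(self):
        good = self._pt(1.0, 1.0, 0.8, 5.0)
        bad = self._pt(0.5, 0.5, 0.7, 9.0)
        assert pareto_frontier([good, bad]) == [good]

    def test_exact_tie_keeps_larger_thresholds(self):
        a = self._pt(1.0, 0.5, 0.8, 5.0)
        b = self._pt(1.0, 1.0, 0.8, 5.0)
        assert pareto_frontier([a, b]) == [b]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)), min_size=1, max_size=42))
    def test_matches_brute_force_dominance_oracle(self, raw):
        rng = np.random.default_rng(16)
        points = [
            self._pt(
                float(i % 6) / 2 + 0.5,
                float(i % 7) / 2,
                s / 10.0,
                float(c),
            )
            for i, (s, c) in enumerate(raw)
        ]
        ours = pareto_frontier(points)
        oracle = brute_force_frontier(points)
        assert [(p.t3d, p.t2d) for p in ours] == [(p.t3d, p.t2d) for p in oracle]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pareto_frontier([])


@pytest.fixture(scope="module")
def mini_cohort():
    """Two small phantoms: one with a sphere and decoys, one decoys only."""
    spec_a = PhantomSpec(
        extents=(48, 48, 16),
        spheres=(SphereSpec((16.0, 16.0, 24.0), 5.0, 0.8),),
        tubes=(
            TubeSpec(((34.0, 8.0, 0.0), (36.0, 20.0, 23.0), (38.0, 32.0, 45.0)), 1.2, 0.7),
        ),
        seed=17,
    )
    spec_b = PhantomSpec(
        extents=(48, 48, 16),
        tubes=(
            TubeSpec(((12.0, 36.0, 0.0), (18.0, 30.0, 23.0), (24.0, 24.0, 45.0)), 1.3, 0.8),
        ),
        seed=18,
    )
    outs = [generate(spec_a), generate(spec_b)]
    return [(o.volume, o.mask, o.truth) for o in outs]


@pytest.fixture(scope="module")
def mini_pipelines(mini_cohort):
    return [ParticipantPipeline(*t) for t in mini_cohort]


class TestFrocGrid:
    def test_default_lattice_has_42_points(self, mini_pipelines):
        points = froc_grid(mini_pipelines)
        assert len(points) == 42
        assert len({(p.t3d, p.t2d) for p in points}) == 42

    def test_grid_of_one_equals_direct_pipeline_run(self, mini_cohort, mini_pipelines):
        t3d, t2d = 1.0, 0.5
        point = froc_grid(mini_pipelines, t3d_values=[t3d], t2d_values=[t2d])[0]
        total_passed = 0
        tp = fn = 0
        for volume, mask, truth in mini_cohort:
            config = PipelineConfig().with_thresholds(t3d, t2d)
            candidates, _ = run_pipeline(volume, mask, config)
            passed = [c for c in candidates if c.status == "passed_2d"]
            total_passed += len(passed)
            r = match(passed, truth)
            tp += r.tp
            fn += r.fn
        assert point.mean_candidates_per_participant == pytest.approx(
            total_passed / len(mini_cohort)
        )
        assert (point.tp, point.fn) == (tp, fn)

    def test_cached_grid_equals_recomputation_at_random_points(self, mini_cohort, mini_pipelines):
        rng = np.random.default_rng(19)
        for _ in range(3):
            t3d = float(rng.choice(DEFAULT_T3D_VALUES))
            t2d = float(rng.choice(DEFAULT_T2D_VALUES))
            cached = [
                p.passed_candidates(t3d, t2d) for p in mini_pipelines
            ]
            for (volume, mask, truth), cand_cached in zip(mini_cohort, cached):
                config = PipelineConfig().with_thresholds(t3d, t2d)
                fresh, _ = run_pipeline(volume, mask, config)
                fresh_passed = [c for c in fresh if c.status == "passed_2d"]
                assert [(c.voxel_index, c.s3d) for c in cand_cached] == [
                    (c.voxel_index, c.s3d) for c in fresh_passed
                ]
                for a, b in zip(cand_cached, fresh_passed):
                    if t2d > 0:
                        assert a.s2d == pytest.approx(b.s2d, abs=1e-12)

    def test_sensitivity_extremes_ordered(self, mini_pipelines):
        permissive = froc_grid(mini_pipelines, t3d_values=[0.5], t2d_values=[0.0])[0]
        strict = froc_grid(mini_pipelines, t3d_values=[3.0], t2d_values=[3.0])[0]
        assert permissive.sensitivity >= strict.sensitivity

    def test_empty_cohort_or_grid_rejected(self, mini_pipelines):
        with pytest.raises(ValueError):
            froc_grid([])
        with pytest.raises(ValueError):
            froc_grid(mini_pipelines, t3d_values=[])


class TestTieredScreen:
    def test_degenerate_tiering_equals_flat_run(self, mini_pipelines):
        setting = (1.0, 0.5)
        per, cohort_match = tiered_screen(
            mini_pipelines, setting_a=setting, setting_c=setting
        )
        flat = froc_grid(mini_pipelines, t3d_values=[1.0], t2d_values=[0.5])[0]
        assert cohort_match.tp == flat.tp
        assert cohort_match.fn == flat.fn

    def test_participant_empty_at_a_is_never_rerun(self, mini_pipelines):
        per, _ = tiered_screen(
            mini_pipelines, setting_a=(1e9, 1e9), setting_c=(0.5, 0.0)
        )
        assert all(rec["setting"] == "A" for rec in per)
        assert all(rec["candidates"] == [] for rec in per)
        total_truth = sum(len(p.truth) for p in mini_pipelines)
        assert sum(rec["match"].fn for rec in per) == total_truth

    def test_tiered_sensitivity_bounded_by_flat_settings(self, mini_pipelines):
        setting_a, setting_c = (2.0, 1.0), (0.5, 0.5)
        _, cohort_match = tiered_screen(
            mini_pipelines, setting_a=setting_a, setting_c=setting_c
        )
        flat_a = froc_grid(mini_pipelines, t3d_values=[setting_a[0]], t2d_values=[setting_a[1]])[0]
        flat_c = froc_grid(mini_pipelines, t3d_values=[setting_c[0]], t2d_values=[setting_c[1]])[0]
        assert flat_a.sensitivity <= cohort_match.sensitivity <= flat_c.sensitivity

    def test_precondition_a_stricter_than_c(self, mini_pipelines):
        with pytest.raises(ValueError):
            tiered_screen(mini_pipelines, setting_a=(0.5, 0.5), setting_c=(1.0, 1.0))
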