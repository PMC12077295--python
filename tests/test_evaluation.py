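"""Hungarian matching, F1 aggregation, angular errors and placement RMSD."""

import itertools

import numpy as np
import pytest

from cryoab.codec import AbPose
from cryoab.evaluation import (
    angular_errors,
    evaluate_system,
    f1_scores,
    match,
    placement_rmsd,
)
from cryoab.rotations import axis_rotation, random_rotation

UZ = np.array([0.0, 0.0, 1.0])


def brute_force_assignment(dist: np.ndarray) -> float:
    """Minimum total distance over all injective assignments (oracle)."""
    n_pred, n_gt = dist.shape
    k = min(n_pred, n_gt)
    best = np.inf
    for rows in itertools.permutations(range(n_pred), k):
        for cols in itertools.permutations(range(n_gt), k):
            best = min(best, sum(dist[r, c] for r, c in zip(rows, cols)))
    return best


class TestMatch:
    def test_single_close_pair_is_tp(self):
        r = match([(0.0, 0.0, 3.0)], [(0.0, 0.0, 0.0)])
        assert (r.tp, r.fp, r.fn) == (1, 0, 0)
        assert r.f1 == pytest.approx(1.0)

    def test_single_distant_pair_is_fp_and_fn(self):
        r = match([(0.0, 0.0, 15.0)], [(0.0, 0.0, 0.0)])
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)
        assert r.f1 == pytest.approx(0.0)

    def test_assignment_beats_greedy(self):
        # distance matrix [[1,2],[2,100]]: optimal pairing is (p0-g1, p1-g0)
        preds = [(0.0, 0.0, 0.0), (0.0, 0.0, 3.0)]
        gts = [(0.0, 0.0, 1.0), (0.0, 0.0, 2.0)]
        r = match(preds, gts, tp_threshold=1000.0)
        total = sum(d for _, _, d in r.pairs)
        dist = np.linalg.norm(
            np.array(preds)[:, None] - np.array(gts)[None], axis=2
        )
        assert total == pytest.approx(brute_force_assignment(dist))

    def test_empty_inputs(self):
        r = match([], [])
        assert (r.tp, r.fp, r.fn) == (0, 0, 0)
        assert r.f1 == pytest.approx(1.0)  # empty system, nothing predicted
        r2 = match([], [(0.0, 0.0, 0.0)])
        assert (r2.tp, r2.fp, r2.fn) == (0, 0, 1)
        r3 = match([(0.0, 0.0, 0.0)], [])
        assert (r3.tp, r3.fp, r3.fn) == (0, 1, 0)

    def test_counting_identities(self, rng):
        for _ in range(20):
            preds = rng.uniform(0, 60, size=(rng.integers(0, 7), 3))
            gts = rng.uniform(0, 60, size=(rng.integers(0, 7), 3))
            r = match(preds, gts)
            assert r.tp + r.fn == len(gts)
            assert r.tp + r.fp == len(preds)

    def test_matches_exhaustive_search_100_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n_pred = int(rng.integers(1, 7))
            n_gt = int(rng.integers(1, 7))
            preds = rng.uniform(0, 50, size=(n_pred, 3))
            gts = rng.uniform(0, 50, size=(n_gt, 3))
            r = match(preds, gts, tp_threshold=np.inf)
            dist = np.linalg.norm(preds[:, None] - gts[None], axis=2)
            total = sum(d for _, _, d in r.pairs)
            assert total == pytest.approx(brute_force_assignment(dist), rel=1e-12)


class TestF1Aggregation:
    def _result(self, tp, fp, fn):
        from cryoab.evaluation import MatchResult

        return MatchResult(pairs=[], tp=tp, fp=fp, fn=fn, n_pred=tp + fp, n_gt=tp + fn)

    def test_all_perfect(self):
        s = f1_scores([self._result(2, 0, 0), self._result(1, 0, 0)])
        assert s["f1_ab"] == pytest.approx(100.0)
        assert s["f1_sys"] == pytest.approx(100.0)

    def test_system_average(self):
        s = f1_scores([self._result(1, 0, 0), self._result(0, 1, 1)])
        assert s["f1_sys"] == pytest.approx(50.0)

    def test_pooled_differs_from_per_system(self):
        # one big perfect system + two small failures: pooling favors the
        # big system, per-system averaging does not
        results = [self._result(8, 0, 0), self._result(0, 1, 1), self._result(0, 1, 1)]
        s = f1_scores(results)
        assert s["f1_ab"] == pytest.approx(100 * 16 / (16 + 2 + 2))
        assert s["f1_sys"] == pytest.approx(100 / 3)
        assert s["f1_ab"] != pytest.approx(s["f1_sys"])

    def test_order_invariance(self, rng):
        results = [self._result(int(a), int(b), int(c)) for a, b, c in rng.integers(0, 4, (6, 3))]
        s1 = f1_scores(results)
        s2 = f1_scores(results[::-1])
        assert s1 == s2


class TestAngles:
    def test_identical_poses_zero_error(self):
        pose = AbPose(rotation=axis_rotation(UZ, 0.5), translation=np.zeros(3))
        d, t = angular_errors(pose, pose)
        assert d == pytest.approx(0.0, abs=1e-9)
        assert t == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_direction(self):
        a = AbPose(rotation=np.eye(3), translation=np.zeros(3))
        b = AbPose(rotation=np.diag([1.0, -1.0, -1.0]), translation=np.zeros(3))
        d, _ = angular_errors(a, b)
        assert d == pytest.approx(180.0)

    def test_theta_wrapping(self):
        a = AbPose(rotation=axis_rotation(UZ, np.radians(175.0)), translation=np.zeros(3))
        b = AbPose(rotation=axis_rotation(UZ, np.radians(-175.0)), translation=np.zeros(3))
        _, t = angular_errors(a, b)
        assert t == pytest.approx(10.0, abs=1e-6)

    def test_direction_error_symmetric(self, rng):
        a = AbPose(rotation=random_rotation(rng), translation=np.zeros(3))
        b = AbPose(rotation=random_rotation(rng), translation=np.zeros(3))
        assert angular_errors(a, b)[0] == pytest.approx(angular_errors(b, a)[0])


class TestPlacementRmsd:
    def test_identical_poses(self, fab_template, rng):
        pose = AbPose(rotation=random_rotation(rng), translation=rng.uniform(0, 50, 3))
        assert placement_rmsd(pose, pose, fab_template) == pytest.approx(0.0)

    def test_pure_translation_equals_offset(self, fab_template, rng):
        r = random_rotation(rng)
        a = AbPose(rotation=r, translation=np.zeros(3))
        b = AbPose(rotation=r, translation=np.array([3.0, 4.0, 0.0]))
        assert placement_rmsd(a, b, fab_template) == pytest.approx(5.0)

    def test_matches_per_atom_loop(self, fab_template, rng):
        a = AbPose(rotation=random_rotation(rng), translation=rng.uniform(0, 30, 3))
        b = AbPose(rotation=random_rotation(rng), translation=rng.uniform(0, 30, 3))
        got = placement_rmsd(a, b, fab_template)
        coords = fab_template.atom_coords
        sq = [
            np.sum((a.rotation @ c + a.translation - b.rotation @ c - b.translation) ** 2)
            for c in coords
        ]
        assert got == pytest.approx(np.sqrt(np.mean(sq)), rel=1e-12)


class TestEvaluateSystem:
    def test_pose_metrics_only_for_true_positives(self, templates, rng):
        gt = [
            AbPose(rotation=random_rotation(rng), translation=np.array([10.0, 10.0, 10.0])),
            AbPose(rotation=random_rotation(rng), translation=np.array([50.0, 50.0, 50.0])),
        ]
        pred = [
            AbPose(rotation=gt[0].rotation, translation=gt[0].translation + 2.0),
            AbPose(rotation=random_rotation(rng), translation=np.array([90.0, 90.0, 90.0])),
        ]
        r = evaluate_system(pred, gt, templates)
        assert r.tp == 1 and r.fp == 1 and r.fn == 1
        assert len(r.angle_errors) == 1
        assert len(r.rmsds) == 1
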