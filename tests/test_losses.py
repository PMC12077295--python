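"""Loss-term identities, oracles and differentiability."""

import numpy as np
import pytest

from cryoab import autograd as ag
from cryoab.codec import GridGeometry, TargetGrid, encode_poses
from cryoab.losses import (
    LossWeights,
    _cell_cost_matrix,
    focal,
    l1_occupancy,
    l2_sinkhorn,
    l3_offset,
    l4_direction,
    l5_angle,
    l6_class,
    sinkhorn_divergence_weights,
    total_loss,
)

from conftest import sample_poses

LN2 = np.log(2.0)


class TestFocal:
    def test_zero_at_perfect_prediction(self):
        assert focal(np.array(1.0 - 1e-9), 1.0, 4.0, 30.0).item() == pytest.approx(0.0, abs=1e-5)
        assert focal(np.array(1e-9), 0.0, 4.0, 30.0).item() == pytest.approx(0.0, abs=1e-5)

    def test_positive_half_prediction(self):
        # lam * 0.5^gamma * ln 2
        val = focal(np.array(0.5), 1.0, 4.0, 30.0).item()
        assert val == pytest.approx(30 * 0.5**4 * LN2, rel=1e-12)
        assert val == pytest.approx(1.29965, abs=1e-5)

    def test_negative_half_prediction(self):
        val = focal(np.array(0.5), 0.0, 4.0, 30.0).item()
        assert val == pytest.approx(0.5**4 * LN2, rel=1e-12)
        assert val == pytest.approx(0.04332, abs=1e-5)

    def test_l1_matches_per_cell_loop(self, rng):
        pred = rng.uniform(0.01, 0.99, size=(4, 4, 4))
        target = (rng.random((4, 4, 4)) < 0.1).astype(float)
        geom = GridGeometry(shape=(4, 4, 4))
        channels = np.zeros((10, 4, 4, 4))
        channels[0] = target
        tg = TargetGrid(channels, geom)
        w = LossWeights()
        got = l1_occupancy(ag.Tensor(np.concatenate([pred[None], np.zeros((9, 4, 4, 4))])), tg, w).item()
        expect = sum(
            focal(np.array(pred[i, j, k]), target[i, j, k], w.gamma, w.lam).item()
            for i in range(4)
            for j in range(4)
            for k in range(4)
        )
        assert got == pytest.approx(expect, rel=1e-9)


class TestSinkhorn:
    def test_identical_measures_vanish(self, rng):
        cost = _cell_cost_matrix((4, 4, 4), 8.0)
        a = rng.random(64) + 1e-3
        a /= a.sum()
        val, _, _ = sinkhorn_divergence_weights(cost, a, a.copy(), blur=8.0)
        assert abs(val) < 1e-6

    def test_symmetry(self, rng):
        cost = _cell_cost_matrix((3, 3, 3), 8.0)
        a = rng.random(27) + 1e-3
        a /= a.sum()
        b = rng.random(27) + 1e-3
        b /= b.sum()
        v1, _, _ = sinkhorn_divergence_weights(cost, a, b, blur=4.0, n_final=30)
        v2, _, _ = sinkhorn_divergence_weights(cost, b, a, blur=4.0, n_final=30)
        assert v1 == pytest.approx(v2, rel=1e-6, abs=1e-8)

    def test_point_masses_approach_squared_distance(self):
        # two unit point masses d apart: S -> d^2 as blur -> 0
        cost = _cell_cost_matrix((8, 1, 1), 8.0)
        for i, j in [(0, 3), (1, 6)]:
            a = np.zeros(8)
            a[i] = 1.0
            b = np.zeros(8)
            b[j] = 1.0
            d2 = cost[i, j]
            for blur in (4.0, 1.0, 0.25):
                val, _, _ = sinkhorn_divergence_weights(cost, a, b, blur=blur, n_final=50)
            assert val == pytest.approx(d2, rel=1e-4)

    def test_monotone_as_mass_approaches_target(self):
        cost = _cell_cost_matrix((12, 1, 1), 8.0)
        b = np.zeros(12)
        b[0] = 1.0
        values = []
        for i in (10, 8, 6, 4, 2):
            a = np.zeros(12)
            a[i] = 1.0
            val, _, _ = sinkhorn_divergence_weights(cost, a, b, blur=8.0, n_final=30)
            values.append(val)
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_l2_zero_for_matching_prediction(self, rng):
        geom = GridGeometry(shape=(6, 6, 6), cell_size=8.0)
        poses = sample_poses(rng, 3, geom)
        tg = encode_poses(poses, geom)
        pred = np.zeros((10, 6, 6, 6))
        pred[0] = tg.occupancy
        val = l2_sinkhorn(ag.Tensor(pred), tg, LossWeights()).item()
        assert abs(val) < 1e-6


class TestPoseTerms:
    def test_l4_zero_at_target_and_two_at_antipode(self, rng):
        p = rng.normal(size=3)
        p /= np.linalg.norm(p)
        assert l4_direction(ag.Tensor(p), p).item() == pytest.approx(0.0, abs=1e-9)
        assert l4_direction(ag.Tensor(-p), p).item() == pytest.approx(2.0, abs=1e-9)

    def test_l4_degenerate_minimum_at_twice_target(self, rng):
        # 1 - <2p, p> + (||2p|| - 1)^2 = 1 - 2 + 1 = 0: the loss is not
        # uniquely minimized at the unit target (documented behavior)
        p = rng.normal(size=3)
        p /= np.linalg.norm(p)
        assert l4_direction(ag.Tensor(2 * p), p).item() == pytest.approx(0.0, abs=1e-9)

    def test_l5_zero_at_target(self):
        u = np.array([np.cos(0.4), np.sin(0.4)])
        assert l5_angle(ag.Tensor(u), u).item() == pytest.approx(0.0, abs=1e-9)

    def test_l3_is_mean_squared_error(self):
        assert l3_offset(ag.Tensor(np.array([1.0, 2.0, 3.0])), np.array([0.0, 0.0, 0.0])).item() == pytest.approx((1 + 4 + 9) / 3)

    def test_l6_values(self):
        w = LossWeights()
        assert l6_class(ag.Tensor(np.array(0.5)), 0.0, w).item() == pytest.approx(0.04332, abs=1e-5)
        assert l6_class(ag.Tensor(np.array(0.5)), 1.0, w).item() == pytest.approx(2.5 * 0.5**4 * LN2, rel=1e-9)
        assert l6_class(ag.Tensor(np.array(1.0 - 1e-9)), 1.0, w).item() == pytest.approx(0.0, abs=1e-5)


class TestTotalLoss:
    def _perfect_prediction(self, tg):
        pred = tg.channels.copy()
        pred[0] = np.clip(pred[0], 1e-9, 1 - 1e-9)
        pred[9] = np.where(tg.occupancy > 0, np.clip(pred[9], 1e-9, 1 - 1e-9), 0.5)
        return pred

    def test_perfect_prediction_vanishes(self, rng):
        geom = GridGeometry(shape=(6, 6, 6), cell_size=8.0)
        tg = encode_poses(sample_poses(rng, 3, geom), geom)
        total, terms = total_loss(ag.Tensor(self._perfect_prediction(tg)), tg)
        assert total.item() == pytest.approx(0.0, abs=1e-3)
        for name in ("l1_focal", "l2_sinkhorn", "l3_offset", "l4_direction", "l5_angle"):
            assert abs(terms[name]) < 1e-3

    def test_lambda_s_zero_reduces_to_global_terms(self, rng):
        geom = GridGeometry(shape=(5, 5, 5), cell_size=8.0)
        tg = encode_poses(sample_poses(rng, 2, geom), geom)
        pred = ag.Tensor(rng.uniform(0.1, 0.9, size=(10, 5, 5, 5)))
        w0 = LossWeights(lam_s=0.0)
        total, terms = total_loss(pred, tg, w0)
        assert total.item() == pytest.approx(terms["l1_focal"] + terms["l2_sinkhorn"], rel=1e-9)

    def test_total_recomposes_from_terms(self, rng):
        geom = GridGeometry(shape=(5, 5, 5), cell_size=8.0)
        tg = encode_poses(sample_poses(rng, 2, geom), geom)
        pred = ag.Tensor(rng.uniform(0.1, 0.9, size=(10, 5, 5, 5)))
        w = LossWeights()
        total, terms = total_loss(pred, tg, w)
        expect = (
            terms["l1_focal"]
            + terms["l2_sinkhorn"]
            + w.lam_s
            * (terms["l3_offset"] + terms["l4_direction"] + terms["l5_angle"] + terms["l6_class"])
        )
        assert total.item() == pytest.approx(expect, rel=1e-9)

    def test_direction_terms_bounded_below(self, rng):
        # closed-form minimum of 1 - c + (c - 1)^2 over c = ||v|| is -1/4
        for _ in range(200):
            v = rng.normal(scale=2.0, size=3)
            p = rng.normal(size=3)
            p /= np.linalg.norm(p)
            assert l4_direction(ag.Tensor(v), p).item() >= -0.25 - 1e-9

    def test_gradient_matches_finite_differences(self, rng):
        geom = GridGeometry(shape=(3, 3, 3), cell_size=8.0)
        tg = encode_poses(sample_poses(rng, 1, geom), geom)
        w = LossWeights(ot_final_iters=60)
        x = ag.parameter(rng.uniform(0.2, 0.8, size=(10, 3, 3, 3)))
        total, _ = total_loss(x, tg, w)
        total.backward()
        eps = 1e-6
        idx = [(0, 1, 1, 1), (0, 2, 0, 1), (1,) + tuple(tg.occupied_cells()[0]),
               (4,) + tuple(tg.occupied_cells()[0]), (9,) + tuple(tg.occupied_cells()[0]),
               (0,) + tuple(tg.occupied_cells()[0])]
        for i in idx:
            orig = x.data[i]
            x.data[i] = orig + eps
            lp = total_loss(x, tg, w)[0].item()
            x.data[i] = orig - eps
            lm = total_loss(x, tg, w)[0].item()
            x.data[i] = orig
            num = (lp - lm) / (2 * eps)
            assert x.grad[i] == pytest.approx(num, rel=1e-3, abs=1e-5)
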