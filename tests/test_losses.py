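"""Loss oracles: hand-evaluated closed forms, brute-force Chamfer,
EMA geometric series, and gradient-flow contracts."""

import numpy as np
import pytest

from vesseltrace.losses import (
    EMAState,
    chamfer_loss,
    edge_length_reg,
    ema_update,
    point_lumen_reg,
    total_loss,
    voxel_loss,
)
from vesseltrace.nn.autodiff import Tensor


def brute_force_chamfer(a, b):
    """O(N*M) all-pairs oracle with unsquared Euclidean norms."""
    total = 0.0
    for p in a:
        total += min(np.sqrt(((p - q) ** 2).sum()) for q in b)
    for q in b:
        total += min(np.sqrt(((q - p) ** 2).sum()) for p in a)
    return total


class TestVoxelLoss:
    def test_perfect_prediction_tends_to_minus_one(self):
        mt = (np.arange(64).reshape(4, 4, 4) % 3 == 0).astype(np.float32)
        mp = mt.copy()  # exact probabilities; internal clamp handles log(0)
        val = voxel_loss(Tensor(mp), mt).item()
        assert val == pytest.approx(-1.0, abs=1e-4)

    def test_single_voxel_hand_value(self):
        # focal: -1 * (1-0.5) * ln 0.5 = 0.34657; dice: 2*0.5/1.5 = 0.66667
        val = voxel_loss(Tensor(np.array([[[0.5]]])), np.array([[[1.0]]])).item()
        assert val == pytest.approx(-0.32010, abs=1e-5)

    def test_empty_foreground_is_zero(self, rng):
        mp = rng.uniform(0.01, 0.99, size=(4, 4, 4)).astype(np.float32)
        mt = np.zeros((4, 4, 4), dtype=np.float32)
        assert voxel_loss(Tensor(mp), mt).item() == pytest.approx(0.0, abs=1e-6)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            voxel_loss(Tensor(np.zeros((2, 2, 2))), np.zeros((3, 2, 2)))


class TestChamfer:
    @pytest.mark.parametrize(
        "cp,ct,expected",
        [
            ([(0, 0, 0), (1, 0, 0)], [(0, 0, 0), (1, 0, 0)], 0.0),
            ([(0, 0, 0)], [(3, 4, 0)], 10.0),
            ([(0, 0, 0), (2, 0, 0)], [(1, 0, 0)], 3.0),
        ],
    )
    def test_toy_cases(self, cp, ct, expected):
        val = chamfer_loss(Tensor(np.array(cp, float)), np.array(ct, float)).item()
        assert val == pytest.approx(expected, abs=1e-6)

    def test_matches_brute_force_on_200_random_instances(self, rng):
        for _ in range(200):
            n, m = rng.integers(1, 31, size=2)
            a = rng.normal(0, 5, size=(n, 3))
            b = rng.normal(0, 5, size=(m, 3))
            got = chamfer_loss(Tensor(a.astype(np.float64)), b).item()
            assert got == pytest.approx(brute_force_chamfer(a, b), abs=1e-9)

    def test_permutation_invariance_and_zero_iff_equal(self, rng):
        a = rng.normal(size=(12, 3))
        perm = rng.permutation(12)
        assert chamfer_loss(Tensor(a), a[perm]).item() == pytest.approx(0.0, abs=1e-5)
        b = a.copy()
        b[3] += 1.0
        assert chamfer_loss(Tensor(a), b).item() > 0.1

    def test_squared_mode(self):
        val = chamfer_loss(
            Tensor(np.array([[0.0, 0.0, 0.0]])), np.array([[3.0, 4.0, 0.0]]),
            squared=True,
        ).item()
        assert val == pytest.approx(50.0, abs=1e-4)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            chamfer_loss(Tensor(np.zeros((0, 3))), np.ones((2, 3)))


class TestEdgeLengthReg:
    def test_hand_values(self):
        assert edge_length_reg(
            Tensor(np.array([(0, 0, 0), (1, 0, 0), (2, 0, 0)], float))
        ).item() == pytest.approx(2.0, abs=1e-6)
        assert edge_length_reg(
            Tensor(np.array([(0, 0, 0), (3, 4, 0)], float))
        ).item() == pytest.approx(25.0, abs=1e-5)

    def test_uniform_placement_is_argmin_for_fixed_endpoints(self):
        # one free middle point between (0,0,0) and (2,0,0)
        def value(x):
            pts = np.array([(0, 0, 0), (x, 0, 0), (2, 0, 0)], float)
            return edge_length_reg(Tensor(pts)).item()

        xs = np.linspace(0.05, 1.95, 77)
        vals = [value(x) for x in xs]
        assert value(1.0) == pytest.approx(2.0, abs=1e-6)
        assert value(0.5) == pytest.approx(2.5, abs=1e-6)
        assert min(vals) >= value(1.0) - 1e-9

    @pytest.mark.parametrize("n_free", [2, 3, 4])
    def test_uniform_argmin_numerically_n_points(self, n_free, rng):
        # N interior points on the segment x in [0, 1]: random placements
        # never beat the uniform one
        uniform = np.linspace(0, 1, n_free + 2)

        def value(xs):
            pts = np.zeros((n_free + 2, 3))
            pts[:, 0] = np.concatenate([[0.0], np.sort(xs), [1.0]])
            return edge_length_reg(Tensor(pts)).item()

        best = value(uniform[1:-1])
        for _ in range(200):
            assert value(rng.uniform(0.01, 0.99, size=n_free)) >= best - 1e-9


class TestPointLumenReg:
    def test_deep_inside_lumen_tends_to_minus_one(self):
        mp = Tensor(np.ones((1, 6, 6, 6), dtype=np.float32))
        pts = Tensor(np.full((8, 3), 0.5, dtype=np.float32))
        assert point_lumen_reg(pts, mp).item() == pytest.approx(-1.0, abs=1e-4)

    def test_half_probability_hand_value(self):
        n = 5
        mp = Tensor(np.full((1, 6, 6, 6), 0.5, dtype=np.float32))
        pts = Tensor(np.full((n, 3), 0.5, dtype=np.float32))
        expected = n * 0.5 * np.log(2.0) - 2 * (0.5 * n) / (1.5 * n)
        assert point_lumen_reg(pts, mp).item() == pytest.approx(expected, abs=1e-5)

    def test_stop_gradient_and_coordinate_gradient(self):
        # mask with a sharp edge along the first axis
        vals = np.zeros((1, 8, 8, 8), dtype=np.float32)
        vals[:, 4:] = 1.0
        mp = Tensor(vals, requires_grad=True)
        pts = Tensor(np.full((4, 3), 0.5, dtype=np.float32), requires_grad=True)
        loss = point_lumen_reg(pts, mp)
        loss.backward()
        assert mp.grad is None or np.all(mp.grad == 0)  # stop-gradient
        assert pts.grad is not None and np.abs(pts.grad).max() > 0


class TestEMA:
    def test_geometric_series_closed_form(self):
        state = EMAState(alpha=0.9)
        for k in range(1, 30):
            ema_update(state, 1.0)
            assert state.running == pytest.approx(1 - 0.9**k, abs=1e-12)

    def test_constant_stream_converges(self):
        state = EMAState(alpha=0.9)
        for _ in range(500):
            ema_update(state, 3.25)
        assert state.running == pytest.approx(3.25, abs=1e-4)

    def test_alpha_zero_tracks_latest(self):
        state = EMAState(alpha=0.0)
        ema_update(state, 7.0)
        assert state.running == 7.0
        ema_update(state, -2.0)
        assert state.running == -2.0

    def test_tensor_term_gradient_scaled_by_one_minus_alpha(self):
        state = EMAState(alpha=0.9, running=2.0)
        x = Tensor(np.array(5.0), requires_grad=True)
        term = ema_update(state, x * 1.0)
        assert term.item() == pytest.approx(0.9 * 2.0 + 0.1 * 5.0)
        term.backward()
        assert x.grad == pytest.approx(0.1)


class TestTotalLoss:
    def _toy_inputs(self, rng):
        mp = Tensor(
            rng.uniform(0.2, 0.8, size=(1, 1, 8, 8, 8)).astype(np.float32),
            requires_grad=True,
        )
        mt = (rng.random((1, 1, 8, 8, 8)) > 0.7).astype(np.float32)
        stages = [
            [
                Tensor(rng.uniform(0.2, 0.8, size=(6, 3)).astype(np.float32),
                       requires_grad=True)
                for _ in range(5)
            ]
        ]
        ct = rng.uniform(0.2, 0.8, size=(9, 3)).astype(np.float32)
        return mp, mt, stages, [ct]

    def test_breakdown_sums_to_total(self, rng):
        mp, mt, stages, cts = self._toy_inputs(rng)
        bd = total_loss(mp, mt, stages, cts, EMAState(), EMAState())
        assert bd.l_total == pytest.approx(
            bd.l_vox + bd.l_cd + bd.l_elr + bd.l_plr, abs=1e-5
        )

    def test_composed_value_matches_component_oracles(self, rng):
        from vesseltrace.losses import matched_polyline_loss

        mp, mt, stages, cts = self._toy_inputs(rng)
        ev, ep = EMAState(), EMAState()
        bd = total_loss(mp, mt, stages, cts, ev, ep)
        mp2 = np.concatenate([mp.data, 1 - mp.data], axis=1)
        mt2 = np.concatenate([mt, 1 - mt], axis=1)
        vox = voxel_loss(Tensor(mp2), mt2, class_axis=1).item()
        cd = chamfer_loss(Tensor(stages[0][-1].data), cts[0]).item() + sum(
            matched_polyline_loss(Tensor(s.data), cts[0]).item()
            for s in stages[0][:-1]
        )
        elr = edge_length_reg(Tensor(stages[0][-1].data)).item()
        plr = point_lumen_reg(Tensor(stages[0][-1].data), Tensor(mp.data[0])).item()
        assert bd.raw_vox == pytest.approx(vox, rel=1e-5)
        assert bd.l_cd == pytest.approx(cd, rel=1e-5)
        assert bd.l_elr == pytest.approx(elr, rel=1e-4)
        assert bd.raw_plr == pytest.approx(plr, rel=1e-4, abs=1e-5)
        assert bd.l_vox == pytest.approx(0.1 * vox, rel=1e-5)  # first EMA step

    def test_deep_supervision_toggle(self, rng):
        mp, mt, stages, cts = self._toy_inputs(rng)
        with_ds = total_loss(mp, mt, stages, cts, EMAState(), EMAState())
        final_only = total_loss(
            mp, mt, stages, cts, EMAState(), EMAState(), deep_supervision=False
        )
        assert with_ds.l_cd > final_only.l_cd

    def test_centerline_terms_send_no_gradient_to_mask(self, rng):
        mp, mt, stages, cts = self._toy_inputs(rng)
        bd = total_loss(mp, mt, stages, cts, EMAState(), EMAState())
        bd.total.backward()
        # recompute with only the centerline terms: mask gradient must come
        # exclusively from the voxel loss (stop-gradient in the lumen term)
        from vesseltrace.nn.autodiff import concat

        mp2 = Tensor(mp.data.copy(), requires_grad=True)
        mt2 = np.concatenate([mt, 1 - mt], axis=1)
        two_class = concat([mp2, 1.0 - mp2], axis=1)
        vox_only = voxel_loss(two_class, mt2, class_axis=1) * 0.1  # first EMA step
        vox_only.backward()
        np.testing.assert_allclose(mp.grad, mp2.grad, atol=1e-6)
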