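"""Network contracts: shapes, determinism, sampling oracles, graph-conv
equivariance, differentiability, and the fixed-chain output topology."""

import numpy as np
import pytest

from vesseltrace.nn.autodiff import Tensor, grid_sample
from vesseltrace.nn.layers import GraphConv, RGConvBlock, chain_adjacency
from vesseltrace.nn.model import (
    VesselCenterlineNet,
    init_polyline,
    load_checkpoint,
    paper_config,
    save_checkpoint,
    tiny_config,
)


@pytest.fixture(scope="module")
def net():
    return VesselCenterlineNet(tiny_config(seed=0))


@pytest.fixture(scope="module")
def vol48(  ):
    rng = np.random.default_rng(42)
    return rng.random((1, 1, 48, 48, 48)).astype(np.float32)


class TestEncoder:
    def test_pyramid_shapes_ceil_halving(self, net, vol48):
        feats = net.encoder_forward(Tensor(vol48))
        shapes = [f.shape[2:] for f in feats]
        assert shapes == [(24, 24, 24), (12, 12, 12), (6, 6, 6), (3, 3, 3), (2, 2, 2)]

    def test_deterministic_forward(self, net, vol48):
        a = net.encoder_forward(Tensor(vol48))[-1].data
        b = net.encoder_forward(Tensor(vol48))[-1].data
        np.testing.assert_array_equal(a, b)

    def test_too_small_input_rejected(self, net):
        with pytest.raises(ValueError, match="smaller"):
            net.encoder_forward(Tensor(np.zeros((1, 1, 16, 16, 16))))

    def test_noncubic_input_shapes(self, net):
        feats = net.encoder_forward(Tensor(np.zeros((1, 1, 48, 40, 64))))
        assert feats[-1].shape[2:] == (2, 2, 2)


class TestVoxelDecoder:
    def test_output_grid_and_range(self, net, vol48):
        feats = net.encoder_forward(Tensor(vol48))
        prob, pyramid = net.voxel_decoder_forward(feats, (48, 48, 48))
        assert prob.shape == (1, 1, 48, 48, 48)
        assert prob.data.min() > 0.0 and prob.data.max() < 1.0
        assert len(pyramid) == 5

    def test_reproducible_output(self, net, vol48):
        feats = net.encoder_forward(Tensor(vol48))
        a, _ = net.voxel_decoder_forward(feats, (48, 48, 48))
        b, _ = net.voxel_decoder_forward(feats, (48, 48, 48))
        np.testing.assert_array_equal(a.data, b.data)


class TestTrilinearSampling:
    def test_voxel_center_exact(self, rng):
        feat = Tensor(rng.normal(size=(3, 4, 4, 4)).astype(np.float32))
        # center of cell (1,2,3) in normalized coords
        c = Tensor(np.array([[(1 + 0.5) / 4, (2 + 0.5) / 4, (3 + 0.5) / 4]],
                            dtype=np.float32))
        out = grid_sample(feat, c)
        np.testing.assert_allclose(out.data[0], feat.data[:, 1, 2, 3], atol=1e-6)

    def test_midpoint_is_mean_of_neighbors(self, rng):
        feat = Tensor(rng.normal(size=(2, 4, 4, 4)).astype(np.float32))
        c = Tensor(np.array([[(1.0 + 0.5 + 0.5) / 4, 0.5 / 4 + 0.125, 0.625]],
                            dtype=np.float32))
        # midpoint between cells (1,.,.) and (2,.,.) along the first axis
        c = Tensor(np.array([[2.0 / 4, 0.625, 0.625]], dtype=np.float32))
        out = grid_sample(feat, c)
        want = 0.5 * (feat.data[:, 1, 2, 2] + feat.data[:, 2, 2, 2])
        np.testing.assert_allclose(out.data[0], want, atol=1e-6)

    def test_out_of_range_clamps_to_border(self, rng):
        feat = Tensor(rng.normal(size=(2, 4, 4, 4)).astype(np.float32))
        outside = Tensor(np.array([[2.0, 0.5, 0.5]], dtype=np.float32))
        border = Tensor(np.array([[(3 + 0.5) / 4, 0.5, 0.5]], dtype=np.float32))
        np.testing.assert_allclose(
            grid_sample(feat, outside).data, grid_sample(feat, border).data, atol=1e-6
        )

    def test_matches_explicit_corner_sum(self, rng):
        feat = Tensor(rng.normal(size=(1, 5, 5, 5)).astype(np.float32))
        coords = rng.uniform(0.1, 0.9, size=(20, 3)).astype(np.float32)
        out = grid_sample(feat, Tensor(coords)).data[:, 0]
        cont = coords * 5 - 0.5
        i0 = np.floor(cont).astype(int)
        f = cont - i0
        want = np.zeros(20)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (f[:, 0] if dx else 1 - f[:, 0])
                        * (f[:, 1] if dy else 1 - f[:, 1])
                        * (f[:, 2] if dz else 1 - f[:, 2])
                    )
                    want += w * feat.data[0, i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        np.testing.assert_allclose(out, want, atol=1e-5)


class TestNeighborPrediction:
    def test_zero_head_neighbors_coincide_and_bound_holds(self, net, vol48):
        stage = net.cl_stages[0]
        feats = net.encoder_forward(Tensor(vol48))
        fmap = feats[-1][0]
        coords = Tensor(init_polyline(0, net.config.num_points))
        pts_f = grid_sample(fmap, coords)
        off = stage.nbr_head(pts_f).tanh()
        bound = 1.0 / np.asarray(fmap.shape[1:])
        scaled = off.data.reshape(-1, stage.k, 3) * bound
        assert np.all(np.abs(scaled) <= bound + 1e-7)
        # zeroing the head collapses neighbors onto candidates
        stage_w = stage.nbr_head.w.data.copy()
        stage_b = stage.nbr_head.b.data.copy()
        stage.nbr_head.w.data[:] = 0
        stage.nbr_head.b.data[:] = 0
        off0 = stage.nbr_head(pts_f).tanh().data
        assert np.all(off0 == 0)
        stage.nbr_head.w.data = stage_w
        stage.nbr_head.b.data = stage_b


class TestGraphConv:
    def test_chain_adjacency_rows_sum_behaviour(self):
        ahat = chain_adjacency(5)
        assert ahat.shape == (5, 5)
        assert np.allclose(ahat, ahat.T)
        # interior row couples exactly self + two neighbors
        assert np.count_nonzero(ahat[2]) == 3

    def test_reversal_equivariance(self, rng):
        n, c = 9, 6
        blk = RGConvBlock(c, rng)
        ahat = chain_adjacency(n)
        x = rng.normal(size=(n, c)).astype(np.float32)
        out = blk(Tensor(x), ahat).data
        out_rev = blk(Tensor(x[::-1].copy()), ahat).data
        np.testing.assert_allclose(out_rev, out[::-1], atol=1e-5)

    def test_zero_main_path_is_identity(self, rng):
        blk = RGConvBlock(4, rng)
        for gc in (blk.gc1, blk.gc2):
            gc.lin.w.data[:] = 0
            gc.lin.b.data[:] = 0
        # zero the LayerNorm gains so the normalized zeros stay zero
        blk.ln1.gamma.data[:] = 0
        blk.ln2.gamma.data[:] = 0
        x = rng.normal(size=(7, 4)).astype(np.float32)
        out = blk(Tensor(x), chain_adjacency(7)).data
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_receptive_field_grows_one_hop_per_graphconv(self, rng):
        n, c = 11, 3
        ahat = chain_adjacency(n)
        x = Tensor(rng.normal(size=(n, c)).astype(np.float32), requires_grad=True)
        blk = RGConvBlock(c, rng)  # two graph convs -> two hops
        out = blk(x, ahat)
        # probe with a random projection (a plain row-sum is constant under
        # the block's final LayerNorm and would carry no gradient)
        probe = Tensor(rng.normal(size=(c,)).astype(np.float32))
        (out[5] * probe).sum().backward()
        touched = np.abs(x.grad).sum(axis=1) > 0
        assert touched[3:8].all()
        assert not touched[:3].any() and not touched[8:].any()


class TestCenterlineDecoder:
    def test_five_stage_outputs_with_num_points(self, net, vol48):
        prob, polys = net.forward(vol48)
        assert len(polys) == 1 and len(polys[0]) == 5
        for stage_out in polys[0]:
            assert stage_out.shape == (net.config.num_points, 3)
            assert np.isfinite(stage_out.data).all()
            assert stage_out.data.min() >= 0 and stage_out.data.max() <= 1

    def test_zeroed_coord_heads_propagate_input(self, vol48):
        net2 = VesselCenterlineNet(tiny_config(seed=1))
        for stage in net2.cl_stages:
            stage.coord_head.lin.w.data[:] = 0
            stage.coord_head.lin.b.data[:] = 0
        init = init_polyline(5, net2.config.num_points)
        _, polys = net2.forward(vol48, init_coords=[init])
        for stage_out in polys[0]:
            np.testing.assert_allclose(stage_out.data, init, atol=1e-6)

    def test_output_depends_on_volume(self):
        # the coordinate heads are zero-initialized (identity at init), so
        # give them small random weights to probe the functional dependence
        net2 = VesselCenterlineNet(tiny_config(seed=3))
        rng = np.random.default_rng(0)
        for stage in net2.cl_stages:
            stage.coord_head.lin.w.data[:] = rng.normal(
                0, 0.01, size=stage.coord_head.lin.w.shape
            )
        init = init_polyline(9, net2.config.num_points)
        a = rng.random((1, 1, 48, 48, 48)).astype(np.float32)
        b = rng.random((1, 1, 48, 48, 48)).astype(np.float32)
        _, pa = net2.forward(a, init_coords=[init.copy()])
        _, pb = net2.forward(b, init_coords=[init.copy()])
        assert not np.allclose(pa[0][-1].data, pb[0][-1].data)

    def test_wrong_init_size_rejected(self, net, vol48):
        with pytest.raises(ValueError, match="init polyline"):
            net.forward(vol48, init_coords=[np.zeros((7, 3), dtype=np.float32)])


class TestInitPolyline:
    def test_range_spacing_and_reproducibility(self):
        a = init_polyline(3, 32)
        b = init_polyline(3, 32)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0
        gaps = np.linalg.norm(np.diff(a, axis=0), axis=1)
        assert np.allclose(gaps, gaps[0], atol=1e-6)
        assert not np.allclose(init_polyline(4, 32), a)


class TestEndToEnd:
    def test_gradients_finite_everywhere(self, vol48):
        from vesseltrace.losses import EMAState, total_loss

        net2 = VesselCenterlineNet(tiny_config(seed=2))
        rng = np.random.default_rng(7)
        mt = (rng.random((1, 1, 48, 48, 48)) > 0.9).astype(np.float32)
        ct = rng.uniform(0.2, 0.8, size=(20, 3)).astype(np.float32)
        prob, polys = net2.forward(vol48)
        bd = total_loss(prob, mt, polys, [ct], EMAState(), EMAState())
        net2.zero_grad()
        bd.total.backward()
        grads = [p.grad for p in net2.parameters()]
        assert all(g is not None and np.isfinite(g).all() for g in grads)

    def test_paper_preset_emits_96_points(self):
        cfg = paper_config()
        assert cfg.num_points == 96

    def test_checkpoint_round_trip(self, net, vol48, tmp_path):
        p = tmp_path / "ck.npz"
        save_checkpoint(p, net)
        model2, window, _ = load_checkpoint(p)
        _, pa = net.forward(vol48)
        _, pb = model2.forward(vol48)
        np.testing.assert_allclose(pa[0][-1].data, pb[0][-1].data, atol=1e-7)
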