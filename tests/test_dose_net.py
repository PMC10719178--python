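"""Residual dose network: identity initialization, transforms, training."""

import numpy as np
import pytest

from ybremdose import nn
from ybremdose.beta_dose import DoseKernel, DoseRateMap, dvk_convolve
from ybremdose.dose_net import (ActivityScaling, DoseNet, DoseNetSpec, DoseStudy,
                                build_dose_net, load_dose_checkpoint, make_pack,
                                predict_dose, save_dose_checkpoint,
                                single_stage_variant, train_dose_net)
from ybremdose.scatter_net import TrainConfig
from ybremdose.volumes import VoxelGrid, VoxelVolume


TINY = DoseNetSpec(extractor_channels=(2, 2, 4), unet_levels=2, unet_base_channels=4)


def _toy_study(seed=0, nz=16, sharp=True):
    """Blurred-activity study whose GT dose is the sharp activity itself."""
    from scipy import ndimage

    g = VoxelGrid((32, 32, nz), (2.0, 2.0, 2.0))
    rng = np.random.default_rng(seed)
    sharp_act = np.zeros(g.shape)
    for _ in range(3):
        i, j, k = rng.integers(8, 24), rng.integers(8, 24), rng.integers(4, nz - 4)
        sharp_act[i - 2:i + 2, j - 2:j + 2, k - 2:k + 2] = rng.uniform(2, 5)
    sharp_act += np.where(ndimage.distance_transform_edt(np.ones(g.shape)) >= 0, 0.5, 0)
    blurred = ndimage.gaussian_filter(sharp_act, 2.0)
    den = VoxelVolume(g, np.ones(g.shape), "density_g_per_cm3")
    act = VoxelVolume(g, blurred, "activity_MBq")
    kernel = DoseKernel(np.ones((1, 1, 1)) * 1e3, (2.0, 2.0, 2.0), 1)
    dvk = dvk_convolve(act, kernel, den)
    gt = DoseRateMap(VoxelVolume(g, sharp_act * 1e3, "dose_rate_nGy_per_s"), "MC")
    return DoseStudy(activity=act, density=den, dvk=dvk, gt=gt)


class TestArchitecture:
    def test_untrained_network_reproduces_dvk_exactly(self):
        net = build_dose_net(TINY, seed=1)
        st = _toy_study(0)
        pred, info = predict_dose(net, st.activity, st.density, st.dvk)
        assert np.allclose(pred.volume.values, st.dvk.volume.values)
        assert info["clamped_fraction"] == 0.0

    @pytest.mark.parametrize("hw", [(128, 128), (96, 64)])
    def test_inplane_size_preserved(self, hw):
        net = build_dose_net(TINY, seed=0)
        h, w = hw
        out = net.forward(np.zeros((1, 2, 11, h, w)), np.zeros((1, 1, h, w)),
                          np.ones((1, 1, h, w)))
        assert out.shape == (1, 1, h, w)

    def test_even_pack_depth_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            DoseNetSpec(pack_depth=10)

    def test_extractor_depth_budget_checked(self):
        with pytest.raises(ValueError):
            DoseNetSpec(pack_depth=5, extractor_depths=(5, 5, 3))

    def test_seeded_init_identical(self):
        a = build_dose_net(TINY, seed=9)
        b = build_dose_net(TINY, seed=9)
        for p1, p2 in zip(a.params, b.params):
            assert np.array_equal(p1[0], p2[0])

    def test_figure_and_text_depth_variants_both_build(self):
        for depths in ((5, 5, 3), (5, 3, 3)):
            spec = DoseNetSpec(extractor_depths=depths,
                               extractor_channels=(2, 2, 2),
                               unet_levels=2, unet_base_channels=4)
            net = build_dose_net(spec, seed=0)
            out = net.forward(np.zeros((1, 2, 11, 16, 16)), np.zeros((1, 1, 16, 16)),
                              np.ones((1, 1, 16, 16)))
            assert out.shape == (1, 1, 16, 16)


class TestPacks:
    def test_replicate_padding_at_ends(self):
        v = np.arange(2 * 2 * 5).reshape(2, 2, 5).astype(float)
        p = make_pack(v, z=0, depth=5)
        assert p.shape == (5, 2, 2)
        # slices below the volume replicate slice 0; the centre is z = 0
        assert np.array_equal(p[0], v[:, :, 0])
        assert np.array_equal(p[1], v[:, :, 0])
        assert np.array_equal(p[2], v[:, :, 0])
        assert np.array_equal(p[3], v[:, :, 1])
        tail = make_pack(v, z=4, depth=5)
        assert np.array_equal(tail[3], v[:, :, 4])
        assert np.array_equal(tail[4], v[:, :, 4])

    def test_scaling_round_trip(self):
        g = VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0))
        act = VoxelVolume(g, np.random.default_rng(0).random(g.shape), "activity_MBq")
        s = ActivityScaling().scale_for(act)
        assert (act.values * s).sum() == pytest.approx(ActivityScaling().normalizing_constant)
        assert np.allclose(act.values * s / s, act.values, rtol=1e-12)


class TestTraining:
    def test_zero_learning_rate_keeps_dvk_output(self):
        net = build_dose_net(TINY, seed=2)
        studies = [_toy_study(s) for s in range(2)]
        net, _ = train_dose_net(net, studies, TrainConfig(learning_rate=0.0, epochs=2),
                                crop_size=32)
        pred, _ = predict_dose(net, studies[0].activity, studies[0].density, studies[0].dvk)
        assert np.allclose(pred.volume.values, studies[0].dvk.volume.values)

    def test_training_beats_dvk_baseline(self):
        net = build_dose_net(TINY, seed=3)
        studies = [_toy_study(s) for s in range(3)]
        net, hist = train_dose_net(
            net, studies, TrainConfig(learning_rate=1e-3, epochs=15, batch_size=8, seed=0),
            crop_size=32)
        assert hist["best_val_mse"] < hist["dvk_baseline_val_mse"]

    def test_gt_labels_required(self):
        net = build_dose_net(TINY, seed=4)
        st = _toy_study(0)
        st.gt = None
        with pytest.raises(ValueError, match="GT"):
            train_dose_net(net, [st], TrainConfig())


class TestInference:
    def test_zero_activity_gives_zero_everywhere(self):
        net = build_dose_net(TINY, seed=5)
        st = _toy_study(1)
        zero_dvk = DoseRateMap(VoxelVolume(st.activity.grid,
                                           np.zeros(st.activity.grid.shape),
                                           "dose_rate_nGy_per_s"), "DVK")
        # zero activity implies zero DVK map; scaling guards against /0 so
        # feed a tiny uniform activity instead
        eps_act = VoxelVolume(st.activity.grid,
                              np.full(st.activity.grid.shape, 1e-12), "activity_MBq")
        pred, _ = predict_dose(net, eps_act, st.density, zero_dvk)
        assert np.allclose(pred.volume.values, 0.0)

    def test_axial_flip_equivariance_interior(self):
        net = build_dose_net(TINY, seed=6)
        # give the net a nonzero residual head so the test is non-trivial
        rng = np.random.default_rng(0)
        net.unet.head.params[0][0][...] = rng.standard_normal(
            net.unet.head.params[0][0].shape) * 0.1
        st = _toy_study(2, nz=24)
        p1, _ = predict_dose(net, st.activity, st.density, st.dvk)

        def flip(v, q):  # axial flip of a volume
            return VoxelVolume(v.grid, v.values[:, :, ::-1].copy(), q)

        st_f = DoseStudy(
            activity=flip(st.activity, "activity_MBq"),
            density=flip(st.density, "density_g_per_cm3"),
            dvk=DoseRateMap(flip(st.dvk.volume, "dose_rate_nGy_per_s"), "DVK"),
        )
        p2, _ = predict_dose(net, st_f.activity, st_f.density, st_f.dvk)
        a = p1.volume.values[:, :, 8:16]
        b = p2.volume.values[:, :, ::-1][:, :, 8:16]
        assert np.abs(a - b).max() <= 1e-4 * (np.abs(a).max() + 1e-12)

    def test_provenance_guard(self):
        two = build_dose_net(TINY, seed=7, variant="two_stage")
        single = build_dose_net(TINY, seed=7, variant="single_stage")
        st = _toy_study(3)
        with pytest.raises(ValueError, match="no-SC"):
            predict_dose(single, st.activity, st.density, st.dvk, recon_tag="CNN_SC")
        with pytest.raises(ValueError, match="scatter-corrected"):
            predict_dose(two, st.activity, st.density, st.dvk, recon_tag="no_SC")

    def test_single_stage_untrained_equals_dvk_of_no_sc_recon(self):
        net = build_dose_net(TINY, seed=8, variant="single_stage")
        st = _toy_study(4)
        kernel = DoseKernel(np.ones((1, 1, 1)) * 1e3, (2.0, 2.0, 2.0), 1)
        out, _ = single_stage_variant(net, st.activity, st.density, kernel)
        expect = dvk_convolve(st.activity, kernel, st.density)
        assert np.allclose(out.volume.values, expect.volume.values)

    def test_checkpoint_round_trip_with_variant_tag(self, tmp_path):
        net = build_dose_net(TINY, seed=9, variant="single_stage")
        net.residual_scale = 123.0
        p = str(tmp_path / "d")
        save_dose_checkpoint(net, p)
        back = load_dose_checkpoint(p)
        assert back.variant == "single_stage"
        assert back.residual_scale == 123.0
        for p1, p2 in zip(net.params, back.params):
            assert np.array_equal(p1[0], p2[0])
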