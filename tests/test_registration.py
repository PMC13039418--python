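import numpy as np
import pytest
from skimage.draw import disk

import mplexquant as mq
from mplexquant.errors import EstimationError, ValidationError
from mplexquant.registration import (
    load_transform,
    normalize_decomposition,
    save_transform,
)
from mplexquant.synthetic import ClusterProfile


def texture_image(seed=0, shape=(512, 512), n_blobs=200):
    """Nuclei-like blob texture for registration tests."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    for _ in range(n_blobs):
        r = rng.integers(10, shape[0] - 10)
        c = rng.integers(10, shape[1] - 10)
        rad = rng.integers(3, 7)
        rr, cc = disk((r, c), rad, shape=shape)
        img[rr, cc] += rng.uniform(50, 100)
    return img


class TestRigidTransform:
    def test_inverse_composes_to_identity(self):
        t = mq.RigidTransform(theta_rad=0.3, ty_px=5.0, tx_px=-2.0, scale=1.2)
        pts = np.random.default_rng(0).uniform(0, 100, (50, 2))
        center = np.array([50.0, 50.0])
        back = t.inverse().apply_to_points(t.apply_to_points(pts, center), center)
        assert np.abs(back - pts).max() < 1e-9


class TestRescale:
    def test_same_target_is_identity(self):
        img = mq.MultiplexImage("r1", {"DAPI": texture_image()}, 0.65)
        assert mq.rescale_to_common_pixel_size(img, 0.65) is img

    def test_factor_two(self):
        img = mq.MultiplexImage("r1", {"DAPI": np.zeros((100, 100))}, 0.65)
        out = mq.rescale_to_common_pixel_size(img, 1.30)
        assert out.shape == (50, 50)
        assert out.pixel_size_um == 1.30

    def test_constant_stays_constant(self):
        img = mq.MultiplexImage("r1", {"DAPI": np.full((90, 90), 7.0)}, 0.65)
        out = mq.rescale_to_common_pixel_size(img, 1.0)
        np.testing.assert_allclose(out.channels["DAPI"], 7.0)


class TestEstimateRigid:
    def test_identity_recovery(self):
        img = texture_image(1)
        t = mq.estimate_rigid(img, img, downsample=4)
        assert abs(t.ty_px) < 0.5 and abs(t.tx_px) < 0.5
        assert abs(np.rad2deg(t.theta_rad)) < 0.2

    def test_pure_translation_recovery(self):
        from scipy import ndimage as ndi

        img = texture_image(2)
        # moving(y) = img(y + (12, -7)); the transform mapping moving onto
        # the fixed frame is then A(x) = x + (-12, 7)
        moving = ndi.shift(img, (-12.0, 7.0), order=1)
        t = mq.estimate_rigid(img, moving, downsample=4)
        assert abs(t.ty_px + 12.0) < 0.5
        assert abs(t.tx_px - 7.0) < 0.5
        assert abs(np.rad2deg(t.theta_rad)) < 0.5

    def test_rotation_plus_shift_recovery(self):
        cfg = mq.TissuePhantomConfig(
            image_size_px=(700, 700), n_cells=350, seed=6, islet_specs=[],
            islet_profiles=[], islet_base_intensity={},
            cluster_profiles=[ClusterProfile("u", 1.0, {"M": 3.0}, {"M": 0.5})],
            noise_sd=0.5,
        )
        rigid = mq.RigidTransform(theta_rad=np.deg2rad(5.0), ty_px=9.0, tx_px=-6.0)
        fixed, moving, _ = mq.generate_round_pair(cfg, rigid, 0.0)
        est = mq.estimate_rigid(fixed.nuclei, moving.nuclei, downsample=4)
        assert abs(est.ty_px - rigid.ty_px) < 0.5
        assert abs(est.tx_px - rigid.tx_px) < 0.5
        assert abs(np.rad2deg(est.theta_rad - rigid.theta_rad)) < 0.5

    def test_constant_image_rejected(self):
        with pytest.raises(EstimationError):
            mq.estimate_rigid(np.ones((64, 64)), np.ones((64, 64)))


class TestEstimateDeformation:
    def test_identity_recovery(self):
        img = texture_image(3, shape=(600, 600))
        grid = mq.estimate_deformation(img, img, step_px=200)
        assert grid.max_displacement < 0.5

    def test_blank_tile_inherits_neighbors(self):
        img = texture_image(4, shape=(600, 600))
        img[180:420, 180:420] = 0.0  # featureless center tile
        grid = mq.estimate_deformation(img, img.copy(), step_px=200)
        # no wild vector at the blank node: everything still near zero
        assert grid.max_displacement < 0.5

    def test_too_small_image_rejected(self):
        with pytest.raises(ValidationError):
            mq.estimate_deformation(np.zeros((50, 50)), np.zeros((50, 50)),
                                    step_px=100)
        with pytest.raises(ValidationError):
            mq.estimate_deformation(np.zeros((500, 500)), np.zeros((500, 500)),
                                    step_px=32)


class TestApplyTransform:
    def test_identity_is_pixel_identical(self):
        img = mq.MultiplexImage("r1", {"DAPI": texture_image(5)}, 0.65)
        out = mq.apply_transform(
            img, mq.RigidTransform(),
            mq.DeformationGrid.zero(img.shape, 200),
        )
        np.testing.assert_array_equal(out.channels["DAPI"],
                                      img.channels["DAPI"])

    def test_constant_interior_preserved(self):
        img = mq.MultiplexImage("r1", {"DAPI": np.full((300, 300), 9.0)}, 0.65)
        out = mq.apply_transform(
            img, mq.RigidTransform(theta_rad=np.deg2rad(2), ty_px=3, tx_px=-2)
        )
        np.testing.assert_allclose(out.channels["DAPI"][50:-50, 50:-50], 9.0)

    def test_blob_intensity_conserved_within_1pct(self):
        img = np.zeros((400, 400))
        rr, cc = disk((200, 200), 30, shape=img.shape)
        img[rr, cc] = 100.0
        mimg = mq.MultiplexImage("r1", {"DAPI": img}, 0.65)
        rigid = mq.RigidTransform(theta_rad=np.deg2rad(4), ty_px=11.0, tx_px=-8.0)
        out = mq.apply_transform(mimg, rigid)
        assert out.channels["DAPI"].sum() == pytest.approx(img.sum(), rel=0.01)

    def test_warp_then_estimate_closure(self):
        img = texture_image(6, shape=(650, 650))
        mimg = mq.MultiplexImage("r1", {"DAPI": img}, 0.65)
        rng = np.random.default_rng(7)
        grid = mq.DeformationGrid.zero(mimg.shape, 200)
        grid.displacements += rng.uniform(-3, 3, grid.displacements.shape)
        grid.displacements -= grid.displacements.reshape(-1, 2).mean(0)
        warped = mq.apply_transform(mimg, deformation=grid)
        # closure: the field aligning the original onto the warped copy is
        # the planted one (warped(x) = img(x + d(x)))
        est = mq.estimate_deformation(warped.channels["DAPI"], img, step_px=200)
        _, est = normalize_decomposition(mq.RigidTransform(), est)
        err = np.abs(est.displacements - grid.displacements)
        assert err[1:-1, 1:-1].max() < 1.0


class TestRegisterRounds:
    def test_empty_list(self):
        img = mq.MultiplexImage("r1", {"DAPI": texture_image(8)}, 0.65)
        aligned, transforms = mq.register_rounds(img, [])
        assert aligned == [] and transforms == []

    def test_self_registration_is_identity(self):
        img = mq.MultiplexImage("r1", {"DAPI": texture_image(9)}, 0.65)
        copy = mq.MultiplexImage("r2", {"DAPI": img.channels["DAPI"].copy()}, 0.65)
        aligned, [(rigid, grid)] = mq.register_rounds(img, [copy],
                                                      downsample=4, step_px=200)
        assert abs(rigid.ty_px) < 0.5 and abs(rigid.tx_px) < 0.5
        assert abs(np.rad2deg(rigid.theta_rad)) < 0.2
        assert grid.max_displacement < 0.5


class TestSerialization:
    def test_round_trip(self, tmp_path):
        rigid = mq.RigidTransform(theta_rad=0.05, ty_px=3.5, tx_px=-1.25)
        grid = mq.DeformationGrid.zero((600, 600), 200)
        grid.displacements += 1.5
        path = tmp_path / "t.yaml"
        save_transform(path, rigid, grid)
        rigid2, grid2 = load_transform(path)
        assert rigid2 == rigid
        np.testing.assert_allclose(grid2.displacements, grid.displacements)
        np.testing.assert_allclose(grid2.node_rows, grid.node_rows)
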