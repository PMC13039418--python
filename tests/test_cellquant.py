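import numpy as np
import pytest
from skimage.draw import disk

import mplexquant as mq
from mplexquant.errors import ConsistencyError, ValidationError

from conftest import brute_force_tessellation, random_nucleus_labels


class TestExpandCells:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            labels = random_nucleus_labels(rng)
            cells = mq.expand_cells(labels, 7)
            oracle = brute_force_tessellation(labels, 7)
            np.testing.assert_array_equal(cells, oracle)

    def test_isolated_disk_grows_to_euclidean_ball(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        rr, cc = disk((32, 32), 10, shape=labels.shape)
        labels[rr, cc] = 1
        cells = mq.expand_cells(labels, 7)
        # the cell is the 7-px Euclidean dilation of the rasterized disk:
        # it must contain the ball the raster is guaranteed to cover and
        # stay inside the ball of the outermost raster pixel radius + 7
        y, x = np.ogrid[:64, :64]
        d2 = (y - 32) ** 2 + (x - 32) ** 2
        r_out = np.sqrt(d2[labels == 1].max())  # outermost nucleus pixel
        outside = d2 > (r_out + 7.0) ** 2
        assert (cells[outside] == 0).all()
        # every pixel within 16 px of the center is ≤ 7 px from the raster
        assert (cells[d2 <= 16**2] == 1).all()
        assert cells[32, 32] == 1 and cells[32, 32 + 16] == 1
        assert cells[32, 32 + 25] == 0

    def test_midpoint_between_two_nuclei(self):
        labels = np.zeros((40, 60), dtype=np.int32)
        labels[20, 20] = 1  # single-pixel nuclei 10 px apart
        labels[20, 30] = 2
        cells = mq.expand_cells(labels, 7)
        # each cell extends at most 5 px toward the other
        assert cells[20, 25] == 1  # equidistant -> smaller label
        assert (cells[20, 21:25] == 1).all()
        assert (cells[20, 26:31] == 2).all()

    def test_monotone_in_expansion(self):
        rng = np.random.default_rng(12)
        labels = random_nucleus_labels(rng)
        prev = mq.expand_cells(labels, 0)
        for e in (2, 5, 8):
            cur = mq.expand_cells(labels, e)
            grown = prev > 0
            assert np.array_equal(cur[grown], prev[grown])
            prev = cur

    def test_zero_expansion_keeps_nuclei_and_negative_rejected(self):
        rng = np.random.default_rng(13)
        labels = random_nucleus_labels(rng)
        np.testing.assert_array_equal(mq.expand_cells(labels, 0), labels)
        with pytest.raises(ValidationError):
            mq.expand_cells(labels, -1)


class TestDetectNuclei:
    def test_blank_image_gives_zero_nuclei(self):
        assert mq.detect_nuclei(np.zeros((64, 64))).max() == 0
        assert mq.detect_nuclei(np.full((64, 64), 7.0)).max() == 0

    def test_well_separated_nuclei_recovered(self, noiseless_phantom):
        img, gt = noiseless_phantom
        found = mq.detect_nuclei(img.nuclei, smooth_sigma=1.0)
        n_true = int(gt.nucleus_labels.max())
        assert abs(int(found.max()) - n_true) <= 0.02 * n_true
        # centroids match the planted ones within 1 px
        from scipy import ndimage as ndi

        cents = np.array(ndi.center_of_mass(found > 0, found,
                                            range(1, found.max() + 1)))
        true = gt.cells[["centroid_row", "centroid_col"]].to_numpy()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(true).query(cents)
        assert np.median(d) < 1.0

    def test_touching_nuclei_split_by_watershed(self):
        img = np.zeros((60, 60))
        rr, cc = disk((30, 22), 8, shape=img.shape)
        img[rr, cc] = 100.0
        rr, cc = disk((30, 38), 8, shape=img.shape)
        img[rr, cc] = 100.0
        labels = mq.detect_nuclei(img, smooth_sigma=1.0, threshold=10.0)
        assert labels.max() == 2


class TestBackground:
    def test_constant_image_maps_to_itself_exactly(self):
        for c in (100.0, 0.1):
            img = np.full((90, 110), c)
            np.testing.assert_array_equal(mq.estimate_background(img), img)

    def test_sparse_dots_vanish(self):
        rng = np.random.default_rng(20)
        img = np.full((300, 300), 50.0)
        for _ in range(30):
            r, c = rng.integers(5, 295, 2)
            img[r : r + 3, c : c + 3] = 500.0
        bg = mq.estimate_background(img)
        interior = bg[30:-30, 30:-30]
        assert np.abs(interior - 50.0).max() <= 0.01 * 50.0

    def test_linear_ramp_preserved_interior(self):
        ramp = np.tile(np.linspace(10, 110, 200), (200, 1))
        bg = mq.estimate_background(ramp)
        interior = slice(40, -40)
        err = np.abs(bg[interior, interior] - ramp[interior, interior])
        assert err.max() < 0.05 * 100

    def test_validation(self):
        with pytest.raises(ValidationError):
            mq.estimate_background(np.zeros((5, 5)), downsize=10)
        with pytest.raises(ValidationError):
            mq.estimate_background(np.zeros((50, 50)), window_px=4)


class TestSubtractBackground:
    def test_clamped_subtraction(self):
        ch = np.array([[5.0, 1.0], [3.0, 3.0]])
        bg = np.array([[2.0, 2.0], [3.0, 4.0]])
        out = mq.subtract_background(ch, bg)
        np.testing.assert_array_equal(out, [[3.0, 0.0], [0.0, 0.0]])
        np.testing.assert_array_equal(mq.subtract_background(ch, ch),
                                      np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            mq.subtract_background(ch, np.zeros((3, 3)))


class TestExtractFeatures:
    def test_disk_morphology(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        rr, cc = disk((32, 32), 10, shape=labels.shape)
        labels[rr, cc] = 1
        img = mq.MultiplexImage("r1", {"DAPI": np.ones((64, 64))},
                                pixel_size_um=0.65)
        table = mq.extract_features(labels, labels, img)
        assert table["equivalent_radius_px"].iloc[0] == pytest.approx(10, rel=0.02)
        assert table["circularity"].iloc[0] >= 0.85
        assert table["aspect_ratio"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_noiseless_phantom_intensities_exact(self, noiseless_phantom):
        img, gt = noiseless_phantom
        table = mq.extract_features(gt.nucleus_labels, gt.cell_labels, img)
        merged = table.merge(gt.cells, on="cell_id")
        for marker in ("P53", "53BP1", "HMGB1"):  # nuclear markers
            err = np.abs(merged[f"{marker}_nuc_mean"] - merged[f"{marker}_true"])
            assert err.max() < 1e-9
        for marker in ("P16", "Insulin"):  # cytosolic: annulus carries the value
            ann_total = merged[f"{marker}_cell_total"] - merged[f"{marker}_nuc_total"]
            ann_n = merged["cell_area_px"] - merged["nucleus_area_px"]
            err = np.abs(ann_total / ann_n - merged[f"{marker}_true"])
            assert err.max() < 1e-9

    def test_total_equals_mean_times_area(self, small_phantom):
        img, gt = small_phantom
        table = mq.extract_features(gt.nucleus_labels, gt.cell_labels, img)
        for marker in img.channel_names:
            np.testing.assert_allclose(
                table[f"{marker}_cell_total"],
                table[f"{marker}_cell_mean"] * table["cell_area_px"],
                rtol=1e-9,
            )

    def test_cell_regions_disjoint_and_bounded(self, small_phantom):
        img, gt = small_phantom
        areas = np.bincount(gt.cell_labels.ravel())[1:]
        assert areas.sum() <= gt.cell_labels.size
        inside = gt.nucleus_labels > 0
        assert np.array_equal(gt.cell_labels[inside], gt.nucleus_labels[inside])

    def test_inconsistent_maps_rejected(self, noiseless_phantom):
        img, gt = noiseless_phantom
        bad = gt.cell_labels.copy()
        bad[bad == 0] = bad.max() + 5  # label with no nucleus
        with pytest.raises(ConsistencyError):
            mq.extract_features(gt.nucleus_labels, bad, img)
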