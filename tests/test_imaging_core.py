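import numpy as np
import pytest

from adiposcope.errors import ConvergenceError, ShapeError, ValidationError
from adiposcope.imaging_core import (
    BinaryMask,
    ChannelStack,
    PolygonROI,
    RasterImage,
    RGBImage,
    downsample_bin,
    hsb_to_rgb,
    intermodes_threshold,
    load_raster_tiff,
    load_rgb_tiff,
    load_roi,
    load_stack_tiff,
    rasterize_roi,
    rgb_to_hsb,
    save_mask_tiff,
    save_raster_tiff,
    save_rgb_tiff,
    save_roi,
    save_stack_tiff,
    split_mosaic,
    threshold_mask,
    tile_mosaic,
    zmax_project,
)
from conftest import make_raster, rgb_from_pixel


class TestTypes:
    def test_raster_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            RasterImage(np.full((2, 2), 300.0))
        with pytest.raises(ValidationError):
            RasterImage(np.full((2, 2), -1.0))

    def test_raster_rejects_bad_pixel_size(self):
        with pytest.raises(ValidationError):
            RasterImage(np.zeros((2, 2)), pixel_size_um=0.0)

    def test_rgb_rejects_mismatched_planes(self):
        with pytest.raises(ShapeError):
            RGBImage(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))

    def test_stack_rejects_empty_and_ragged(self):
        with pytest.raises(ValidationError):
            ChannelStack(())
        with pytest.raises(ShapeError):
            ChannelStack((make_raster(np.zeros((2, 2))), make_raster(np.zeros((3, 2)))))

    def test_polygon_needs_three_vertices_and_area(self):
        with pytest.raises(ValidationError):
            PolygonROI(np.array([[0, 0], [1, 1]]))
        with pytest.raises(ValidationError):
            PolygonROI(np.array([[0, 0], [1, 1], [2, 2]]))  # collinear

    def test_mask_area(self):
        m = BinaryMask(np.eye(4, dtype=bool))
        assert m.area_px == 4


class TestRgbToHsb:
    def test_pure_red(self):
        h = rgb_to_hsb(rgb_from_pixel((255, 0, 0)))
        assert h.hue[0, 0] == 0.0
        assert h.brightness[0, 0] == 255.0

    def test_pure_green(self):
        h = rgb_to_hsb(rgb_from_pixel((0, 255, 0)))
        assert h.hue[0, 0] == pytest.approx(85.0)  # 120 deg * 255/360
        assert h.brightness[0, 0] == 255.0

    def test_gray_is_achromatic(self):
        h = rgb_to_hsb(rgb_from_pixel((128, 128, 128)))
        assert h.saturation[0, 0] == 0.0
        assert h.brightness[0, 0] == 128.0
        assert h.hue[0, 0] == 0.0

    def test_round_trip_random_colors(self, rng):
        rgb = rng.uniform(0, 255, size=(16, 16, 3))
        img = RGBImage(rgb[..., 0], rgb[..., 1], rgb[..., 2])
        h = rgb_to_hsb(img)
        back = hsb_to_rgb(h.hue, h.saturation, h.brightness)
        np.testing.assert_allclose(back, rgb, atol=1e-9)


class TestZmaxProject:
    def test_single_slice_identity(self):
        img = make_raster([[1.0, 2.0], [3.0, 4.0]])
        out = zmax_project(ChannelStack((img,)))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_constant_slices(self):
        slices = tuple(make_raster(np.full((3, 3), v)) for v in (10.0, 50.0, 30.0))
        out = zmax_project(ChannelStack(slices))
        np.testing.assert_array_equal(out.pixels, np.full((3, 3), 50.0))

    def test_matches_brute_force(self, rng):
        arrs = [rng.uniform(0, 255, (8, 8)) for _ in range(3)]
        stack = ChannelStack(tuple(make_raster(a) for a in arrs))
        out = zmax_project(stack)
        expected = np.empty((8, 8))
        for i in range(8):
            for j in range(8):
                expected[i, j] = max(a[i, j] for a in arrs)
        np.testing.assert_array_equal(out.pixels, expected)

    def test_dominates_every_slice(self, rng):
        arrs = [rng.uniform(0, 255, (6, 6)) for _ in range(4)]
        out = zmax_project(ChannelStack(tuple(make_raster(a) for a in arrs)))
        for a in arrs:
            assert np.all(out.pixels >= a)


class TestTileMosaic:
    def test_single_tile_identity(self):
        t = make_raster([[1.0, 2.0]])
        out = tile_mosaic([[t]])
        np.testing.assert_array_equal(out.pixels, t.pixels)

    def test_quadrants(self):
        tiles = [
            [make_raster(np.full((2, 2), 10.0)), make_raster(np.full((2, 2), 20.0))],
            [make_raster(np.full((2, 2), 30.0)), make_raster(np.full((2, 2), 40.0))],
        ]
        out = tile_mosaic(tiles)
        assert out.shape == (4, 4)
        assert out.pixels[0, 0] == 10.0
        assert out.pixels[0, 3] == 20.0
        assert out.pixels[3, 0] == 30.0
        assert out.pixels[3, 3] == 40.0

    def test_round_trip(self, rng):
        tiles = [
            [make_raster(rng.uniform(0, 255, (3, 5))) for _ in range(4)]
            for _ in range(2)
        ]
        mosaic = tile_mosaic(tiles)
        back = split_mosaic(mosaic, 2, 4)
        for i in range(2):
            for j in range(4):
                np.testing.assert_array_equal(back[i][j].pixels, tiles[i][j].pixels)

    def test_ragged_rejected(self):
        t = make_raster(np.zeros((2, 2)))
        with pytest.raises(ShapeError):
            tile_mosaic([[t, t], [t]])
        with pytest.raises(ShapeError):
            tile_mosaic([[t, make_raster(np.zeros((2, 3)))]])


class TestDownsampleBin:
    def test_identity_at_source_width(self):
        img = make_raster(np.arange(16, dtype=float).reshape(4, 4))
        out = downsample_bin(img, 4)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_constant_block(self):
        img = make_raster(np.full((4, 4), 42.0))
        out = downsample_bin(img, 2)
        assert out.shape == (2, 2)
        np.testing.assert_allclose(out.pixels, 42.0)

    def test_checkerboard_block_mean(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 255.0
        out = downsample_bin(make_raster(board), 2)
        np.testing.assert_allclose(out.pixels, 127.5)

    def test_mean_conserved_exactly(self, rng):
        arr = rng.uniform(0, 255, (12, 8))
        out = downsample_bin(make_raster(arr), 4)
        assert out.pixels.mean() == pytest.approx(arr.mean(), abs=1e-10)

    def test_aspect_ratio_and_pixel_size(self):
        img = make_raster(np.zeros((20, 10)), pixel_size_um=2.0)
        out = downsample_bin(img, 5)
        assert out.shape == (10, 5)
        assert out.pixel_size_um == pytest.approx(4.0)

    def test_target_larger_than_source_rejected(self):
        with pytest.raises(ValidationError):
            downsample_bin(make_raster(np.zeros((4, 4))), 5)


class TestRasterizeRoi:
    def test_axis_aligned_square(self):
        roi = PolygonROI(np.array([[0, 0], [0, 10], [10, 10], [10, 0]], dtype=float))
        mask = rasterize_roi(roi, (20, 20))
        assert mask.area_px == 100
        assert mask.data[:10, :10].all()

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            PolygonROI(np.array([[0, 0], [5, 5], [10, 10]], dtype=float))

    def test_random_polygon_area_matches_shoelace(self, rng):
        # random convex polygons >= 50x50 px: raster area within 2% of shoelace
        for _ in range(5):
            pts = rng.uniform(10, 180, size=(12, 2))
            center = pts.mean(axis=0)
            order = np.argsort(np.arctan2(*(pts - center).T))
            roi = PolygonROI(pts[order])
            span = np.ptp(pts[order][:, 0])
            if span < 50:
                continue
            mask = rasterize_roi(roi, (200, 200))
            assert mask.area_px == pytest.approx(roi.area, rel=0.02)

    def test_clipped_to_grid(self):
        roi = PolygonROI(np.array([[-5, -5], [-5, 5], [5, 5], [5, -5]], dtype=float))
        mask = rasterize_roi(roi, (10, 10))
        assert mask.area_px == 25  # only the in-grid quadrant


class TestThresholdMask:
    def test_full_range_selects_all(self, rng):
        img = make_raster(rng.uniform(0, 255, (8, 8)))
        assert threshold_mask(img, 0, 255).area_px == 64

    def test_constant_34_below_gate(self):
        img = make_raster(np.full((5, 5), 34.0))
        assert threshold_mask(img, 35, 255).area_px == 0

    def test_boundary_inclusive(self):
        img = make_raster(np.full((2, 2), 35.0))
        assert threshold_mask(img, 35, 255).area_px == 4
        assert threshold_mask(img, 0, 35).area_px == 4

    def test_invalid_interval(self):
        img = make_raster(np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            threshold_mask(img, 200, 100)

    def test_disjoint_ranges_give_disjoint_masks(self, rng):
        img = make_raster(rng.uniform(0, 255, (16, 16)))
        a = threshold_mask(img, 0, 100)
        b = threshold_mask(img, 101, 255)
        assert not np.any(a.data & b.data)


class TestIntermodes:
    def test_delta_spikes(self):
        hist = np.zeros(256)
        hist[10] = 5
        hist[200] = 3
        assert intermodes_threshold(hist) == 105

    def test_symmetric_equal_modes(self):
        x = np.arange(256)
        hist = np.exp(-((x - 50) ** 2) / 50.0) + np.exp(-((x - 150) ** 2) / 50.0)
        assert intermodes_threshold(hist) == 100

    def test_unimodal_raises(self):
        hist = np.zeros(256)
        hist[100] = 10
        with pytest.raises(ConvergenceError):
            intermodes_threshold(hist)
        x = np.arange(256)
        with pytest.raises(ConvergenceError):
            intermodes_threshold(np.exp(-((x - 128.0) ** 2) / 200.0))

    def test_sampled_bimodal_between_modes(self, rng):
        for _ in range(10):
            w = rng.uniform(0.3, 0.7)
            samples = np.concatenate(
                [
                    rng.normal(30, 10, int(5000 * w)),
                    rng.normal(180, 10, int(5000 * (1 - w))),
                ]
            )
            hist, _ = np.histogram(np.clip(samples, 0, 255), bins=256, range=(0, 256))
            thr = intermodes_threshold(hist.astype(float))
            assert 30 < thr < 180

    def test_accepts_image_input(self, rng):
        arr = np.where(rng.random((64, 64)) < 0.5, 40.0, 200.0)
        thr = intermodes_threshold(make_raster(arr))
        assert 40 < thr < 200

    def test_rejects_bad_histogram(self):
        with pytest.raises(ValidationError):
            intermodes_threshold(np.zeros(100))


class TestIO:
    def test_raster_tiff_round_trip(self, tmp_path, rng):
        img = make_raster(np.round(rng.uniform(0, 255, (6, 7))))
        save_raster_tiff(img, tmp_path / "x.tif")
        back = load_raster_tiff(tmp_path / "x.tif")
        np.testing.assert_array_equal(back.pixels, img.pixels)

    def test_rgb_tiff_round_trip(self, tmp_path, rng):
        arr = np.round(rng.uniform(0, 255, (4, 5, 3)))
        img = RGBImage.from_array(arr)
        save_rgb_tiff(img, tmp_path / "x.tif")
        back = load_rgb_tiff(tmp_path / "x.tif")
        np.testing.assert_array_equal(back.to_array(), arr)

    def test_stack_tiff_round_trip(self, tmp_path, rng):
        stack = ChannelStack(
            tuple(make_raster(np.round(rng.uniform(0, 255, (4, 4)))) for _ in range(3))
        )
        save_stack_tiff(stack, tmp_path / "s.tif")
        back = load_stack_tiff(tmp_path / "s.tif")
        np.testing.assert_array_equal(back.to_array(), stack.to_array())

    def test_16bit_rescaled(self, tmp_path):
        import tifffile

        arr = np.full((3, 3), 65535, dtype=np.uint16)
        tifffile.imwrite(tmp_path / "deep.tif", arr)
        img = load_raster_tiff(tmp_path / "deep.tif")
        np.testing.assert_allclose(img.pixels, 255.0)

    def test_mask_tiff(self, tmp_path):
        import tifffile

        m = BinaryMask(np.eye(3, dtype=bool))
        save_mask_tiff(m, tmp_path / "m.tif")
        arr = tifffile.imread(tmp_path / "m.tif")
        assert set(np.unique(arr)) == {0, 255}

    @pytest.mark.parametrize("suffix", [".csv", ".json"])
    def test_roi_round_trip(self, tmp_path, suffix):
        roi = PolygonROI(np.array([[0, 0], [0, 10], [10, 5]], dtype=float))
        path = tmp_path / f"roi{suffix}"
        save_roi(roi, path)
        back = load_roi(path)
        np.testing.assert_allclose(back.vertices, roi.vertices)
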