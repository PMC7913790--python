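"""Stack loading round trips, frame selection, subtraction, masks."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from iffmap import image_io
from iffmap.synthetic import gaussian_blob
from iffmap.types import ConcentrationStack, RegionMask, RoiPolygon


@pytest.fixture()
def small_stack():
    rng = np.random.default_rng(0)
    frames = np.stack([gaussian_blob((16, 16), sigma=3.0) * (1 + 0.1 * k) for k in range(8)])
    frames += rng.uniform(0, 0.01, frames.shape)
    return ConcentrationStack(
        frames=frames,
        frame_times=np.arange(8) * 2.5,
        pixel_spacing=0.8,
        pre_contrast_count=1,
    )


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


class TestLoadStack:
    def test_npz_round_trip_bit_exact(self, small_stack, tmp_path):
        path = image_io.save_stack_npz(small_stack, tmp_path / "stack.npz")
        loaded = image_io.load_stack(path)
        np.testing.assert_array_equal(loaded.frames, small_stack.frames)
        np.testing.assert_array_equal(loaded.frame_times, small_stack.frame_times)
        assert loaded.pixel_spacing == small_stack.pixel_spacing
        assert loaded.pre_contrast_count == 1

    def test_nifti_round_trip(self, small_stack, tmp_path):
        path = image_io.save_stack_nifti(small_stack, tmp_path / "stack.nii")
        loaded = image_io.load_stack(path)
        np.testing.assert_allclose(loaded.frames, small_stack.frames, rtol=0, atol=1e-12)
        np.testing.assert_array_equal(loaded.frame_times, small_stack.frame_times)

    def test_nifti_time_subset_selection(self, small_stack, tmp_path):
        path = image_io.save_stack_nifti(small_stack, tmp_path / "stack.nii")
        loaded = image_io.load_stack(path, time_indices=[0, 2, 4, 6])
        assert loaded.n_frames == 4
        np.testing.assert_array_equal(loaded.frame_times, small_stack.frame_times[[0, 2, 4, 6]])
        np.testing.assert_allclose(loaded.frames, small_stack.frames[[0, 2, 4, 6]], atol=1e-12)

    def test_missing_sidecar_is_an_error(self, small_stack, tmp_path):
        path = image_io.save_stack_npz(small_stack, tmp_path / "stack.npz")
        path.with_name("stack.json").unlink()
        with pytest.raises(FileNotFoundError, match="timing"):
            image_io.load_stack(path)

    def test_dicom_round_trip_to_quantization(self, small_stack, tmp_path):
        d = image_io.save_stack_dicom(small_stack, tmp_path / "series")
        loaded = image_io.load_stack(d, pre_contrast_count=1)
        span = small_stack.frames.max() - small_stack.frames.min()
        np.testing.assert_allclose(loaded.frames, small_stack.frames, atol=span / 65535 + 1e-12)
        np.testing.assert_allclose(loaded.frame_times, small_stack.frame_times, atol=1e-5)
        assert loaded.pixel_spacing == pytest.approx(0.8)

    def test_dicom_frames_shuffled_on_disk_reordered_by_time(self, small_stack, tmp_path):
        d = image_io.save_stack_dicom(small_stack, tmp_path / "series")
        # scramble the filename order so name order != time order
        files = sorted(d.glob("*.dcm"))
        for i, f in enumerate(files):
            f.rename(d / f"z_{(len(files) - i):02d}.dcm")
        loaded = image_io.load_stack(d)
        assert np.all(np.diff(loaded.frame_times) > 0)
        span = small_stack.frames.max() - small_stack.frames.min()
        np.testing.assert_allclose(loaded.frames, small_stack.frames, atol=span / 65535 + 1e-12)

    def test_fewer_than_four_frames_rejected(self, small_stack, tmp_path):
        path = image_io.save_stack_npz(small_stack, tmp_path / "stack.npz")
        with pytest.raises(ValueError, match="4 frames"):
            image_io.load_stack(path, time_indices=[0, 1, 2])


# ---------------------------------------------------------------------------
# frame selection
# ---------------------------------------------------------------------------


class TestSelectSpanningFrames:
    @pytest.mark.parametrize(
        "n_available,n_select,pre,expected",
        [
            (1200, 4, 1, [0, 1, 600, 1199]),
            (4, 4, 1, [0, 1, 2, 3]),
            (5, 4, 1, [0, 1, 3, 4]),  # linspace(1, 4, 3) rounds 2.5 up
            (1200, 5, 1, [0, 1, 400, 800, 1199]),
        ],
    )
    def test_selection_rule(self, n_available, n_select, pre, expected):
        assert image_io.select_spanning_frames(n_available, n_select, pre) == expected

    def test_first_frame_is_pre_and_last_is_final(self):
        idx = image_io.select_spanning_frames(977, 6, 3)
        assert idx[0] == 0
        assert idx[1] == 3  # first post frame
        assert idx[-1] == 976
        assert np.all(np.diff(idx) > 0)

    def test_too_many_requested(self):
        with pytest.raises(ValueError, match="cannot select"):
            image_io.select_spanning_frames(4, 5, 1)


class TestSubtractBackground:
    def _stack(self, frames, pre):
        frames = np.asarray(frames, dtype=float)
        return ConcentrationStack(
            frames=frames,
            frame_times=np.arange(len(frames), dtype=float),
            pixel_spacing=1.0,
            pre_contrast_count=pre,
        )

    def test_constant_subtraction(self):
        st = self._stack([np.full((4, 4), 5.0), np.full((4, 4), 7.0)], pre=1)
        out = image_io.subtract_background(st)
        np.testing.assert_array_equal(out.frames[0], np.full((4, 4), 2.0))
        assert out.pre_contrast_count == 0
        assert out.n_frames == 1

    def test_negative_clamped_to_zero(self):
        st = self._stack([np.full((4, 4), 5.0), np.full((4, 4), 3.0)], pre=1)
        out = image_io.subtract_background(st)
        np.testing.assert_array_equal(out.frames[0], np.zeros((4, 4)))

    def test_mean_of_multiple_pre_frames(self):
        st = self._stack(
            [np.full((4, 4), 4.0), np.full((4, 4), 6.0), np.full((4, 4), 10.0)], pre=2
        )
        out = image_io.subtract_background(st)
        np.testing.assert_array_equal(out.frames[0], np.full((4, 4), 5.0))

    def test_no_pre_frame_is_an_error(self):
        st = self._stack([np.ones((4, 4))] * 3, pre=0)
        with pytest.raises(ValueError, match="pre-contrast"):
            image_io.subtract_background(st)

    def test_idempotent_with_zero_pre_frame(self):
        """Re-subtracting with an all-zero pre frame changes nothing."""
        st = self._stack([np.zeros((4, 4)), np.full((4, 4), 2.0), np.full((4, 4), 3.0)], pre=1)
        out = image_io.subtract_background(st)
        again = ConcentrationStack(
            frames=np.concatenate([np.zeros((1, 4, 4)), out.frames]),
            frame_times=np.concatenate([[out.frame_times[0] - 1], out.frame_times]),
            pixel_spacing=1.0,
            pre_contrast_count=1,
        )
        out2 = image_io.subtract_background(again)
        np.testing.assert_array_equal(out2.frames, out.frames)


# ---------------------------------------------------------------------------
# polygons and masks
# ---------------------------------------------------------------------------


def _point_in_polygon_evenodd(px, py, verts):
    """Independent scalar even-odd oracle with the same half-open convention."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue
        if (y1 <= py) != (y2 <= py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def _oracle_mask(verts, grid_shape):
    ny, nx = grid_shape
    return np.array(
        [[_point_in_polygon_evenodd(x, y, verts) for x in range(nx)] for y in range(ny)]
    )


class TestRasterizePolygon:
    def test_axis_aligned_square_covers_nine_centers(self):
        poly = RoiPolygon([(0.5, 0.5), (3.5, 0.5), (3.5, 3.5), (0.5, 3.5)])
        mask = image_io.rasterize_polygon(poly, (8, 8))
        assert mask.pixel_count == 9
        assert mask.mask[1:4, 1:4].all()

    def test_triangle_matches_brute_force_oracle(self):
        verts = [(0.0, 0.0), (4.0, 0.0), (0.0, 4.0)]
        mask = image_io.rasterize_polygon(RoiPolygon(verts), (8, 8))
        np.testing.assert_array_equal(mask.mask, _oracle_mask(verts, (8, 8)))

    def test_full_cover_polygon(self):
        poly = RoiPolygon([(-1.0, -1.0), (8.0, -1.0), (8.0, 8.0), (-1.0, 8.0)])
        mask = image_io.rasterize_polygon(poly, (8, 8))
        assert mask.pixel_count == 64

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate or self-intersecting"):
            image_io.rasterize_polygon(
                RoiPolygon([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]), (8, 8)
            )

    def test_self_intersecting_polygon_rejected(self):
        bowtie = RoiPolygon([(0.0, 0.0), (4.0, 4.0), (4.0, 0.0), (0.0, 4.0)])
        with pytest.raises(ValueError, match="degenerate or self-intersecting"):
            image_io.rasterize_polygon(bowtie, (8, 8))

    @given(
        st.lists(
            st.tuples(
                st.floats(0.2, 30.8).map(lambda v: round(v, 2)),
                st.floats(0.2, 30.8).map(lambda v: round(v, 2)),
            ),
            min_size=4,
            max_size=9,
            unique=True,
        )
    )
    def test_random_convex_polygons_match_oracle(self, points):
        """Convex hulls of random point sets rasterize identically to the oracle."""
        from shapely.geometry import MultiPoint

        hull = MultiPoint(points).convex_hull
        if hull.geom_type != "Polygon" or hull.area < 0.5:
            return
        verts = list(hull.exterior.coords)[:-1]
        mask = image_io.rasterize_polygon(RoiPolygon(verts), (32, 32))
        np.testing.assert_array_equal(mask.mask, _oracle_mask(verts, (32, 32)))

    def test_roi_json_round_trip(self, tmp_path):
        poly = RoiPolygon([(1.0, 2.0), (5.0, 2.5), (3.0, 6.0)], label="tumor")
        path = image_io.save_roi_json(poly, tmp_path / "roi.json")
        loaded = image_io.load_roi_json(path)
        np.testing.assert_array_equal(loaded.vertices, poly.vertices)
        assert loaded.label == "tumor"


class TestParenchymaRing:
    def test_single_pixel_tumor_radius_one_gives_four_neighbours(self):
        tumor = np.zeros((7, 7), dtype=bool)
        tumor[3, 3] = True
        ring = image_io.make_parenchyma_ring(RegionMask(tumor, "tumor"), 1.0, 1.0)
        assert ring.pixel_count == 4
        assert ring.mask[2, 3] and ring.mask[4, 3] and ring.mask[3, 2] and ring.mask[3, 4]

    def test_tumor_at_border_ring_clipped(self):
        tumor = np.zeros((6, 6), dtype=bool)
        tumor[0, 0] = True
        ring = image_io.make_parenchyma_ring(RegionMask(tumor, "tumor"), 1.0, 1.0)
        assert ring.grid_shape == (6, 6)
        assert ring.pixel_count == 2  # (0,1) and (1,0); the rest is out of bounds

    def test_zero_radius_after_rounding_is_an_error(self):
        tumor = RegionMask(np.ones((5, 5), dtype=bool), "tumor")
        with pytest.raises(ValueError, match="zero-pixel"):
            image_io.make_parenchyma_ring(tumor, 0.4, 1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_ring_always_disjoint_from_tumor(self, seed):
        rng = np.random.default_rng(seed)
        tumor = rng.random((32, 32)) < 0.15
        if not tumor.any():
            return
        ring = image_io.make_parenchyma_ring(RegionMask(tumor, "tumor"), 2.0, 1.0)
        assert not np.any(ring.mask & tumor)

    def test_mask_exports(self, tmp_path):
        mask = RegionMask(np.eye(5, dtype=bool), "tumor")
        png = image_io.mask_to_png(mask, tmp_path / "m.png")
        csv = image_io.mask_to_rle_csv(mask, tmp_path / "m.csv")
        assert png.exists()
        text = csv.read_text().splitlines()
        assert text[0] == "row,start_col,length"
        assert len(text) == 6  # one run per row
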