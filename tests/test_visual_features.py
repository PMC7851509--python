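import numpy as np
import pandas as pd
import pytest

from traminer.io_events import SensorMap
from traminer.visual_features import (
    SPEED_COLORS,
    find_intersections,
    flatten_binarize,
    make_layout_transform,
    render_gvfe_image,
    render_speed_image,
    render_traj_image,
    speed_bin,
)

from conftest import make_trajectory


def square_map(xmax=10.0, ymax=13.0):
    df = pd.DataFrame(
        {
            "x": [0.0, xmax, 0.0, xmax],
            "y": [0.0, 0.0, ymax, ymax],
            "kind": "motion",
            "ordinal": [1, 2, 3, 4],
        },
        index=pd.Index(["A", "B", "C", "D"], name="s_id"),
    )
    return SensorMap(df)


class TestLayoutTransform:
    def test_uniform_scale_for_matching_aspect(self):
        lt = make_layout_transform(square_map(), margin=0.0)
        assert lt.scale == pytest.approx(10.0)  # 10 px per meter

    def test_pixel_center_round_trip(self):
        lt = make_layout_transform(square_map(), margin=0.5)
        cols = np.array([0, 13, 99])
        rows = np.array([0, 77, 129])
        x, y = lt.to_meters(cols, rows)
        c2, r2 = lt.to_pixel(x, y)
        np.testing.assert_array_equal(c2, cols)
        np.testing.assert_array_equal(r2, rows)

    def test_margin_keeps_sensors_off_the_edge(self):
        margin = 0.5
        lt = make_layout_transform(square_map(), margin=margin)
        # hand-computed affine: padded box 11 x 14 m, scale = min(100/11, 130/14)
        assert lt.scale == pytest.approx(min(100 / 11, 130 / 14))
        for x, y in [(0, 0), (10, 13)]:
            u = (x - lt.x0) * lt.scale
            v = (y - lt.y0) * lt.scale
            pad = margin * lt.scale
            assert pad - 1e-9 <= u <= lt.width - pad + 1e-9
            assert pad - 1e-9 <= v <= lt.height - pad + 1e-9

    def test_degenerate_box_rejected(self):
        df = pd.DataFrame(
            {"x": [1.0, 1.0], "y": [2.0, 5.0], "kind": "motion", "ordinal": [1, 2]},
            index=pd.Index(["A", "B"], name="s_id"),
        )
        with pytest.raises(ValueError, match="degenerate"):
            make_layout_transform(SensorMap(df), margin=0.0)


class TestIntersections:
    def test_single_segment_cannot_cross(self):
        traj = make_trajectory([0, 1], [(0, 0), (2, 2)])
        assert find_intersections(traj) == []

    def test_zigzag_crossing_found(self):
        traj = make_trajectory([0, 1, 2, 3], [(0, 0), (2, 2), (2, 0), (0, 2)])
        pts = find_intersections(traj)
        assert len(pts) == 1
        assert pts[0] == pytest.approx((1.0, 1.0))

    def test_shared_endpoint_of_consecutive_segments_excluded(self):
        traj = make_trajectory([0, 1, 2], [(0, 0), (3, 0), (3, 4)])
        assert find_intersections(traj) == []

    def test_collinear_rewalk_contributes_no_points(self):
        traj = make_trajectory([0, 1, 2, 3], [(0, 0), (2, 0), (0, 0), (2, 0)])
        assert find_intersections(traj) == []


class TestTrajImage:
    def setup_method(self):
        self.lt = make_layout_transform(square_map(), margin=0.5)

    def test_single_pass_draws_thin_white_line(self):
        traj = make_trajectory([0, 5], [(2, 6), (6, 6)])
        img = render_traj_image(traj, self.lt)
        white = (img == 255).all(axis=2)
        red = (img[..., 0] == 255) & (img[..., 1] == 0)
        assert white.sum() > 0
        assert red.sum() == 0
        # 1 px stroke: each touched column has exactly one white row
        cols = np.flatnonzero(white.any(axis=0))
        assert all(white[:, c].sum() == 1 for c in cols)

    def test_pacing_thickens_edge_to_traversal_count(self):
        traj = make_trajectory([0, 4, 8, 12], [(2, 6), (6, 6), (2, 6), (6, 6)])
        img = render_traj_image(traj, self.lt)
        white = (img == 255).all(axis=2)
        cols = np.flatnonzero(white.any(axis=0))
        mid = cols[len(cols) // 2]
        assert white[:, mid].sum() == 3  # walked 3 times -> 3 px stroke

    def test_stroke_width_monotone_in_traversals_and_capped(self):
        widths = []
        for n_walks in (1, 2, 3, 5, 7, 9):
            pts, times = [], []
            for k in range(n_walks + 1):
                pts.append((2, 6) if k % 2 == 0 else (6, 6))
                times.append(4.0 * k)
            img = render_traj_image(make_trajectory(times, pts), self.lt)
            white = (img == 255).all(axis=2)
            mid = np.flatnonzero(white.any(axis=0))
            mid = mid[len(mid) // 2]
            widths.append(int(white[:, mid].sum()))
        assert widths == sorted(widths)  # never thins with more traversals
        assert max(widths) <= 7  # cap

    def test_crossing_marked_with_red_circle_at_transformed_point(self):
        traj = make_trajectory([0, 1, 2, 3], [(0, 0), (2, 2), (2, 0), (0, 2)])
        img = render_traj_image(traj, self.lt)
        red = (img[..., 0] == 255) & (img[..., 1] == 0) & (img[..., 2] == 0)
        assert red.sum() >= 1
        rows, cols = np.nonzero(red)
        c_exp, r_exp = self.lt.to_pixel(1.0, 1.0)
        assert abs(cols.mean() - c_exp) <= 1.0
        assert abs(rows.mean() - r_exp) <= 1.0

    def test_out_of_extent_trajectory_rejected(self):
        traj = make_trajectory([0, 1], [(0, 0), (500, 500)])
        with pytest.raises(ValueError, match="outside"):
            render_traj_image(traj, self.lt)

    def test_rendering_is_deterministic(self):
        traj = make_trajectory([0, 1, 2, 3], [(0, 0), (2, 2), (2, 0), (0, 2)])
        a = render_traj_image(traj, self.lt)
        b = render_traj_image(traj, self.lt)
        assert (a == b).all()


class TestSpeedBin:
    @pytest.mark.parametrize(
        "v,expected_bin",
        [(0, 1), (1.9, 1), (3, 2), (5, 3), (7, 4), (9, 5), (11, 6), (13, 7), (14.5, 7), (16, 8)],
    )
    def test_bin_assignment(self, v, expected_bin):
        idx, color = speed_bin(v)
        assert idx == expected_bin
        assert color == SPEED_COLORS[expected_bin - 1]

    def test_violet_for_two_to_four(self):
        assert speed_bin(3)[1] == (238, 130, 238)

    def test_red_above_fifteen(self):
        assert speed_bin(16)[1] == (255, 0, 0)

    def test_invalid_speed_rejected(self):
        with pytest.raises(ValueError):
            speed_bin(-1)
        with pytest.raises(ValueError):
            speed_bin(float("nan"))


class TestSpeedImage:
    def setup_method(self):
        self.lt = make_layout_transform(square_map(), margin=0.5)

    def _colors(self, img):
        pix = img.reshape(-1, 3)
        drawn = pix[(pix != 0).any(axis=1)]
        return {tuple(c) for c in drawn}

    def test_uniform_walk_is_all_purple(self):
        traj = make_trajectory([0, 2, 4], [(2, 6), (4, 6), (6, 6)])  # 1 m/s
        assert self._colors(render_speed_image(traj, self.lt)) == {(128, 0, 128)}

    def test_most_recent_speed_wins_on_rewalk(self):
        # 1 m/s out, 3 m/s back over the same section
        traj = make_trajectory([0, 4, 4 + 4 / 3], [(2, 6), (6, 6), (2, 6)])
        assert self._colors(render_speed_image(traj, self.lt)) == {(238, 130, 238)}

    def test_two_sections_two_colors(self):
        traj = make_trajectory([0, 4, 4.8], [(2, 6), (6, 6), (6, 10)])  # 1 then 5 m/s
        assert self._colors(render_speed_image(traj, self.lt)) == {
            (128, 0, 128),
            (0, 0, 255),
        }

    def test_zero_dt_rejected(self):
        traj = make_trajectory([0, 0], [(2, 6), (6, 6)])
        with pytest.raises(ValueError):
            render_speed_image(traj, self.lt)


class TestGvfeImage:
    def test_worked_sensor_sequence(self):
        img = render_gvfe_image([5, 3, 5, 10, 11, 1], n_sensors=67, width=32)
        assert img.shape == (67, 32)
        expected = {(1, 5), (2, 3), (3, 5), (4, 10), (5, 11), (6, 1)}
        got = {(k + 1, s + 1) for s, k in zip(*np.nonzero(img))}
        assert got == expected

    def test_empty_sequence_is_blank(self):
        assert render_gvfe_image([], n_sensors=67, width=14).sum() == 0

    @pytest.mark.parametrize("T_s_width", [14, 32, 60, 110, 169])
    def test_height_is_sensor_inventory_regardless_of_width(self, T_s_width):
        img = render_gvfe_image([1, 2, 3], n_sensors=67, width=T_s_width)
        assert img.shape[0] == 67

    def test_one_pixel_per_firing(self):
        rng = np.random.default_rng(0)
        seq = rng.integers(1, 68, size=25)
        img = render_gvfe_image(seq, n_sensors=67, width=32)
        assert img.sum() == 25

    def test_overlong_sequence_rejected(self):
        with pytest.raises(ValueError, match="exceeds width"):
            render_gvfe_image([1] * 15, n_sensors=67, width=14)

    def test_out_of_range_ordinal_rejected(self):
        with pytest.raises(ValueError):
            render_gvfe_image([68], n_sensors=67, width=14)


class TestFlattenBinarize:
    def test_default_canvas_has_39000_features(self):
        img = np.zeros((130, 100, 3), dtype=np.uint8)
        assert flatten_binarize(img).shape == (39_000,)

    def test_black_image_maps_to_zero_vector(self):
        img = np.zeros((130, 100, 3), dtype=np.uint8)
        assert flatten_binarize(img).sum() == 0

    def test_single_red_pixel_sets_exactly_one_feature(self):
        img = np.zeros((130, 100, 3), dtype=np.uint8)
        img[7, 13, 0] = 255
        vec = flatten_binarize(img)
        assert vec.sum() == 1
        assert vec[(7 * 100 + 13) * 3] == 1  # row-major, channel-minor

    def test_binarization_is_idempotent(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(13, 10, 3)).astype(np.uint8)
        once = flatten_binarize(img)
        twice = flatten_binarize(once.reshape(13, 10, 3) * 255)
        np.testing.assert_array_equal(once, twice)
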