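"""Spline, interfilament-distance, and bookkeeping contracts with analytic oracles."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import tomomorph as tm

VX = 15.84


def helix_trace(radius=120.0, pitch=80.0, turns=2.0, step_deg=20.0) -> tm.FilamentTrace:
    th = np.arange(0.0, 2 * math.pi * turns + 1e-12, math.radians(step_deg))
    pts = np.column_stack([radius * np.cos(th), radius * np.sin(th), pitch * th / (2 * math.pi)])
    return tm.FilamentTrace("helix", pts)


def helix_arc_length(radius, pitch, turns):
    return turns * math.sqrt((2 * math.pi * radius) ** 2 + pitch**2)


class TestParsePointModel:
    def test_empty_stream(self):
        assert tm.parse_point_model(io.StringIO(""), voxel_size=VX) == []

    def test_two_contours_three_points(self):
        text = "\n".join(
            ["1 1 0 0 0", "1 1 1 0 0", "1 1 2 0 0", "1 2 0 5 0", "1 2 0 6 0", "1 2 0 7 1"]
        )
        traces = tm.parse_point_model(io.StringIO(text), voxel_size=VX)
        assert len(traces) == 2
        assert all(len(t.points) == 3 for t in traces)
        np.testing.assert_allclose(traces[0].points[1], [VX, 0, 0])

    def test_four_column_dialect(self):
        traces = tm.parse_point_model(io.StringIO("7 1 2 3\n7 4 5 6\n"), voxel_size=1.0)
        assert len(traces) == 1
        np.testing.assert_allclose(traces[0].points, [[1, 2, 3], [4, 5, 6]])

    def test_malformed_line_reports_number(self):
        with pytest.raises(tm.PointModelError, match="line 2"):
            tm.parse_point_model(io.StringIO("1 1 0 0 0\n1 1 x 0 0\n"), voxel_size=1.0)
        with pytest.raises(tm.PointModelError, match="columns"):
            tm.parse_point_model(io.StringIO("1 1 0\n"), voxel_size=1.0)

    def test_single_point_contour_skipped_with_warning(self):
        text = "1 1 0 0 0\n1 2 0 0 0\n1 2 1 0 0\n"
        with pytest.warns(UserWarning, match="single point"):
            traces = tm.parse_point_model(io.StringIO(text), voxel_size=1.0)
        assert [t.filament_id for t in traces] == ["1-2"]

    def test_round_trip_of_generated_bundle(self):
        scene = tm.gen_filament_bundle(tm.BundleSpec(n_filaments=5, seed=2, length=200.0))
        buf = io.StringIO()
        tm.write_point_model(scene.traces, buf, voxel_size=VX)
        buf.seek(0)
        back = tm.parse_point_model(buf, voxel_size=VX)
        assert len(back) == 5
        for orig, rt in zip(scene.traces, back):
            np.testing.assert_allclose(rt.points, orig.points, atol=VX * 1e-3 + 1e-6)


class TestSplineModel:
    def test_two_point_segment_length(self):
        sp = tm.fit_spline(tm.FilamentTrace("s", np.array([[0.0, 0, 0], [100.0, 0, 0]])))
        assert sp.total_length == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(sp.position(50.0), [50.0, 0, 0], atol=1e-9)

    def test_collinear_points_reproduce_line(self):
        pts = np.column_stack([np.linspace(0, 90, 10), np.zeros(10), np.zeros(10)])
        sp = tm.fit_spline(tm.FilamentTrace("line", pts))
        s = np.linspace(0, sp.total_length, 37)
        pos = sp.position(s)
        assert np.abs(pos[:, 1:]).max() < 1e-6
        np.testing.assert_allclose(pos[:, 0], s, atol=1e-6)

    def test_helix_arc_length_closed_form(self):
        sp = tm.fit_spline(helix_trace(turns=2.0))
        assert sp.total_length == pytest.approx(helix_arc_length(120.0, 80.0, 2.0), rel=0.01)

    def test_interpolates_input_points(self):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.uniform(5, 40, size=(7, 3)), axis=0)
        trace = tm.FilamentTrace("w", pts)
        sp = tm.fit_spline(trace)
        chord = np.concatenate(([0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))))
        for t_chord, p in zip(chord, pts):
            # chord parameter -> arc length via the model's own table, then evaluate
            s = np.interp(t_chord, sp._t_fine, sp._s_fine)
            np.testing.assert_allclose(sp.position(s), p, atol=1e-6)

    def test_length_at_least_end_to_end(self):
        rng = np.random.default_rng(8)
        pts = np.cumsum(rng.uniform(-20, 40, size=(6, 3)), axis=0)
        sp = tm.fit_spline(tm.FilamentTrace("r", pts))
        assert sp.total_length >= sp.end_to_end() - 1e-9

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            tm.FilamentTrace("d", np.array([[0.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]]))


class TestResampleArclength:
    def test_straight_400A_at_40A_gives_11_points(self):
        sp = tm.fit_spline(tm.FilamentTrace("s", np.array([[0.0, 0, 0], [400.0, 0, 0]])))
        pos, tan = tm.resample_arclength(sp, spacing=40.0)
        assert len(pos) == 11
        np.testing.assert_allclose(np.diff(pos[:, 0]), 40.0, atol=1e-9)
        np.testing.assert_allclose(tan, np.tile([1.0, 0, 0], (11, 1)), atol=1e-12)

    def test_uniform_gaps_partial_interval_dropped(self):
        sp = tm.fit_spline(helix_trace(turns=1.5))
        pos, tan = tm.resample_arclength(sp, spacing=40.0)
        assert len(pos) == int(sp.total_length // 40.0) + 1
        chords = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.all(chords <= 40.0 + 1e-6)
        assert np.all(chords >= 0.98 * 40.0)
        np.testing.assert_allclose(np.linalg.norm(tan, axis=1), 1.0, atol=1e-9)

    def test_helix_tangents_within_one_degree(self):
        radius, pitch = 120.0, 80.0
        sp = tm.fit_spline(helix_trace(radius, pitch, turns=2.0, step_deg=20.0))
        pos, tan = tm.resample_arclength(sp, spacing=40.0)
        # analytic tangent at azimuth theta recovered from the xy position
        th = np.unwrap(np.arctan2(pos[:, 1], pos[:, 0]))
        c = pitch / (2 * math.pi)
        analytic = np.column_stack([-radius * np.sin(th), radius * np.cos(th), np.full_like(th, c)])
        analytic /= np.linalg.norm(analytic, axis=1, keepdims=True)
        angles = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", tan, analytic), -1, 1)))
        interior = angles[1:-1]  # ends feel the natural boundary condition
        assert interior.max() < 1.0


class TestNearestNeighborDistances:
    @staticmethod
    def _line(x_nm, y_nm, fid, length_nm=300.0):
        pts_nm = np.array([[x_nm, y_nm, 0.0], [x_nm, y_nm, length_nm]])
        return tm.fit_spline(tm.FilamentTrace(fid, pts_nm * 10.0))

    def test_two_parallel_lines(self):
        splines = [self._line(0, 0, "a"), self._line(54.0, 0, "b")]
        table, summary = tm.nearest_neighbor_distances({"t": splines})
        np.testing.assert_allclose(table.nn_distance_nm, [54.0, 54.0], atol=1e-9)
        assert summary["mean_nm"] == pytest.approx(54.0)
        assert summary["sd_nm"] == pytest.approx(0.0, abs=1e-12)

    def test_equilateral_triangle_bundle(self):
        side = 54.0
        splines = [
            self._line(0, 0, "a"),
            self._line(side, 0, "b"),
            self._line(side / 2, side * math.sqrt(3) / 2, "c"),
        ]
        table, summary = tm.nearest_neighbor_distances({"t": splines})
        assert summary["n"] == 3
        np.testing.assert_allclose(table.nn_distance_nm, side, atol=1e-9)

    def test_matches_dense_brute_force(self):
        scene = tm.gen_filament_bundle(
            tm.BundleSpec(n_filaments=10, seed=5, length=150.0, wobble_amplitude=3.0)
        )
        splines = [tm.fit_spline(t) for t in scene.traces]
        table, _ = tm.nearest_neighbor_distances({"t": splines})
        # oracle: min over all pairs of 1 Å-resampled point clouds
        dense = []
        for sp in splines:
            n = int(math.ceil(sp.total_length)) + 1
            dense.append(sp.position(np.linspace(0, sp.total_length, n)))
        trees = [cKDTree(p) for p in dense]
        for i, row in table.iterrows():
            brute = min(
                trees[j].query(dense[i])[0].min() for j in range(len(dense)) if j != i
            )
            assert abs(row.nn_distance_nm - brute / 10.0) < 0.2

    def test_rigid_motion_invariance(self):
        scene = tm.gen_filament_bundle(tm.BundleSpec(n_filaments=6, seed=13, length=200.0))
        splines = [tm.fit_spline(t) for t in scene.traces]
        _, base = tm.nearest_neighbor_distances({"t": splines})
        angle = 0.7
        rot = np.array(
            [
                [math.cos(angle), -math.sin(angle), 0],
                [math.sin(angle), math.cos(angle), 0],
                [0, 0, 1],
            ]
        ) @ np.array([[1, 0, 0], [0, math.cos(0.4), -math.sin(0.4)], [0, math.sin(0.4), math.cos(0.4)]])
        moved = [
            tm.fit_spline(
                tm.FilamentTrace(t.filament_id, t.points @ rot.T + np.array([500.0, -300.0, 900.0]))
            )
            for t in scene.traces
        ]
        _, rotated = tm.nearest_neighbor_distances({"t": moved})
        assert rotated["mean_nm"] == pytest.approx(base["mean_nm"], abs=1e-3)
        assert rotated["median_nm"] == pytest.approx(base["median_nm"], abs=1e-3)

    def test_single_filament_tomogram_is_empty_not_error(self):
        table, summary = tm.nearest_neighbor_distances({"t": [self._line(0, 0, "a")]})
        assert len(table) == 0 and summary["n"] == 0

    def test_all_pairs_mode_counts(self):
        splines = [self._line(0, 0, "a"), self._line(54, 0, "b"), self._line(0, 54, "c")]
        table, summary = tm.nearest_neighbor_distances({"t": splines}, all_pairs=True)
        assert len(table) == 3  # 3 unordered pairs
        assert summary["n"] == 3


class TestDefectBookkeeping:
    @staticmethod
    def _traces(n_total, flags):
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        out = []
        for i in range(n_total):
            out.append(tm.FilamentTrace(f"f{i}", pts, defect_flag=flags.get(i)))
        return out

    def test_paper_tally_15_of_481(self):
        flags = {i: "missing_protofilament" for i in range(15)}
        res = tm.defect_fraction(self._traces(481, flags))
        assert (res.n_defective, res.n_total) == (15, 481)
        assert res.percent == "3%"

    def test_zero_defects(self):
        res = tm.defect_fraction(self._traces(10, {}))
        assert res.percent == "0%" and res.fraction == 0.0

    def test_category_partition(self):
        flags = {i: "missing_protofilament" for i in range(15)}
        flags.update({15 + i: "incomplete_end" for i in range(3)})
        res = tm.defect_fraction(self._traces(481, flags))
        assert res.by_category == {"missing_protofilament": 15, "incomplete_end": 3}
        assert res.n_defective == 18 and res.n_defective <= res.n_total
        assert 0.0 <= res.fraction <= 1.0


class TestDepthProfile:
    def test_center_of_section_convention(self):
        depths = [tm.section_depth_from_index(i, pitch_um=5.0) for i in range(5)]
        assert depths == [2.5, 7.5, 12.5, 17.5, 22.5]

    def test_empty_and_sorted(self):
        assert len(tm.depth_profile([])) == 0
        records = [
            (tm.SectionDepth("t3", 3, tm.section_depth_from_index(3)), 12),
            (tm.SectionDepth("t0", 0, tm.section_depth_from_index(0)), 7),
            (tm.SectionDepth("t1", 1, tm.section_depth_from_index(1)), 9),
        ]
        table = tm.depth_profile(records)
        assert list(table.tomogram_id) == ["t0", "t1", "t3"]
        assert list(table.filament_count) == [7, 9, 12]
        shuffled = tm.depth_profile(list(reversed(records)))
        pd.testing.assert_frame_equal(table, shuffled)

    def test_duplicate_tomogram_rejected(self):
        records = [
            (tm.SectionDepth("t0", 0, 2.5), 7),
            (tm.SectionDepth("t0", 1, 7.5), 9),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            tm.depth_profile(records)
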