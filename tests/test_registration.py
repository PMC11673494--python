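import numpy as np
import pytest

import facemetry as fm
from facemetry.registration import SurfaceDistance, _point_triangle_closest, deviation_colors


def brute_force_distances(points, mesh):
    tri = mesh.vertices[mesh.faces]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        cps = _point_triangle_closest(np.repeat(p[None], len(tri), 0), tri)
        out[i] = np.linalg.norm(p - cps, axis=1).min()
    return out


def small_random_surface(n_vertices=100, seed=0):
    """Irregular ~100-vertex open surface for oracle comparisons."""
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    xy = rng.uniform(-20, 20, size=(n_vertices, 2))
    z = 3 * np.sin(xy[:, 0] / 7) * np.cos(xy[:, 1] / 9)
    tri = Delaunay(xy)
    return fm.FaceMesh(np.column_stack([xy, z]), tri.simplices)


class TestKabsch:
    def test_identity_for_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3)) * 20
        T = fm.kabsch(pts, pts)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(T.translation, 0, atol=1e-10)

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(size=(10, 3)) * 20
        T = fm.RigidTransform.from_axis_angle([0, 1, 0], np.radians(30), [5, -2, 1])
        rec = fm.kabsch(pts, T.apply(pts))
        assert np.abs(rec.rotation - T.rotation).max() < 1e-8
        assert np.abs(rec.translation - T.translation).max() < 1e-8

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        with pytest.raises(fm.DegenerateInputError):
            fm.kabsch(pts, pts + [0, 1, 0])


class TestPrealign:
    def test_identity_for_identical_landmark_sets(self, template):
        _, lms, _ = template
        T = fm.prealign(lms, lms)
        assert np.abs(T.rotation - np.eye(3)).max() < 1e-10
        assert np.abs(T.translation).max() < 1e-10

    def test_recovers_known_transform(self, template):
        _, lms, _ = template
        T = fm.RigidTransform.from_axis_angle([0, 1, 0], np.radians(30), [5, -2, 1])
        rec = fm.prealign(lms, lms.transformed(T))
        assert np.abs(rec.rotation - T.rotation).max() < 1e-8
        assert np.abs(rec.translation - T.translation).max() < 1e-8

    def test_two_points_rejected(self):
        a = fm.LandmarkSet({"ExL": [1, 0, 0], "ExR": [-1, 0, 0]})
        with pytest.raises((fm.DegenerateInputError, fm.MissingLandmarkError)):
            fm.prealign(a, a, names=["ExL", "ExR"])


class TestBuildFrame:
    def test_canonical_template_gives_identity_frame(self, template):
        _, lms, _ = template
        frame = fm.build_frame(lms)
        assert np.abs(frame.origin).max() < 1e-6
        assert np.abs(frame.axes - np.eye(3)).max() < 1e-6

    def test_transform_equivariance(self, template):
        """Frame coordinates of landmarks are invariant under a common
        rigid transform of the landmark set."""
        _, lms, _ = template
        frame = fm.build_frame(lms)
        T = fm.RigidTransform.from_axis_angle([1, 0.5, -0.2], 0.7, [10, -5, 8])
        frame_T = fm.build_frame(lms.transformed(T))
        for name in ("Prn", "Gl", "Me'"):
            before = frame.coords(lms[name])
            after = frame_T.coords(T.apply(lms[name][None])[0])
            assert np.abs(before - after).max() < 1e-8

    def test_coincident_tragions_rejected(self, template):
        _, lms, _ = template
        pts = lms.to_dict()
        pts["TraR"] = pts["TraL"]
        with pytest.raises(fm.DegenerateInputError):
            fm.build_frame(fm.LandmarkSet(pts))

    def test_missing_landmark_named(self, template):
        _, lms, _ = template
        pts = {n: p for n, p in lms.to_dict().items() if n != "OrbL"}
        with pytest.raises(fm.MissingLandmarkError, match="OrbL"):
            fm.build_frame(fm.LandmarkSet(pts))


class TestPointToSurface:
    def test_identical_meshes_give_zero(self, template):
        mesh, _, _ = template
        d = fm.point_to_surface(mesh, mesh)
        assert np.abs(d).max() < 1e-12

    def test_offset_plane_distance_and_sign(self):
        plane = fm.FaceMesh(
            np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0.0]]),
            np.array([[0, 1, 3], [0, 3, 2]]),
        )
        above = plane.copy()
        above.vertices = above.vertices + [0, 0, 0.5]
        d = fm.point_to_surface(above, plane)
        assert np.allclose(d, 0.5, atol=1e-12)
        below = plane.copy()
        below.vertices = below.vertices - [0, 0, 0.5]
        d = fm.point_to_surface(below, plane)
        assert np.allclose(d, -0.5, atol=1e-12)

    def test_matches_brute_force_exactly(self, rng):
        surface = small_random_surface()
        queries = rng.uniform(-25, 25, size=(120, 3))
        sd = SurfaceDistance(surface)
        _, d, _ = sd.query(queries)
        assert np.array_equal(d, brute_force_distances(queries, surface))


class TestIcp:
    def test_self_registration_is_identity(self, template):
        mesh, _, _ = template
        T, trace = fm.icp_best_fit(mesh, mesh)
        assert np.abs(T.rotation - np.eye(3)).max() < 1e-8
        assert np.abs(T.translation).max() < 1e-8
        assert len(trace) <= 2

    def test_recovers_synthetic_misalignment(self, clean_pair):
        T_true = fm.RigidTransform.from_axis_angle([0.3, 1, 0.2], np.radians(5), [3, 0, -1])
        moved = clean_pair.scan.transformed(T_true)
        moved_lms = clean_pair.scan_landmarks.transformed(T_true)
        init = fm.prealign(moved_lms, clean_pair.scan_landmarks)
        T, _ = fm.icp_best_fit(moved, clean_pair.scan, init=init)
        recovered = T.compose(T_true)
        disp = recovered.apply(clean_pair.scan.vertices) - clean_pair.scan.vertices
        assert np.linalg.norm(disp, axis=1).mean() < 1e-3

    @pytest.mark.parametrize("seed", range(3))
    def test_trace_non_increasing(self, model, seed):
        gt = fm.PairGroundTruth(
            transform=fm.RigidTransform.from_axis_angle([1, 0.2, 0.1], np.radians(8), [4, -3, 2]),
            noise_sd=0.2,
            seed=seed,
        )
        pair = fm.make_scan_pair(model, gt)
        init = fm.prealign(pair.recon_landmarks, pair.scan_landmarks)
        _, trace = fm.icp_best_fit(pair.recon, pair.scan, init=init)
        assert all(trace[i + 1] <= trace[i] + 1e-9 for i in range(len(trace) - 1))

    def test_empty_mesh_rejected(self, template):
        mesh, _, _ = template
        empty = fm.FaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(fm.InvalidArgumentError):
            fm.icp_best_fit(empty, mesh)


class TestRegionRmse:
    def test_zero_distances_give_zero_everywhere(self, template):
        _, _, labels = template
        r = fm.region_rmse(np.zeros(len(labels)), labels)
        assert all(v == 0 for v in r.values() if not np.isnan(v))

    def test_constant_magnitude_gives_that_rmse(self, template):
        _, _, labels = template
        signs = np.where(np.arange(len(labels)) % 2, 1.0, -1.0)
        r = fm.region_rmse(1.7 * signs, labels)
        for reg in fm.REGION_LABELS:
            assert r[reg] == pytest.approx(1.7)
        assert r["face"] == pytest.approx(1.7)

    def test_hand_computed_regions(self):
        labels = np.array(["nose"] * 2 + ["chin"] * 3 + ["background"], dtype=object)
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 99.0])
        r = fm.region_rmse(d, labels)
        assert r["nose"] == pytest.approx(np.sqrt((1 + 4) / 2))
        assert r["chin"] == pytest.approx(np.sqrt((9 + 16 + 25) / 3))
        assert r["face"] == pytest.approx(np.sqrt((1 + 4 + 9 + 16 + 25) / 5))
        assert np.isnan(r["forehead"])  # empty region reported as missing

    def test_length_mismatch_rejected(self):
        with pytest.raises(fm.InvalidArgumentError):
            fm.region_rmse(np.zeros(3), np.array(["nose"] * 4, dtype=object))


class TestLandmarkDeviation:
    def test_identical_sets_give_zero(self, template):
        _, lms, _ = template
        frame = fm.build_frame(lms)
        table = fm.landmark_deviation(lms, lms, frame)
        assert (table.to_numpy() == 0).all()

    def test_three_four_five_decomposition(self, template):
        _, lms, _ = template
        frame = fm.build_frame(lms)
        shifted = fm.LandmarkSet(
            {n: p + frame.axes @ [0.3, 0.4, 0.0] for n, p in lms.to_dict().items()}
        )
        table = fm.landmark_deviation(lms, shifted, frame)
        assert np.allclose(table["Dx"], 0.3, atol=1e-9)
        assert np.allclose(table["Dy"], 0.4, atol=1e-9)
        assert np.allclose(table["Dz"], 0.0, atol=1e-9)
        assert np.allclose(table["D"], 0.5, atol=1e-9)

    def test_pythagorean_identity(self, template, rng):
        _, lms, _ = template
        frame = fm.build_frame(lms)
        shifted = fm.LandmarkSet(
            {n: p + rng.normal(0, 2, 3) for n, p in lms.to_dict().items()}
        )
        table = fm.landmark_deviation(lms, shifted, frame)
        lhs = table["D"] ** 2
        rhs = table["Dx"] ** 2 + table["Dy"] ** 2 + table["Dz"] ** 2
        assert np.abs(lhs - rhs).max() < 1e-9


class TestColormap:
    def test_zero_maps_to_mid_scale_green(self):
        c = deviation_colors(np.zeros(3), 3.0)
        assert (c == [0, 255, 0]).all()

    def test_extremes_clamp_to_pure_colors(self):
        c = deviation_colors(np.array([-3.0, 3.0, -99.0, 99.0]), 3.0)
        assert (c[0] == [0, 0, 255]).all() and (c[2] == [0, 0, 255]).all()
        assert (c[1] == [255, 0, 0]).all() and (c[3] == [255, 0, 0]).all()

    def test_invalid_range_rejected(self, template):
        mesh, _, _ = template
        with pytest.raises(fm.InvalidArgumentError):
            fm.export_colormap(mesh, np.zeros(mesh.n_vertices), "x.ply", range_mm=0)

    def test_length_mismatch_rejected(self, template, tmp_path):
        mesh, _, _ = template
        with pytest.raises(fm.InvalidArgumentError):
            fm.export_colormap(mesh, np.zeros(3), str(tmp_path / "x.ply"))
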