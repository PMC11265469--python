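"""Smoothing, subdivision, clipping, flow extensions, and tet quality."""

import numpy as np
import pytest

from aortamorph.mesh import Plane, TetMesh, TriSurface, cap_all_openings, enclosed_volume
from aortamorph.preprocess import (
    add_flow_extension,
    clip_opening,
    laplacian_smooth,
    subdivide_butterfly,
    taubin_smooth,
    taubin_passband_to_mu,
    tet_skewness,
)
from conftest import make_cylinder, make_icosphere


def noisy_sphere(sigma=0.05, seed=0, level=3):
    sphere = make_icosphere(level)
    rng = np.random.default_rng(seed)
    radial = sphere.vertices / np.linalg.norm(sphere.vertices, axis=1, keepdims=True)
    out = sphere.copy()
    out.vertices = sphere.vertices + sigma * rng.standard_normal(
        (sphere.n_vertices, 1)) * radial
    return out


class TestTaubin:
    def test_passband_mapping(self):
        assert taubin_passband_to_mu(0.1) == pytest.approx(1 / (0.1 - 2))
        with pytest.raises(ValueError, match="mu"):
            taubin_passband_to_mu(1.5)

    def test_planar_grid_interior_unchanged(self):
        # regular planar grid: umbrella vector vanishes at interior vertices
        n = 7
        gx, gy = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces += [[a, a + 1, a + n + 1], [a, a + n + 1, a + n]]
        patch = TriSurface(verts, np.array(faces))
        out = taubin_smooth(patch, iterations=10)
        np.testing.assert_allclose(out.vertices, patch.vertices, atol=1e-12)

    def test_noise_reduction_on_sphere(self):
        noisy = noisy_sphere()
        out = taubin_smooth(noisy, passband=0.1, iterations=100)
        def rms_radial(s):
            return np.sqrt(np.mean((np.linalg.norm(s.vertices, axis=1) - 1.0) ** 2))
        assert rms_radial(out) < rms_radial(noisy)

    def test_volume_preserved_vs_laplacian_shrinkage(self):
        # fine mesh: the low-frequency amplification of the Taubin band-pass
        # shrinks with edge length, plain Laplacian shrinkage does not
        noisy = noisy_sphere(level=5)
        v0 = enclosed_volume(noisy)
        taubin = taubin_smooth(noisy, passband=0.1, iterations=100)
        lap = laplacian_smooth(noisy, lam=0.5, iterations=100)
        assert abs(enclosed_volume(taubin) - v0) / v0 <= 0.02
        assert (v0 - enclosed_volume(lap)) / v0 >= 0.10

    def test_connectivity_and_boundaries_preserved(self):
        tube = make_cylinder(n_theta=16, n_z=8)
        out = taubin_smooth(tube, iterations=50)
        np.testing.assert_array_equal(out.faces, tube.faces)
        loops0 = {frozenset(lp.tolist()) for lp in tube.boundary_loops()}
        # boundary vertices frozen in place
        for lp in tube.boundary_loops():
            np.testing.assert_allclose(out.vertices[lp], tube.vertices[lp])
        assert {frozenset(lp.tolist()) for lp in out.boundary_loops()} == loops0

    def test_invalid_parameters(self, cube):
        with pytest.raises(ValueError):
            taubin_smooth(cube, passband=2.5)
        with pytest.raises(ValueError):
            taubin_smooth(cube, iterations=0)


class TestButterfly:
    def test_counts_and_interpolating_property(self, cube):
        e = 18  # cube edge count: V - E + F = 2 -> 8 - E + 12 = 2
        out = subdivide_butterfly(cube, 1)
        assert out.n_faces == 4 * cube.n_faces
        assert out.n_vertices == cube.n_vertices + e
        np.testing.assert_array_equal(out.vertices[:8], cube.vertices)

    def test_octahedron_refines_toward_smooth_limit(self):
        # The interpolating butterfly limit of an octahedron is a smooth,
        # bounded, sphere-like surface (not an exact sphere): the radius
        # spread converges geometrically and every original vertex stays put.
        verts = np.array([[1., 0, 0], [-1, 0, 0], [0, 1, 0],
                          [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        faces = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                          [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]])
        surf = TriSurface(verts, faces)
        devs = []
        for _ in range(3):
            surf = subdivide_butterfly(surf, 1)
            r = np.linalg.norm(surf.vertices, axis=1)
            devs.append(np.abs(r - r.mean()).max())
            np.testing.assert_allclose(np.linalg.norm(surf.vertices[:6], axis=1), 1.0)
        assert abs(devs[2] - devs[1]) < 0.5 * abs(devs[1] - devs[0])
        assert devs[2] < 0.1  # stays sphere-like, no divergence at valence-4 points

    def test_labels_inherited(self, cube):
        cube.region_labels[:2] = "inlet"
        out = subdivide_butterfly(cube)
        assert int((out.region_labels == "inlet").sum()) == 8

    def test_boundary_edges_fall_back_to_midpoint(self):
        tube = make_cylinder(n_theta=8, n_z=3)
        out = subdivide_butterfly(tube)
        assert out.n_faces == 4 * tube.n_faces
        # boundary rings stay on z = 0 and z = height planes
        loops = out.boundary_loops()
        for lp in loops:
            z = out.vertices[lp][:, 2]
            assert np.ptp(z) < 1e-12


class TestClipOpening:
    def test_cylinder_midcut_loop_on_plane(self):
        tube = cap_all_openings(make_cylinder(radius=1, height=2, n_theta=64, n_z=32))
        plane = Plane([0, 0, 1.0], [0, 0, 1])
        out = clip_opening(tube, plane, label="outlet:1")
        assert out.vertices[:, 2].max() <= 1.0 + 1e-12
        loop = out.openings["outlet:1"]
        np.testing.assert_allclose(out.vertices[loop][:, 2], 1.0, atol=1e-9)
        r = np.linalg.norm(out.vertices[loop][:, :2], axis=1)
        # cut points on diagonal edges sit on chords: sag <= 1 - cos(pi/64)
        np.testing.assert_allclose(r, 1.0, atol=1.3e-3)

    def test_plane_missing_surface_raises(self, cube):
        with pytest.raises(ValueError, match="misses"):
            clip_opening(cube, Plane([10, 0, 0], [1, 0, 0]))

    def test_capped_cut_area_matches_disc(self):
        tube = cap_all_openings(make_cylinder(radius=1, height=2, n_theta=128, n_z=16))
        out = clip_opening(tube, Plane([0, 0, 1.37], [0, 0, 1]), label="cut", cap=True)
        from aortamorph.mesh import face_normals_areas
        _, areas = face_normals_areas(out, check_degenerate=False)
        cap_area = areas[out.region_labels == "cut"].sum()
        assert cap_area == pytest.approx(np.pi, rel=5e-3)
        assert out.is_closed()


class TestFlowExtension:
    def _open_tube(self):
        tube = make_cylinder(radius=0.01, height=0.05, n_theta=48, n_z=10)
        loops = tube.boundary_loops()
        bottom = min(loops, key=lambda lp: tube.vertices[lp][:, 2].mean())
        top = max(loops, key=lambda lp: tube.vertices[lp][:, 2].mean())
        tube.openings["inlet"] = bottom
        tube.openings["outlet:1"] = top
        return tube

    @pytest.mark.parametrize("factor,expected", [(5.0, 0.10), (0.5, 0.01)])
    def test_extension_length(self, factor, expected):
        tube = self._open_tube()
        out = add_flow_extension(tube, "outlet:1", factor)
        length = out.vertices[:, 2].max() - tube.vertices[:, 2].max()
        # equivalent diameter of a polygonal ring is slightly under 2r
        assert length == pytest.approx(expected, rel=5e-3)

    def test_watertight_after_capping(self):
        tube = self._open_tube()
        out = add_flow_extension(tube, "outlet:1", 5.0)
        out = add_flow_extension(out, "inlet", 0.5)
        assert cap_all_openings(out).is_closed()

    def test_volume_increase_matches_cylinder(self):
        tube = self._open_tube()
        v0 = enclosed_volume(cap_all_openings(tube))
        out = add_flow_extension(tube, "outlet:1", 5.0)
        v1 = enclosed_volume(cap_all_openings(out))
        area = np.pi * 0.01**2
        d_eq = 2 * np.sqrt(area * np.sinc(2 / 48) / np.pi)  # polygon correction
        expected = (np.pi / 4) * d_eq**2 * 5 * d_eq
        assert v1 - v0 == pytest.approx(expected, rel=0.02)

    def test_missing_label_raises(self):
        tube = self._open_tube()
        with pytest.raises(KeyError, match="no opening"):
            add_flow_extension(tube, "outlet:9", 5.0)


class TestTetSkewness:
    def test_regular_tet_is_zero(self):
        a = np.array([1., 1, 1]) / np.sqrt(3)
        nodes = np.array([[1., 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]))
        rep = tet_skewness(mesh)
        assert rep.skewness[0] == pytest.approx(0.0, abs=1e-12)

    def test_sliver_near_one(self):
        nodes = np.array([[0., 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                          [0.5, np.sqrt(3) / 6, 1e-6]])
        rep = tet_skewness(TetMesh(nodes, np.array([[0, 1, 2, 3]])))
        assert rep.skewness[0] > 0.99

    def test_threshold_report_matches_brute_force(self):
        rng = np.random.default_rng(3)
        nodes = rng.standard_normal((40, 3))
        tets = rng.choice(40, size=(60, 4), replace=True)
        # discard degenerate index combos
        tets = tets[np.array([len(set(t)) == 4 for t in tets])]
        rep = tet_skewness(TetMesh(nodes, tets), threshold=0.9)
        np.testing.assert_array_equal(rep.above_threshold,
                                      np.nonzero(rep.skewness > 0.9)[0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        nodes = rng.standard_normal((12, 3))
        tets = np.array([[0, 1, 2, 3], [4, 5, 6, 7], [8, 9, 10, 11]])
        s1 = tet_skewness(TetMesh(nodes, tets)).skewness
        s2 = tet_skewness(TetMesh(nodes * 137.0, tets)).skewness
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_inverted_elements_flagged(self):
        nodes = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        rep = tet_skewness(TetMesh(nodes, np.array([[0, 2, 1, 3]])))
        assert 0 in rep.inverted
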