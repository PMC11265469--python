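"""Inlet-profile construction, registration, flows, and flow splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aortamorph as am
from aortamorph.boundary import (
    IDWInterpolator,
    read_transient_profile,
    write_profiles_csv,
    write_transient_profile,
)
from aortamorph.mesh import Plane


def disc_samples(n_side=21, radius=1.0):
    g = np.linspace(-radius, radius, n_side)
    gx, gy = np.meshgrid(g, g)
    keep = gx**2 + gy**2 <= radius**2
    return np.column_stack([gx[keep], gy[keep], np.zeros(keep.sum())])


def make_series(n_phases=5, n_side=9):
    pos = disc_samples(n_side)
    times = np.linspace(0.0, 0.8, n_phases)
    vel = np.zeros((n_phases, len(pos), 3))
    for k in range(n_phases):
        vel[k, :, 2] = (k + 1) * 0.1
    return am.VelocitySampleSeries(phase_times=times, positions=pos, velocities=vel)


class TestInterpVelocityTime:
    def test_exact_at_phase_times_and_midpoint(self):
        s = make_series()
        np.testing.assert_array_equal(am.interp_velocity_time(s, 0.2), s.velocities[1])
        mid = am.interp_velocity_time(s, 0.3)
        np.testing.assert_allclose(mid, 0.5 * (s.velocities[1] + s.velocities[2]))

    def test_cyclic_wrap_toward_phase_zero(self):
        s = make_series()
        v = am.interp_velocity_time(s, 0.9, cycle_length=1.0)
        frac = (0.9 - 0.8) / (1.0 - 0.8)
        np.testing.assert_allclose(
            v, (1 - frac) * s.velocities[-1] + frac * s.velocities[0])

    def test_dense_resampling_preserves_flow_integral(self):
        # piecewise-linear in t: trapezoid over any refinement is identical
        s = make_series()
        coarse = np.trapezoid([am.interp_velocity_time(s, t)[:, 2].mean()
                               for t in s.phase_times], s.phase_times)
        dense_t = np.linspace(0, 0.8, 401)
        dense = np.trapezoid([am.interp_velocity_time(s, t)[:, 2].mean()
                              for t in dense_t], dense_t)
        assert dense == pytest.approx(coarse, rel=1e-10)

    def test_validation_rejects_bad_series(self):
        pos = disc_samples(5)
        with pytest.raises(ValueError, match="increasing"):
            am.VelocitySampleSeries(np.array([0.0, 0.0]), pos,
                                    np.zeros((2, len(pos), 3)))
        with pytest.raises(ValueError, match="finite"):
            am.VelocitySampleSeries(np.array([0.0, 1.0]), pos,
                                    np.full((2, len(pos), 3), np.inf))


class TestIDW:
    def test_coincident_target_returns_sample(self):
        pos = disc_samples(9)
        vel = np.random.default_rng(0).standard_normal((len(pos), 3))
        out = am.idw_project(pos, vel, pos[[3, 17]])
        np.testing.assert_array_equal(out, vel[[3, 17]])

    def test_uniform_field_reproduced(self):
        pos = disc_samples(9)
        vel = np.tile([0.1, -0.2, 0.7], (len(pos), 1))
        out = am.idw_project(pos, vel, np.array([[0.05, 0.33, 0.0], [0, 0, 0.0]]))
        np.testing.assert_allclose(out, [[0.1, -0.2, 0.7]] * 2)

    def test_knn_matches_brute_force_when_k_all(self):
        rng = np.random.default_rng(1)
        pos = disc_samples(15)
        vel = rng.standard_normal((len(pos), 3))
        targets = rng.uniform(-0.5, 0.5, (20, 2))
        targets = np.column_stack([targets, np.zeros(20)])
        mine = am.idw_project(pos, vel, targets, power=2, k_neighbors=None)
        d = np.linalg.norm(targets[:, None] - pos[None], axis=2)
        w = d**-2.0
        brute = (w @ vel) / w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(mine, brute, atol=1e-12)

    def test_linear_field_error_bounded(self):
        pos = disc_samples(41)
        vel = np.column_stack([pos[:, 0], 2 * pos[:, 1], np.zeros(len(pos))])
        rng = np.random.default_rng(2)
        targets = rng.uniform(-0.4, 0.4, (50, 2))
        targets = np.column_stack([targets, np.zeros(50)])
        out = am.idw_project(pos, vel, targets, k_neighbors=8)
        expect = np.column_stack([targets[:, 0], 2 * targets[:, 1], np.zeros(50)])
        field_range = 2 * 0.8  # vy spans [-0.8, 0.8] over the sampled band
        assert np.abs(out - expect).max() <= 0.05 * field_range

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            IDWInterpolator().fit(np.empty((0, 3)), np.empty((0, 3)))


class TestRegistration:
    def setup_method(self):
        self.pos = disc_samples(15, radius=0.01)
        rng = np.random.default_rng(5)
        r2 = self.pos[:, 0] ** 2 + self.pos[:, 1] ** 2
        self.vel = np.zeros((len(self.pos), 3))
        self.vel[:, 2] = 1.0 - r2 / 0.01**2  # Poiseuille-like
        self.plane = Plane([0, 0, 0], [0, 0, 1])

    def test_identity_matches_plain_idw(self):
        out = am.register_to_inlet(self.pos, self.vel, self.pos,
                                   source_plane=self.plane)
        plain = am.idw_project(self.pos, self.vel, self.pos)
        np.testing.assert_allclose(out, plain, atol=1e-12)

    def test_translation_invariance(self):
        shift = np.array([0.3, -0.1, 0.25])
        out = am.register_to_inlet(self.pos, self.vel, self.pos + shift,
                                   source_plane=self.plane)
        base = am.register_to_inlet(self.pos, self.vel, self.pos,
                                    source_plane=self.plane)
        np.testing.assert_allclose(out, base, atol=1e-12)

    @pytest.mark.parametrize("angle", [np.pi / 2, 0.3, 1.2])
    def test_rotation_rotates_vectors_and_preserves_flux(self, angle):
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])  # about x (in-plane axis)
        rotated_targets = self.pos @ R.T
        out = am.register_to_inlet(self.pos, self.vel, rotated_targets,
                                   source_plane=self.plane,
                                   inlet_normal_hint=R @ [0, 0, 1])
        base = am.register_to_inlet(self.pos, self.vel, self.pos,
                                    source_plane=self.plane)
        np.testing.assert_allclose(out, base @ R.T, atol=1e-9)
        # through-plane flux (sum of normal components) preserved
        flux0 = base @ np.array([0, 0, 1.0])
        flux1 = out @ (R @ [0, 0, 1.0])
        np.testing.assert_allclose(flux1.sum(), flux0.sum(), rtol=1e-10)

    def test_degenerate_inlet_rejected(self):
        with pytest.raises(ValueError, match="inlet"):
            am.register_to_inlet(self.pos, self.vel, self.pos[:2])


class TestFlowThroughPlane:
    def _disc_mesh(self, radius=1.0, n=200):
        # fan triangulation of a disc in the z = 0 plane
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                                np.zeros(n)])
        verts = np.vstack([[0, 0, 0], ring])
        faces = np.column_stack([np.zeros(n, int), 1 + np.arange(n),
                                 1 + (np.arange(n) + 1) % n])
        return verts, faces

    def test_uniform_axial_flow_equals_area(self):
        verts, faces = self._disc_mesh()
        v = np.tile([0, 0, 1.0], (len(verts), 1))
        q = am.flow_through_plane(verts, faces, v)
        assert q == pytest.approx(np.pi, rel=5e-3)

    def test_in_plane_velocity_gives_zero(self):
        verts, faces = self._disc_mesh()
        v = np.tile([2.0, -1.0, 0.0], (len(verts), 1))
        assert am.flow_through_plane(verts, faces, v) == pytest.approx(0.0, abs=1e-12)

    def test_poiseuille_flow_rate(self):
        # u = u0 (1 - r^2/R^2): Q = u0 pi R^2 / 2; midpoint rule on a fine fan
        R, u0, n_r, n_t = 1.0, 2.0, 60, 120
        rr = np.linspace(0, R, n_r)
        tt = np.linspace(0, 2 * np.pi, n_t, endpoint=False)
        gr, gt = np.meshgrid(rr[1:], tt)
        verts = np.vstack([[0, 0, 0], np.column_stack([
            (gr * np.cos(gt)).ravel(), (gr * np.sin(gt)).ravel(),
            np.zeros(gr.size)])])
        idx = lambda i_r, i_t: 1 + (i_t % n_t) * (n_r - 1) + i_r
        faces = []
        for i_t in range(n_t):
            faces.append([0, idx(0, i_t), idx(0, i_t + 1)])
            for i_r in range(n_r - 2):
                faces.append([idx(i_r, i_t), idx(i_r + 1, i_t), idx(i_r + 1, i_t + 1)])
                faces.append([idx(i_r, i_t), idx(i_r + 1, i_t + 1), idx(i_r, i_t + 1)])
        faces = np.array(faces)
        r = np.linalg.norm(verts[:, :2], axis=1)
        v = np.zeros((len(verts), 3))
        v[:, 2] = u0 * (1 - r**2 / R**2)
        q = am.flow_through_plane(verts, faces, v)
        assert q == pytest.approx(u0 * np.pi * R**2 / 2, rel=0.01)


class TestFlowSplit:
    def test_branch_flow_and_tree_conservation(self):
        assert am.branch_flow(1.0, 0.8) == pytest.approx(0.2)
        assert am.branch_flow(0.37, 0.37) == 0.0
        # nested bifurcations: upstream/downstream plane differences sum to inlet
        rng = np.random.default_rng(8)
        q_planes = np.sort(rng.uniform(0.1, 1.0, 4))[::-1]  # decreasing downstream
        branches = [am.branch_flow(q_planes[i], q_planes[i + 1]) for i in range(3)]
        total = sum(branches) + q_planes[-1]
        assert total == pytest.approx(q_planes[0], abs=1e-12)

    def test_fractions_of_unity_inlet(self):
        split = am.compute_flow_split(np.array([[0.25, 0.25, 0.5]]), np.array([1.0]))
        np.testing.assert_allclose(split.w_N, [[0.25, 0.25, 0.5]])

    def test_rescaling_when_fractions_do_not_sum_to_one(self):
        split = am.compute_flow_split(np.array([[0.2, 0.3, 0.6]]), np.array([1.0]))
        np.testing.assert_allclose(split.w_N, [[2 / 11, 3 / 11, 6 / 11]])
        assert split.w_N.sum() == pytest.approx(1.0, abs=1e-15)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(2, 6), st.integers(0, 1000))
    def test_reconstructed_outlet_flows_sum_to_inlet(self, m, seed):
        rng = np.random.default_rng(seed)
        steps = 5
        Q_n = rng.uniform(-0.2, 1.0, (steps, m))
        Q_n[np.abs(Q_n.sum(axis=1)) < 1e-3] += 0.5  # avoid degenerate rows
        Q_i = rng.uniform(0.5, 2.0, steps)
        split = am.compute_flow_split(Q_n, Q_i)
        np.testing.assert_allclose(split.w_N.sum(axis=1), 1.0, atol=1e-12)
        recon = (Q_i[:, None] * split.w_N).sum(axis=1)
        np.testing.assert_allclose(recon, Q_i, atol=1e-12)

    def test_retrograde_warning_and_zero_inlet_rejected(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="aortamorph.boundary"):
            am.compute_flow_split(np.array([[-0.1, 1.0]]), np.array([1.0]))
        assert any("retrograde" in r.message for r in caplog.records)
        with pytest.raises(ValueError, match="zero inlet"):
            am.compute_flow_split(np.array([[0.5, 0.5]]), np.array([0.0]))


class TestProfileExport:
    def test_csv_row_count(self, tmp_path):
        import pandas as pd
        times = np.array([0.0, 0.1])
        pts = disc_samples(3)[:3]
        vel = np.random.default_rng(0).standard_normal((2, 3, 3))
        path = tmp_path / "prof.csv"
        write_profiles_csv(times, vel, pts, path)
        df = pd.read_csv(path)
        assert len(df) == 6
        assert list(df.columns) == ["time_s", "node_id", "x", "y", "z",
                                    "vx", "vy", "vz"]

    def test_transient_profile_round_trip(self, tmp_path):
        times = np.linspace(0, 1, 4)
        pts = disc_samples(5)
        vel = np.random.default_rng(3).standard_normal((4, len(pts), 3))
        path = tmp_path / "inlet.prof"
        write_transient_profile("inlet", times, pts, vel, path)
        back = read_transient_profile(path)
        assert back["name"] == "inlet"
        # %.9e formatting: round trip exact to ~1e-9 relative
        np.testing.assert_allclose(back["time"], times, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(back["points"], pts, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(back["velocities"], vel, rtol=1e-8, atol=1e-12)
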