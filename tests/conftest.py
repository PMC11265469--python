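"""Shared geometric fixtures: canonical closed solids and tube meshes.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from aortamorph.mesh import TriSurface

# unit cube, outward-oriented
_CUBE_VERTS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=float)
_CUBE_FACES = np.array([
    [0, 2, 1], [0, 3, 2],          # bottom  (-z)
    [4, 5, 6], [4, 6, 7],          # top     (+z)
    [0, 1, 5], [0, 5, 4],          # front   (-y)
    [2, 3, 7], [2, 7, 6],          # back    (+y)
    [0, 4, 7], [0, 7, 3],          # left    (-x)
    [1, 2, 6], [1, 6, 5],          # right   (+x)
])


@pytest.fixture
def cube() -> TriSurface:
    return TriSurface(_CUBE_VERTS.copy(), _CUBE_FACES.copy())


def make_icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriSurface:
    """Unit icosphere by midpoint subdivision of an icosahedron."""
    phi = (1 + np.sqrt(5)) / 2
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        verts = list(v)

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = verts[a] + verts[b]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_f = []
        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_f += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v = np.array(verts)
        f = np.array(new_f)
    return TriSurface(v * radius, f)


def make_cylinder(radius: float = 1.0, height: float = 2.0, n_theta: int = 48,
                  n_z: int = 24, closed: bool = False) -> TriSurface:
    """Open (or capped) cylinder along +z with base at z = 0."""
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    z = np.linspace(0.0, height, n_z)
    ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            np.zeros(n_theta)])
    verts = np.vstack([ring + [0, 0, zz] for zz in z])
    i = np.arange(n_z - 1)[:, None]
    j = np.arange(n_theta)[None, :]
    jn = (j + 1) % n_theta
    v00 = i * n_theta + j
    v01 = i * n_theta + jn
    v10 = (i + 1) * n_theta + j
    v11 = (i + 1) * n_theta + jn
    faces = np.vstack([
        np.stack([v00, v01, v11], axis=2).reshape(-1, 3),
        np.stack([v00, v11, v10], axis=2).reshape(-1, 3),
    ])
    surf = TriSurface(verts, faces)
    # ensure outward orientation
    from aortamorph.mesh import face_normals_areas
    n, _ = face_normals_areas(surf, check_degenerate=False)
    c = verts[faces[0]].mean(axis=0)
    if np.dot(n[0], [c[0], c[1], 0.0]) < 0:
        surf.faces = surf.faces[:, ::-1]
    if closed:
        from aortamorph.mesh import cap_all_openings
        surf = cap_all_openings(surf)
    return surf


@pytest.fixture(scope="session")
def icosphere4() -> TriSurface:
    return make_icosphere(4)


@pytest.fixture(scope="session")
def healthy_recovery():
    """Full morph-and-spline recovery on the healthy phantom (shared: costly)."""
    import aortamorph as am
    from aortamorph import synthetic as syn

    params = syn.healthy_preset()
    kfs, truth = syn.make_keyframes(params)
    base = kfs.base
    grid_ref = am.generate_control_points(
        base, syn.centerline_path(params), 19, 6, station_mode="parameter")
    morphed = []
    for t_k in kfs.phase_times:
        target, _ = syn.make_phantom_surface(params, float(t_k))
        grid_t = am.generate_control_points(
            target, syn.centerline_path(params, t=float(t_k)), 19, 6,
            station_mode="parameter")
        model = am.rbf_fit(grid_ref.flat(),
                           am.corresponding_displacements(grid_ref, grid_t))
        morphed.append(model.predict(base.vertices))
    kf_rbf = am.KeyFrameSet(phase_times=kfs.phase_times,
                            displacements=np.asarray(morphed),
                            cycle_length=params.cycle_length, base=base)
    seq = am.interpolate_in_time(kf_rbf, dt=1e-3, p=0.999)
    return {"params": params, "keyframes": kfs, "truth": truth,
            "morphed": np.asarray(morphed), "sequence": seq, "base": base}
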