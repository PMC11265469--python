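"""RBF-based surface morphing between cardiac key-frames.

The moving-wall kinematics are encoded as sparse control points: a structured
``i x j`` grid (i cross-sectional planes along a lumen path, j points per
circumference) sampled on every key-frame surface, plus static anchor points
that pin branch regions. The displacement of the control points from the
reference (peak-systole) grid to a target key-frame grid is interpolated to
every wall vertex with a radial basis function augmented by an affine
polynomial, which reproduces rigid motions and uniform scalings exactly.

:class:`RBFMorpher` is a scikit-learn style estimator: ``fit(centers,
displacements)`` solves the augmented symmetric system once per study and
``predict(points)`` evaluates the displacement field anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq, solve
from sklearn.base import BaseEstimator

from .mesh import STATIC, TriSurface

logger = logging.getLogger(__name__)

_DUPLICATE_TOL = 1e-9  # m


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _phi_linear(r: np.ndarray) -> np.ndarray:
    return r


def _phi_cubic(r: np.ndarray) -> np.ndarray:
    return r**3


def _phi_thin_plate(r: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r * r * np.log(r)
    return np.where(r > 0, out, 0.0)


KERNELS = {
    "linear_polyharmonic": _phi_linear,
    "cubic_polyharmonic": _phi_cubic,
    "thin_plate": _phi_thin_plate,
    "gaussian": None,  # handled via epsilon
}


# ---------------------------------------------------------------------------
# control-point grids
# ---------------------------------------------------------------------------

@dataclass
class ControlPointGrid:
    """Structured control-point matrix for one key-frame.

    ``points`` has shape (n_planes, n_per_plane, 3); ``static_anchors`` are
    extra zero-displacement points (branch stubs, extension ends).
    """

    points: np.ndarray
    static_anchors: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    frame_id: str = ""
    plane_stations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.static_anchors = np.asarray(self.static_anchors, dtype=float).reshape(-1, 3)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must be (n_planes, n_per_plane, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite control points")

    @property
    def shape(self) -> tuple[int, int]:
        return self.points.shape[:2]

    def flat(self) -> np.ndarray:
        return self.points.reshape(-1, 3)


def _polyline_arclength(path: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_path(path: np.ndarray, n_dense: int = 2000):
    """Densely resample a polyline by arc length; return points and tangents."""
    s = _polyline_arclength(path)
    sd = np.linspace(0.0, s[-1], n_dense)
    pts = np.column_stack([np.interp(sd, s, path[:, k]) for k in range(3)])
    tan = np.gradient(pts, sd, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return sd, pts, tan


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b (Rodrigues)."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-12:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _ray_surface_hits(origin: np.ndarray, direction: np.ndarray,
                      tri: np.ndarray) -> np.ndarray:
    """Positive ray parameters for all triangle intersections (Moller-Trumbore)."""
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(direction[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    mask = np.abs(a) > 1e-30
    ts = []
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(mask, 1.0 / a, 0.0)
        s = origin[None, :] - tri[:, 0]
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ direction)
        t = f * np.einsum("ij,ij->i", q, e2)
    ok = mask & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-12)
    return t[ok]


def generate_control_points(
    surface: TriSurface,
    path: np.ndarray,
    n_planes: int = 19,
    n_per_plane: int = 6,
    extra_points: np.ndarray | None = None,
    frame_id: str = "",
    margin: float = 0.02,
    station_mode: str = "arclength",
) -> ControlPointGrid:
    """Sample a structured i x j control grid by ray casting from a lumen path.

    Planes sit at uniform stations normal to the local path tangent
    (stations inset by ``margin`` of the total so end planes stay on the
    surface); in each plane, ``n_per_plane`` rays leave the path point at
    equal angles and the nearest positive surface hit becomes one control
    point. The angular phase of the first ray is carried between planes by
    the minimal rotation between consecutive tangents (parallel transport),
    so the grid stays structured around bends.

    ``station_mode='arclength'`` spaces stations uniformly in arc length
    (uniform longitudinal distances on a single geometry).
    ``station_mode='parameter'`` spaces them uniformly in the supplied
    polyline's own parameterization: when the key-frame paths of one study
    are sampled at matched parameters (registered centerlines), the i-th
    plane then cuts the *same material station* on every frame, which is
    what makes control points correspond across frames.
    """
    if n_planes < 2 or n_per_plane < 3:
        raise ValueError("need n_planes >= 2 and n_per_plane >= 3")
    path = np.asarray(path, dtype=float)
    if station_mode == "arclength":
        sd, pts, tan = _resample_path(path)
    elif station_mode == "parameter":
        u = np.linspace(0.0, 1.0, len(path))
        ud = np.linspace(0.0, 1.0, 2000)
        pts = np.column_stack([np.interp(ud, u, path[:, k]) for k in range(3)])
        tan = np.gradient(pts, ud, axis=0)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        sd = ud
    else:
        raise ValueError(f"unknown station_mode {station_mode!r}")
    total = sd[-1]
    stations = np.linspace(margin * total, (1 - margin) * total, n_planes)
    idx = np.searchsorted(sd, stations).clip(0, len(sd) - 1)

    tri = surface.vertices[surface.faces]
    angles = 2 * np.pi * np.arange(n_per_plane) / n_per_plane
    grid = np.empty((n_planes, n_per_plane, 3))

    t_prev = tan[idx[0]]
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, t_prev)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = ref - np.dot(ref, t_prev) * t_prev
    e1 /= np.linalg.norm(e1)
    multi_hits = 0
    for i, (st, ii) in enumerate(zip(stations, idx)):
        t_cur = tan[ii]
        e1 = _minimal_rotation(t_prev, t_cur) @ e1
        e1 -= np.dot(e1, t_cur) * t_cur
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t_cur, e1)
        origin = pts[ii]
        for j, ang in enumerate(angles):
            d = np.cos(ang) * e1 + np.sin(ang) * e2
            hits = _ray_surface_hits(origin, d, tri)
            if hits.size == 0:
                raise ValueError(
                    f"ray missed the surface at plane {i}, angle index {j}")
            if hits.size > 1:
                multi_hits += 1  # e.g. the ray crosses the other limb of a bend
            grid[i, j] = origin + hits.min() * d
        t_prev = t_cur
    if multi_hits:
        logger.info("%d/%d rays had multiple surface hits (nearest chosen)",
                    multi_hits, n_planes * n_per_plane)

    extra = (np.empty((0, 3)) if extra_points is None
             else np.asarray(extra_points, dtype=float).reshape(-1, 3))
    return ControlPointGrid(grid, static_anchors=extra, frame_id=frame_id,
                            plane_stations=stations)


def corresponding_displacements(
    grid_ref: ControlPointGrid, grid_target: ControlPointGrid
) -> np.ndarray:
    """Element-wise control-point displacements target - reference.

    Static anchors contribute exactly zero displacement; the returned array
    stacks grid displacements then anchor zeros, matching the center stacking
    of :func:`morph_surface`.
    """
    if grid_ref.shape != grid_target.shape:
        raise ValueError(f"grid shapes differ: {grid_ref.shape} vs {grid_target.shape}")
    if len(grid_ref.static_anchors) != len(grid_target.static_anchors):
        raise ValueError("static anchor counts differ")
    d = grid_target.flat() - grid_ref.flat()
    return np.vstack([d, np.zeros_like(grid_ref.static_anchors)])


# ---------------------------------------------------------------------------
# RBF estimator
# ---------------------------------------------------------------------------

class RBFMorpher(BaseEstimator):
    """Radial-basis-function displacement interpolator with affine term.

    Solves, per displacement component, the augmented symmetric system

        [ K + s I   P ] [w]   [d]
        [ P^T       0 ] [c] = [0]

    with ``K_ij = phi(|x_i - x_j|)``, ``P = [1, x, y, z]`` and smoothing
    ``s >= 0`` (s = 0 interpolates the centers exactly). The affine block
    makes translations, rotations and uniform scalings reproduce exactly.

    Parameters
    ----------
    kernel : one of ``linear_polyharmonic``, ``cubic_polyharmonic`` (default),
        ``thin_plate``, ``gaussian``.
    smoothing : ridge added to the kernel diagonal.
    epsilon : shape parameter, Gaussian kernel only.

    Attributes
    ----------
    centers_ : (n, 3) fitted centers.
    weights_ : (n, 3) kernel coefficients per component.
    poly_coeffs_ : (4, 3) affine coefficients (constant + linear).
    condition_ : estimated condition number of the interpolation system.
    """

    def __init__(self, kernel: str = "cubic_polyharmonic", smoothing: float = 0.0,
                 epsilon: float = 1.0):
        self.kernel = kernel
        self.smoothing = smoothing
        self.epsilon = epsilon

    def _phi(self, r: np.ndarray) -> np.ndarray:
        if self.kernel == "gaussian":
            return np.exp(-((self.epsilon * r) ** 2))
        try:
            return KERNELS[self.kernel](r)
        except KeyError:
            raise ValueError(f"unknown kernel {self.kernel!r}; "
                             f"choose from {sorted(KERNELS)}") from None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RBFMorpher":
        X = np.asarray(X, dtype=float).reshape(-1, 3)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y must have matching first dimension")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        n = len(X)
        if n < 4:
            raise ValueError("need >= 4 centers for the affine term")
        dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
        off = dist[~np.eye(n, dtype=bool)]
        if off.size and off.min() < _DUPLICATE_TOL:
            raise ValueError("duplicate centers within 1e-9 m")
        K = self._phi(dist) + self.smoothing * np.eye(n)
        P = np.column_stack([np.ones(n), X])
        A = np.zeros((n + 4, n + 4))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        rhs = np.zeros((n + 4, y.shape[1]))
        rhs[:n] = y
        self.condition_ = float(np.linalg.cond(A))
        if self.condition_ > 1e14:
            logger.warning("RBF system nearly singular (cond ~ %.2e); "
                           "falling back to least squares", self.condition_)
            sol = lstsq(A, rhs)[0]
        else:
            sol = solve(A, rhs, assume_a="sym")
        self.centers_ = X
        self.weights_ = sol[:n]
        self.poly_coeffs_ = sol[n:]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("RBFMorpher is not fitted")
        X = np.asarray(X, dtype=float).reshape(-1, 3)
        out = np.empty((len(X), self.weights_.shape[1]))
        P = np.column_stack([np.ones(len(X)), X])
        chunk = 4096  # bound the (points x centers) distance block
        for a in range(0, len(X), chunk):
            b = min(a + chunk, len(X))
            r = np.linalg.norm(X[a:b, None, :] - self.centers_[None], axis=2)
            out[a:b] = self._phi(r) @ self.weights_ + P[a:b] @ self.poly_coeffs_
        return out


def rbf_fit(centers: np.ndarray, displacements: np.ndarray,
            kernel: str = "cubic_polyharmonic", smoothing: float = 0.0) -> RBFMorpher:
    """Functional wrapper over :class:`RBFMorpher`."""
    return RBFMorpher(kernel=kernel, smoothing=smoothing).fit(centers, displacements)


def rbf_evaluate(model: RBFMorpher, query_points: np.ndarray) -> np.ndarray:
    return model.predict(query_points)


def morph_surface(
    base: TriSurface,
    grid_ref: ControlPointGrid,
    grid_target: ControlPointGrid,
    kernel: str = "cubic_polyharmonic",
    smoothing: float = 0.0,
    frame_id: str | None = None,
) -> TriSurface:
    """Morph the base (peak-systole) surface toward a target key-frame.

    Control-point displacements (with zero-displacement static anchors) drive
    the RBF field; vertices whose every incident face is labeled ``static``
    are pinned at exactly zero displacement. Connectivity is unchanged.
    """
    disp = corresponding_displacements(grid_ref, grid_target)
    centers = np.vstack([grid_ref.flat(), grid_ref.static_anchors])
    model = RBFMorpher(kernel=kernel, smoothing=smoothing).fit(centers, disp)
    field = model.predict(base.vertices)
    static_mask = base.vertex_labels() == STATIC
    field[static_mask] = 0.0
    out = base.copy()
    out.vertices = base.vertices + field

    from .mesh import face_normals_areas  # local import to avoid cycle at module load
    n_old, _ = face_normals_areas(base, check_degenerate=False)
    n_new, _ = face_normals_areas(out, check_degenerate=False)
    flipped = int(np.sum(np.einsum("ij,ij->i", n_old, n_new) < 0))
    if flipped:
        logger.warning("morph inverted %d faces relative to base", flipped)
    out.frame_id = frame_id if frame_id is not None else grid_target.frame_id
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def grid_to_frame(grid: ControlPointGrid):
    """Control grid as a pandas DataFrame (frame_id, plane, slot, x, y, z)."""
    import pandas as pd

    i, j = grid.shape
    plane, slot = np.divmod(np.arange(i * j), j)
    df = pd.DataFrame({
        "frame_id": grid.frame_id, "plane": plane, "slot": slot,
        "x": grid.flat()[:, 0], "y": grid.flat()[:, 1], "z": grid.flat()[:, 2],
    })
    return df


def grid_from_frame(df, static_anchors=None) -> ControlPointGrid:
    i = df["plane"].max() + 1
    j = df["slot"].max() + 1
    pts = df.sort_values(["plane", "slot"])[["x", "y", "z"]].to_numpy().reshape(i, j, 3)
    fid = str(df["frame_id"].iloc[0]) if len(df) else ""
    return ControlPointGrid(pts, static_anchors=static_anchors
                            if static_anchors is not None else np.empty((0, 3)),
                            frame_id=fid)
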