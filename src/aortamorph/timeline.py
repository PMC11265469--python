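"""Temporal interpolation of key-frame displacements and moving-mesh
kinematic diagnostics.

Key-frame displacement fields (relative to the peak-systole base surface)
are interpolated over one cardiac cycle with a cubic smoothing spline
(default p = 0.999, csaps convention) at a fixed CFD time step (default
1 ms). The aorta is assumed motionless during diastole: frames after the
early-diastole key-frame hold its displacement, and phantom knots at t = 0
and t = T carrying that held displacement close the cycle periodically.

The discrete motion is checked against the space conservation law: the
per-step change of the enclosed volume must equal the sum of the face
swept volumes. Swept volumes are computed *exactly* for linear per-step
vertex motion by summing signed origin-tetrahedra over each swept prism's
boundary (with a globally consistent diagonal split of the lateral quads),
so the residual is at round-off for any mesh and motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline
from sklearn.base import BaseEstimator

from .io import write_surface
from .mesh import TriSurface, cap_all_openings, enclosed_volume

logger = logging.getLogger(__name__)

KEYFRAME_NAMES = ("mid-acceleration", "peak systole", "mid-deceleration", "early diastole")


@dataclass
class KeyFrameSet:
    """Ordered key-frame displacement fields over one cardiac cycle.

    ``frames`` maps strictly increasing phase times in [0, T) to per-node
    displacements w.r.t. ``base`` (the peak-systole surface); the peak-systole
    frame must carry identically zero displacement.
    """

    phase_times: np.ndarray
    displacements: np.ndarray  # (n_frames, n_nodes, 3)
    cycle_length: float
    base: TriSurface
    names: tuple = KEYFRAME_NAMES

    def __post_init__(self) -> None:
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if np.any(np.diff(self.phase_times) <= 0):
            raise ValueError("phase times must be strictly increasing")
        if self.phase_times[0] < 0 or self.phase_times[-1] >= self.cycle_length:
            raise ValueError("phase times must lie in [0, T)")
        if self.displacements.shape[1] != self.base.n_vertices:
            raise ValueError("displacement fields must match base node count")


@dataclass
class FrameSequence:
    """Dense per-node displacement trajectory at uniform time step."""

    times: np.ndarray
    displacements: np.ndarray  # (n_frames, n_nodes, 3)
    dt: float
    frozen_mask: np.ndarray
    base: TriSurface | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class MotionDiagnostics:
    """Per-step space-conservation bookkeeping (volumes in m^3)."""

    volumes: np.ndarray           # V_k per frame
    dV: np.ndarray                # V_{k+1} - V_k per step
    swept_sums: np.ndarray        # sum_j deltaV_j per step
    residuals: np.ndarray         # |dV - sum deltaV_j|
    tolerance: float

    @property
    def passed(self) -> bool:
        return bool(np.all(self.residuals <= self.tolerance))


class TemporalSpline(BaseEstimator):
    """Cubic smoothing spline in the csaps ``p`` convention, per column.

    ``p = 1`` is the interpolating limit (not-a-knot cubic spline, which
    reproduces cubic polynomials exactly); ``p < 1`` trades fit for
    smoothness via lam = (1 - p)/p in the scipy smoothing-spline objective.
    Evaluation is a single linear operator applied to the knot values, so
    fitting thousands of per-node columns costs one small solve per knot.
    """

    def __init__(self, p: float = 0.999):
        self.p = p

    def fit(self, t: np.ndarray, y: np.ndarray) -> "TemporalSpline":
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")
        self.t_ = t
        self.y_ = y.reshape(len(t), -1)
        self._yshape = y.shape[1:]
        return self

    def _operator(self, t_eval: np.ndarray) -> np.ndarray:
        """Matrix M with spline(t_eval) = M @ y, built column-by-column."""
        n = len(self.t_)
        M = np.empty((len(t_eval), n))
        eye = np.eye(n)
        for k in range(n):
            if self.p >= 1.0:
                sp = CubicSpline(self.t_, eye[:, k], bc_type="not-a-knot")
            else:
                sp = make_smoothing_spline(self.t_, eye[:, k],
                                           lam=(1.0 - self.p) / self.p)
            M[:, k] = sp(t_eval)
        return M

    def predict(self, t_eval: np.ndarray) -> np.ndarray:
        if not hasattr(self, "t_"):
            raise RuntimeError("TemporalSpline is not fitted")
        t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
        out = self._operator(t_eval) @ self.y_
        return out.reshape((len(t_eval),) + self._yshape)


def interpolate_in_time(
    keyframes: KeyFrameSet, dt: float = 1e-3, p: float = 0.999
) -> FrameSequence:
    """Densify key-frame displacements to a uniform-step trajectory.

    Phantom knots at t = 0 and t = T carry the early-diastole displacement
    (diastolic hold + periodic closure); frames at or after the last
    key-frame time are frozen at that displacement, and frame 0 (the cycle
    seam inside the diastolic hold) is set to it exactly.
    """
    T = keyframes.cycle_length
    gaps = np.diff(np.concatenate([[0.0], keyframes.phase_times, [T]]))
    if dt >= gaps[gaps > 0].min():
        raise ValueError(f"dt = {dt} not smaller than the smallest key gap")
    if len(keyframes.phase_times) < 3:
        raise ValueError("need at least 3 key-frames")

    d_last = keyframes.displacements[-1]
    knot_t = np.concatenate([[0.0], keyframes.phase_times, [T]])
    knot_y = np.concatenate([d_last[None], keyframes.displacements, d_last[None]])

    n = int(round(T / dt))
    times = np.arange(n) * dt
    t_last = keyframes.phase_times[-1]
    frozen = times >= t_last
    active = ~frozen & (times > 0)

    spline = TemporalSpline(p=p).fit(knot_t, knot_y.reshape(len(knot_t), -1))
    disp = np.empty((n, keyframes.base.n_vertices, 3))
    disp[frozen] = d_last
    disp[0] = d_last
    if active.any():
        disp[active] = spline.predict(times[active]).reshape(-1, keyframes.base.n_vertices, 3)
    frozen_mask = frozen.copy()
    frozen_mask[0] = True
    return FrameSequence(times=times, displacements=disp, dt=dt,
                         frozen_mask=frozen_mask, base=keyframes.base)


def export_frames(
    seq: FrameSequence, base: TriSurface, outdir: str | Path, fmt: str = "vtp"
) -> pd.DataFrame:
    """Write one surface file per step plus a CSV manifest (index, time_s, path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k in range(seq.n_frames):
        name = f"frame_{k:06d}.{fmt}"
        surf = base.copy()
        surf.vertices = base.vertices + seq.displacements[k]
        surf.phase_time = float(seq.times[k])
        try:
            write_surface(surf, outdir / name, fmt)
        except OSError as exc:
            raise OSError(f"failed writing frame {k}: {exc}") from exc
        rows.append({"index": k, "time_s": seq.times[k], "path": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# swept volumes / space conservation
# ---------------------------------------------------------------------------

def _origin_tet_volumes(tri: np.ndarray) -> np.ndarray:
    """Signed origin-tetrahedron volume of each triangle (p, q, r)."""
    return np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0


def swept_volumes(faces: np.ndarray, v0: np.ndarray, v1: np.ndarray) -> np.ndarray:
    """Exact per-face swept volume for linear vertex motion v0 -> v1.

    Each face sweeps a (possibly degenerate) triangular prism. Its signed
    volume is the sum of signed origin-tetrahedra over the prism's closed
    boundary: top/bottom triangles plus three lateral quads, each quad split
    along the diagonal anchored at its smaller global vertex id so that the
    two prisms sharing an edge split the shared quad identically and their
    lateral contributions cancel over a closed surface.
    """
    a0, b0, c0 = v0[faces[:, 0]], v0[faces[:, 1]], v0[faces[:, 2]]
    a1, b1, c1 = v1[faces[:, 0]], v1[faces[:, 1]], v1[faces[:, 2]]
    top = _origin_tet_volumes(np.stack([a1, b1, c1], axis=1))
    bot = -_origin_tet_volumes(np.stack([a0, b0, c0], axis=1))
    total = top + bot
    for i, j in ((0, 1), (1, 2), (2, 0)):
        u, v = faces[:, i], faces[:, j]
        u0, u1 = v0[u], v1[u]
        w0, w1 = v0[v], v1[v]
        # outward lateral quad (u0, w0, w1, u1); split by the diagonal from
        # the endpoint with the smaller global index
        pick = (u < v)[:, None]
        # diagonal from u-side: (u0,w0,w1) + (u0,w1,u1); from v-side: (u0,w0,u1) + (w0,w1,u1)
        t1 = np.where(pick[..., None],
                      np.stack([u0, w0, w1], axis=1),
                      np.stack([u0, w0, u1], axis=1))
        t2 = np.where(pick[..., None],
                      np.stack([u0, w1, u1], axis=1),
                      np.stack([w0, w1, u1], axis=1))
        total += _origin_tet_volumes(t1) + _origin_tet_volumes(t2)
    return total


def grid_velocity(seq: FrameSequence, k: int, base: TriSurface | None = None) -> np.ndarray:
    """Per-face grid-velocity flux v_g,j . A_j = deltaV_j / dt at step k."""
    base = base or seq.base
    if base is None:
        raise ValueError("a base surface is required")
    if k + 1 >= seq.n_frames:
        raise IndexError(f"step {k} has no successor frame")
    v0 = base.vertices + seq.displacements[k]
    v1 = base.vertices + seq.displacements[k + 1]
    return swept_volumes(base.faces, v0, v1) / seq.dt


def check_space_conservation(
    seq: FrameSequence, base: TriSurface | None = None, rel_tol: float = 1e-10
) -> MotionDiagnostics:
    """Verify |V_{k+1} - V_k - sum_j deltaV_j| <= rel_tol * max(V) per step.

    The wall surface must be closed; open inlet/outlet loops are capped
    (the caps then move with their boundary vertices).
    """
    base = base or seq.base
    if base is None:
        raise ValueError("a base surface is required")
    closed = base if base.is_closed() else cap_all_openings(base)
    n_extra = closed.n_vertices - base.n_vertices
    vols = np.empty(seq.n_frames)
    sweeps = np.empty(seq.n_frames - 1)

    def frame_vertices(k: int) -> np.ndarray:
        v = closed.vertices.copy()
        v[: base.n_vertices] += seq.displacements[k]
        if n_extra:
            # cap centroids follow their loops
            for loop_i, loop in enumerate(base.boundary_loops()):
                v[base.n_vertices + loop_i] = v[loop].mean(axis=0)
        return v

    prev = frame_vertices(0)
    surf = closed.copy()
    surf.vertices = prev
    vols[0] = enclosed_volume(surf)
    for k in range(1, seq.n_frames):
        cur = frame_vertices(k)
        sweeps[k - 1] = swept_volumes(closed.faces, prev, cur).sum()
        surf.vertices = cur
        vols[k] = enclosed_volume(surf)
        prev = cur
    dV = np.diff(vols)
    residuals = np.abs(dV - sweeps)
    return MotionDiagnostics(volumes=vols, dV=dV, swept_sums=sweeps,
                             residuals=residuals, tolerance=rel_tol * vols.max())


def displacement_stats(seq: FrameSequence, inlet_radius: float) -> pd.DataFrame:
    """Per-node time-averaged displacement normalized by the inlet radius.

    Returns columns ``magnitude, x, y, z``: cycle averages of |d| and of the
    signed components, each divided by ``inlet_radius`` (dimensionless, for
    surface maps like the normalized-displacement figures of compliant-aorta
    studies).
    """
    if inlet_radius <= 0:
        raise ValueError("inlet_radius must be positive")
    mag = np.linalg.norm(seq.displacements, axis=2).mean(axis=0) / inlet_radius
    comp = seq.displacements.mean(axis=0) / inlet_radius
    return pd.DataFrame({"magnitude": mag, "x": comp[:, 0],
                         "y": comp[:, 1], "z": comp[:, 2]})
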