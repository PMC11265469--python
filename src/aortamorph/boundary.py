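"""MRI-derived boundary conditions: inlet velocity profiles and outlet
flow splits.

The inlet pipeline mirrors clinical 4D-flow practice: scattered
three-component velocity samples per MRI phase (~30-40 ms apart) are
linearly interpolated in time to the CFD step, rigidly registered onto the
(possibly moving) inlet plane, and projected onto the inlet mesh nodes by
inverse-distance weighting. Outlet fractions follow w_n = Q_n / Q_i with a
final rescale w_N = w_n / sum(w_n) so the fractions always sum to one.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .mesh import Plane, TriSurface, face_normals_areas

logger = logging.getLogger(__name__)

_SPEED_SANITY = 10.0  # m/s; 4D-flow VENC is an order of magnitude below this


@dataclass
class VelocitySampleSeries:
    """Scattered velocity samples on the inlet plane, one set per MRI phase.

    ``positions`` is shared across phases (same acquisition grid);
    ``velocities`` has shape (n_phases, n_samples, 3).
    """

    phase_times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    plane: Plane | None = None

    def __post_init__(self) -> None:
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if np.any(np.diff(self.phase_times) <= 0):
            raise ValueError("phase times must be strictly increasing")
        if self.positions.shape[0] < 3:
            raise ValueError("each phase needs >= 3 samples")
        if self.velocities.shape != (len(self.phase_times),) + self.positions.shape:
            raise ValueError("velocities must be (n_phases, n_samples, 3)")
        speeds = np.linalg.norm(self.velocities, axis=2)
        if not np.all(np.isfinite(speeds)) or speeds.max(initial=0.0) >= _SPEED_SANITY:
            raise ValueError(f"sample speeds must be finite and < {_SPEED_SANITY} m/s")


@dataclass
class FlowSplit:
    """Raw (w_n) and rescaled (w_N) per-outlet flow fractions per time step."""

    outlet_ids: list
    Q_n: np.ndarray          # (n_steps, m)
    Q_i: np.ndarray          # (n_steps,)
    w_n: np.ndarray
    w_N: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w_N, columns=[f"w_N[{o}]" for o in self.outlet_ids])


# ---------------------------------------------------------------------------
# time interpolation
# ---------------------------------------------------------------------------

def interp_velocity_time(series: VelocitySampleSeries, t: float,
                         cycle_length: float | None = None) -> np.ndarray:
    """Velocity samples linearly interpolated between bracketing MRI phases.

    At a phase time the phase is returned exactly. ``t`` beyond the last
    phase wraps cyclically toward phase 0 at t = ``cycle_length`` when given.
    """
    pt = series.phase_times
    if t < pt[0] or t > pt[-1]:
        if cycle_length is None:
            raise ValueError(f"t = {t} outside phase range and no cycle_length for wrap")
        t = t % cycle_length
        if t > pt[-1]:
            # interpolate across the seam toward phase 0 at t = T
            frac = (t - pt[-1]) / (cycle_length - pt[-1])
            return (1 - frac) * series.velocities[-1] + frac * series.velocities[0]
    k = int(np.searchsorted(pt, t, side="right") - 1)
    k = min(max(k, 0), len(pt) - 2)
    if t == pt[k]:
        return series.velocities[k].copy()
    frac = (t - pt[k]) / (pt[k + 1] - pt[k])
    return (1 - frac) * series.velocities[k] + frac * series.velocities[k + 1]


# ---------------------------------------------------------------------------
# inverse-distance projection
# ---------------------------------------------------------------------------

class IDWInterpolator(BaseEstimator):
    """Inverse-distance-weighted vector interpolation over k nearest samples.

    v(x) = sum_i w_i v_i / sum_i w_i, w_i = |x - x_i|^-power over the
    ``k_neighbors`` nearest sources (``k_neighbors=None`` uses all sources,
    the exactness/testing mode). A query coinciding with a source (distance
    < 1e-12 m) returns that source's value exactly.
    """

    def __init__(self, power: float = 2.0, k_neighbors: int | None = 8):
        self.power = power
        self.k_neighbors = k_neighbors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "IDWInterpolator":
        X = np.asarray(X, dtype=float).reshape(-1, 3)
        if len(X) == 0:
            raise ValueError("empty sample set")
        self.X_ = X
        self.y_ = np.asarray(y, dtype=float).reshape(len(X), -1)
        self.tree_ = cKDTree(X)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "tree_"):
            raise RuntimeError("IDWInterpolator is not fitted")
        X = np.asarray(X, dtype=float).reshape(-1, 3)
        k = len(self.X_) if self.k_neighbors is None else min(self.k_neighbors, len(self.X_))
        dist, idx = self.tree_.query(X, k=k)
        dist = np.atleast_2d(dist.reshape(len(X), k))
        idx = idx.reshape(len(X), k)
        exact = dist[:, 0] < 1e-12
        with np.errstate(divide="ignore"):
            w = dist ** (-self.power)
        w[exact] = 0.0
        out = np.einsum("nk,nkc->nc", w, self.y_[idx]) / np.where(
            exact, 1.0, w.sum(axis=1))[:, None]
        out[exact] = self.y_[idx[exact, 0]]
        return out


def idw_project(positions: np.ndarray, velocities: np.ndarray,
                target_points: np.ndarray, power: float = 2.0,
                k_neighbors: int | None = 8) -> np.ndarray:
    """Functional wrapper over :class:`IDWInterpolator`."""
    model = IDWInterpolator(power=power, k_neighbors=k_neighbors)
    return model.fit(positions, velocities).predict(target_points)


# ---------------------------------------------------------------------------
# registration onto the (moving) inlet
# ---------------------------------------------------------------------------

def _plane_frame(points: np.ndarray, normal_hint: np.ndarray | None = None):
    """Centroid and best-fit unit normal of a point set (SVD plane fit)."""
    c = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - c, full_matrices=False)
    n = vt[-1]
    if normal_hint is not None and np.dot(n, normal_hint) < 0:
        n = -n
    return c, n


def register_to_inlet(
    sample_positions: np.ndarray,
    sample_velocities: np.ndarray,
    inlet_points: np.ndarray,
    source_plane: Plane | None = None,
    inlet_normal_hint: np.ndarray | None = None,
    power: float = 2.0,
    k_neighbors: int | None = 8,
) -> np.ndarray:
    """Rigidly align the MRI sample plane onto the current inlet and project.

    The source frame (centroid + normal) is mapped onto the inlet frame by
    the minimal rotation taking normal to normal (in-plane axes follow with
    no extra twist), sources are transported into the inlet frame, velocities
    are rotated with the same rigid transform, and IDW projection evaluates
    them at the inlet nodes. Rotating the vectors with the plane preserves
    the through-plane volumetric flux under any rigid inlet motion.
    """
    from .morphing import _minimal_rotation

    if len(inlet_points) < 3:
        raise ValueError("degenerate inlet: need >= 3 nodes")
    if source_plane is not None:
        c_s, n_s = source_plane.origin, source_plane.normal
    else:
        c_s, n_s = _plane_frame(sample_positions)
    c_t, n_t = _plane_frame(inlet_points, normal_hint=inlet_normal_hint)
    if np.dot(n_s, n_t) < 0:  # keep through-plane direction consistent
        n_t = -n_t
    R = _minimal_rotation(n_s, n_t)
    moved = (sample_positions - c_s) @ R.T + c_t
    vrot = sample_velocities @ R.T
    return idw_project(moved, vrot, inlet_points, power=power, k_neighbors=k_neighbors)


# ---------------------------------------------------------------------------
# flows and splits
# ---------------------------------------------------------------------------

def flow_through_opening(surface: TriSurface, label: str,
                         nodal_velocities: np.ndarray) -> float:
    """Net flow Q [m^3/s] through the faces labeled ``label`` (midpoint rule).

    Q = sum_faces (mean nodal velocity . face normal) * area.
    """
    mask = surface.region_labels == label
    if not mask.any():
        raise KeyError(f"no faces labeled {label!r}")
    normals, areas = face_normals_areas(surface, check_degenerate=False)
    v_face = np.asarray(nodal_velocities, dtype=float)[surface.faces[mask]].mean(axis=1)
    return float(np.einsum("ij,ij->i", v_face, normals[mask]) @ areas[mask])


def flow_through_plane(points: np.ndarray, faces: np.ndarray,
                       nodal_velocities: np.ndarray,
                       normal: np.ndarray | None = None) -> float:
    """Net flow through an arbitrary planar triangulation of an opening."""
    surf = TriSurface(points, faces)
    n, a = face_normals_areas(surf, check_degenerate=False)
    if normal is not None:
        normal = np.asarray(normal, float)
        sign = np.sign(n @ normal)
        n = n * sign[:, None]
    v_face = np.asarray(nodal_velocities, float)[faces].mean(axis=1)
    return float(np.einsum("ij,ij->i", v_face, n) @ a)


def branch_flow(Q_upstream: np.ndarray | float, Q_downstream: np.ndarray | float):
    """Net branch flow from planes bracketing a bifurcation."""
    return np.asarray(Q_upstream, dtype=float) - np.asarray(Q_downstream, dtype=float)


def compute_flow_split(Q_n: np.ndarray, Q_i: np.ndarray,
                       outlet_ids: list | None = None) -> FlowSplit:
    """Per-step outlet fractions w_n = Q_n/Q_i rescaled to w_N summing to 1.

    Retrograde (negative) flows stay signed; a warning is emitted because
    negative fractions change the meaning of an outflow boundary condition.
    """
    Q_n = np.atleast_2d(np.asarray(Q_n, dtype=float))
    Q_i = np.asarray(Q_i, dtype=float).reshape(-1)
    if Q_n.shape[0] != len(Q_i):
        raise ValueError("Q_n must have one row per Q_i time step")
    if np.any(Q_i == 0):
        raise ValueError(f"zero inlet flow at steps {np.nonzero(Q_i == 0)[0].tolist()}")
    w_n = Q_n / Q_i[:, None]
    sums = w_n.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError(f"degenerate steps with sum w_n = 0: "
                         f"{np.nonzero(sums == 0)[0].tolist()}")
    w_N = w_n / sums[:, None]
    if np.any(w_N < 0):
        logger.warning("retrograde outlet flow: negative fractions at %d steps",
                       int(np.any(w_N < 0, axis=1).sum()))
    ids = outlet_ids if outlet_ids is not None else list(range(1, Q_n.shape[1] + 1))
    return FlowSplit(outlet_ids=ids, Q_n=Q_n, Q_i=Q_i, w_n=w_n, w_N=w_N)


# ---------------------------------------------------------------------------
# profile export (CSV + solver transient-profile dialect)
# ---------------------------------------------------------------------------

def write_profiles_csv(times: np.ndarray, nodal_velocities: np.ndarray,
                       points: np.ndarray, path: str | Path) -> None:
    """Plain long-format CSV: time_s, node_id, x, y, z, vx, vy, vz."""
    times = np.asarray(times, float)
    v = np.asarray(nodal_velocities, float)
    n = v.shape[1]
    rows = {
        "time_s": np.repeat(times, n),
        "node_id": np.tile(np.arange(n), len(times)),
        "x": np.tile(points[:, 0], len(times)),
        "y": np.tile(points[:, 1], len(times)),
        "z": np.tile(points[:, 2], len(times)),
        "vx": v[:, :, 0].ravel(),
        "vy": v[:, :, 1].ravel(),
        "vz": v[:, :, 2].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9e")


def write_transient_profile(name: str, times: np.ndarray, points: np.ndarray,
                            nodal_velocities: np.ndarray, path: str | Path) -> None:
    """Solver transient-profile ASCII dialect (s-expression blocks, %.9e).

    Layout::

        ((name transient n_points n_times)
         (time (t0 t1 ...))
         (x (...)) (y (...)) (z (...))
         (vx (... per time, point-major ...)) (vy ...) (vz ...))
    """
    times = np.asarray(times, float)
    pts = np.asarray(points, float)
    v = np.asarray(nodal_velocities, float)

    def vec(a: np.ndarray) -> str:
        return " ".join(f"{x:.9e}" for x in np.asarray(a).ravel())

    blocks = [f"(({name} transient {len(pts)} {len(times)})",
              f" (time ({vec(times)}))"]
    for lab, col in zip(("x", "y", "z"), pts.T):
        blocks.append(f" ({lab} ({vec(col)}))")
    for lab, comp in zip(("vx", "vy", "vz"), np.moveaxis(v, 2, 0)):
        blocks.append(f" ({lab} ({vec(comp)}))")
    Path(path).write_text("\n".join(blocks) + ")\n")


def read_transient_profile(path: str | Path) -> dict:
    """Round-trip reader for :func:`write_transient_profile`."""
    text = Path(path).read_text()
    m = re.match(r"\(\((\S+) transient (\d+) (\d+)\)", text)
    if m is None:
        raise ValueError(f"{path}: not a transient profile file")
    name, n_pts, n_t = m.group(1), int(m.group(2)), int(m.group(3))
    fields = {}
    for fm in re.finditer(r"\((\w+) \(([^()]*)\)\)", text):
        vals = np.array(fm.group(2).split(), dtype=float)
        fields[fm.group(1)] = vals
    out = {"name": name, "time": fields["time"],
           "points": np.column_stack([fields["x"], fields["y"], fields["z"]])}
    out["velocities"] = np.stack(
        [fields[c].reshape(n_t, n_pts) for c in ("vx", "vy", "vz")], axis=2)
    return out
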