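"""Analytically known synthetic inputs: a moving idealized aorta, MRI-like
inlet velocity series, and wall-shear series with closed-form biomarkers.

The phantom is a U-bend tube (ascending straight, 180-degree arch,
descending straight) whose wall moves with the two dominant components of
aortic kinematics: radial compliance (relative amplitude ``eps``) and a
feet-head translation of the root (``delta_fh``), both largest proximally
and decaying exponentially along the arc length — the descending aorta is
braced by the spine and barely moves. The systolic waveform is a half-sine
over ``t_sys`` followed by a flat diastole, consistent with the modeling
assumption that the aorta is motionless during diastole.

Every generator is a pure function of (params, seed): identical inputs give
bitwise-identical outputs. Each generator also returns its exact ground
truth (displacement fields, flow rates, TAWSS/OSI), which is what makes the
rest of the pipeline testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .boundary import VelocitySampleSeries
from .hemodynamics import WallShearSeries
from .mesh import Plane, TriSurface
from .timeline import FrameSequence, KeyFrameSet

FH_AXIS = np.array([0.0, 0.0, 1.0])  # feet-head direction (config axis, +z)


@dataclass(frozen=True)
class AortaPhantomParams:
    """Stated world of the phantom; defaults emulate a healthy adult aorta.

    Lengths in meters, times in seconds. ``radial_amplitude`` ~5% matches
    reported thoracic diameter changes of 1.7-3.6 mm on a ~30 mm vessel;
    ``root_axial_amplitude`` 9 mm matches reported feet-head root excursion.
    ``aneurysm`` is (arc-length center, Gaussian width, radius amplification)
    or None.
    """

    ascending_length: float = 0.07
    arch_radius: float = 0.03
    descending_length: float = 0.12
    base_radius: float = 1.49e-2
    radial_amplitude: float = 0.05
    root_axial_amplitude: float = 9e-3
    motion_decay_length: float = 0.08
    aneurysm: tuple | None = None
    t_sys: float = 0.35
    cycle_length: float = 60.0 / 61.0
    n_axial: int = 80
    n_circ: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if not (0 <= self.radial_amplitude < 0.5):
            raise ValueError("radial_amplitude must lie in [0, 0.5)")
        if not (0 < self.t_sys < self.cycle_length):
            raise ValueError("need 0 < t_sys < cycle_length")
        if self.aneurysm is not None:
            _, _, amp = self.aneurysm
            if amp < 1:
                raise ValueError("aneurysm amplification must be >= 1")
            if self.base_radius * amp >= self.arch_radius:
                raise ValueError("aneurysm bulge would self-intersect the arch")

    @property
    def total_length(self) -> float:
        return self.ascending_length + np.pi * self.arch_radius + self.descending_length

    @property
    def t_peak(self) -> float:
        return 0.5 * self.t_sys


def healthy_preset(**overrides) -> AortaPhantomParams:
    """Healthy control: inlet radius 1.49e-2 m, no bulge, HR 61 bpm."""
    return replace(AortaPhantomParams(), **overrides)


def patient_preset(**overrides) -> AortaPhantomParams:
    """Root-aneurysm patient: inlet radius 1.58e-2 m, proximal bulge
    amplified to a ~50 mm diameter, HR 49 bpm."""
    base = AortaPhantomParams(
        base_radius=1.58e-2,
        aneurysm=(0.045, 0.012, 1.58),
        cycle_length=60.0 / 49.0,
    )
    return replace(base, **overrides)


PRESETS = {"healthy": healthy_preset, "patient": patient_preset}


# ---------------------------------------------------------------------------
# analytic geometry
# ---------------------------------------------------------------------------

def waveform(params: AortaPhantomParams, t) -> np.ndarray:
    """Half-sine systole, flat (zero) diastole; peaks at t_sys/2."""
    t = np.asarray(t, dtype=float) % params.cycle_length
    w = np.sin(np.pi * t / params.t_sys)
    return np.where(t <= params.t_sys, w, 0.0)


def _decay(params: AortaPhantomParams, s: np.ndarray) -> np.ndarray:
    return np.exp(-np.asarray(s, dtype=float) / params.motion_decay_length)


def _bulge(params: AortaPhantomParams, s: np.ndarray) -> np.ndarray:
    if params.aneurysm is None:
        return np.ones_like(np.asarray(s, dtype=float))
    s0, width, amp = params.aneurysm
    return 1.0 + (amp - 1.0) * np.exp(-((np.asarray(s, float) - s0) ** 2) / (2 * width**2))


def centerline(params: AortaPhantomParams, s: np.ndarray):
    """Centerline points and unit tangents at arc lengths ``s`` (U-bend)."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    La, R = params.ascending_length, params.arch_radius
    arch_end = La + np.pi * R
    pts = np.empty((len(s), 3))
    tan = np.empty((len(s), 3))
    asc = s <= La
    pts[asc] = np.column_stack([np.zeros(asc.sum()), np.zeros(asc.sum()), s[asc]])
    tan[asc] = [0.0, 0.0, 1.0]
    arch = (s > La) & (s <= arch_end)
    phi = (s[arch] - La) / R
    pts[arch] = np.column_stack([R * (1 - np.cos(phi)), np.zeros(arch.sum()),
                                 La + R * np.sin(phi)])
    tan[arch] = np.column_stack([np.sin(phi), np.zeros(arch.sum()), np.cos(phi)])
    desc = s > arch_end
    pts[desc] = np.column_stack([np.full(desc.sum(), 2 * R), np.zeros(desc.sum()),
                                 La - (s[desc] - arch_end)])
    tan[desc] = [0.0, 0.0, -1.0]
    return pts, tan


def centerline_path(params: AortaPhantomParams, n: int = 400,
                    t: float | None = None) -> np.ndarray:
    """Dense centerline polyline, the lumen path input for control points.

    Includes the feet-head root offset at time ``t`` (default: peak systole,
    matching the base surface the control points are cast from).
    """
    s = np.linspace(0.0, params.total_length, n)
    pts = centerline(params, s)[0]
    t = params.t_peak if t is None else t
    w = float(waveform(params, t))
    offset = params.root_axial_amplitude * w * _decay(params, s)
    return pts + offset[:, None] * FH_AXIS


def _tube_points(params: AortaPhantomParams, t: float) -> np.ndarray:
    """Exact wall vertex positions at time t on the (s, theta) lattice."""
    s = np.linspace(0.0, params.total_length, params.n_axial)
    theta = 2 * np.pi * np.arange(params.n_circ) / params.n_circ
    C, T = centerline(params, s)
    e1 = np.tile(np.array([0.0, 1.0, 0.0]), (len(s), 1))
    e2 = np.cross(T, e1)
    w = float(waveform(params, t))
    h = _decay(params, s)
    g = _bulge(params, s)
    radius = params.base_radius * g * (1.0 + params.radial_amplitude * w * h)
    offset = params.root_axial_amplitude * w * h
    ring = (np.cos(theta)[None, :, None] * e1[:, None, :]
            + np.sin(theta)[None, :, None] * e2[:, None, :])
    pts = (C[:, None, :] + offset[:, None, None] * FH_AXIS
           + radius[:, None, None] * ring)
    return pts.reshape(-1, 3)


def _tube_faces(n_axial: int, n_circ: int) -> np.ndarray:
    i = np.arange(n_axial - 1)[:, None]
    j = np.arange(n_circ)[None, :]
    jn = (j + 1) % n_circ
    v00 = i * n_circ + j
    v01 = i * n_circ + jn
    v10 = (i + 1) * n_circ + j
    v11 = (i + 1) * n_circ + jn
    f1 = np.stack([v00, v01, v11], axis=2).reshape(-1, 3)
    f2 = np.stack([v00, v11, v10], axis=2).reshape(-1, 3)
    return np.vstack([f1, f2])


def make_phantom_surface(params: AortaPhantomParams, t: float):
    """Phantom wall surface at time ``t`` plus its exact displacement field.

    Returns ``(surface, displacement)`` where ``displacement`` is the
    per-vertex ground-truth motion relative to peak systole (zero at
    ``t = t_peak`` by construction). The tube is open at both ends; the
    rings are registered as openings ``inlet`` (s = 0) and ``outlet:1``.
    """
    pts = _tube_points(params, t)
    ref = _tube_points(params, params.t_peak)
    faces = _tube_faces(params.n_axial, params.n_circ)
    surf = TriSurface(pts, faces, phase_time=float(t))
    # consistent outward orientation (fixed lattice -> fixed winding check)
    from .mesh import face_normals_areas

    n0, _ = face_normals_areas(surf, check_degenerate=False)
    centroid0 = pts[faces[0]].mean(axis=0)
    axis_pt = centerline(params, np.array([0.0]))[0][0]
    if np.dot(n0[0], centroid0 - axis_pt) < 0:
        surf.faces = surf.faces[:, ::-1]
    nc = params.n_circ
    surf.openings["inlet"] = np.arange(nc, dtype=np.int64)[::-1]
    surf.openings["outlet:1"] = np.arange((params.n_axial - 1) * nc,
                                          params.n_axial * nc, dtype=np.int64)
    return surf, pts - ref


def analytic_displacement(params: AortaPhantomParams, t) -> np.ndarray:
    """Closed-form displacement field(s) relative to peak systole.

    For scalar ``t`` returns (n_vertices, 3); for a time vector returns
    (n_t, n_vertices, 3). The field is
    ``R0 g(s) eps (w(t)-1) h(s) r_hat + delta_fh (w(t)-1) h(s) e_fh``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    s = np.linspace(0.0, params.total_length, params.n_axial)
    theta = 2 * np.pi * np.arange(params.n_circ) / params.n_circ
    _, T = centerline(params, s)
    e1 = np.tile(np.array([0.0, 1.0, 0.0]), (len(s), 1))
    e2 = np.cross(T, e1)
    rhat = (np.cos(theta)[None, :, None] * e1[:, None, :]
            + np.sin(theta)[None, :, None] * e2[:, None, :])
    h = _decay(params, s)
    g = _bulge(params, s)
    radial = (params.base_radius * g * params.radial_amplitude * h)[:, None, None] * rhat
    axial = (params.root_axial_amplitude * h)[:, None, None] * FH_AXIS
    per_vertex = (radial + axial).reshape(-1, 3)
    dw = waveform(params, t_arr) - 1.0
    out = dw[:, None, None] * per_vertex[None]
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


DEFAULT_PHASES = ("mid-acceleration", "peak systole", "mid-deceleration", "early diastole")


def keyframe_times(params: AortaPhantomParams) -> np.ndarray:
    """Default key-frame instants: quarter points of systole plus its end."""
    ts = params.t_sys
    return np.array([0.25 * ts, 0.5 * ts, 0.75 * ts, ts])


def make_keyframes(params: AortaPhantomParams, phases: np.ndarray | None = None,
                   dt: float = 1e-3):
    """Key-frame set plus the dense analytic ground-truth trajectory.

    Returns ``(KeyFrameSet, FrameSequence)``; the sequence holds the exact
    displacement at every step of the cycle (for parameter-recovery tests).
    """
    times = keyframe_times(params) if phases is None else np.asarray(phases, float)
    base, _ = make_phantom_surface(params, params.t_peak)
    disp = analytic_displacement(params, times)
    kfs = KeyFrameSet(phase_times=times, displacements=disp,
                      cycle_length=params.cycle_length, base=base)
    n = int(round(params.cycle_length / dt))
    t_dense = np.arange(n) * dt
    truth = FrameSequence(
        times=t_dense,
        displacements=analytic_displacement(params, t_dense),
        dt=dt,
        frozen_mask=t_dense >= times[-1],
        base=base,
    )
    return kfs, truth


# ---------------------------------------------------------------------------
# MRI-like inlet series
# ---------------------------------------------------------------------------

def make_inlet_series(
    params: AortaPhantomParams,
    n_phases: int = 34,
    sample_spacing: float = 2.5e-3,
    peak_velocity: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[VelocitySampleSeries, dict]:
    """Poiseuille inlet samples on a jittered MRI-like grid, one set per phase.

    Returns the series and a ground-truth dict with the peak flow rate
    ``Q_peak = u0 pi R^2 / 2`` and the per-phase flow ``Q(t)``. Noise is
    seeded Gaussian on each velocity component (VENC-like).
    """
    if n_phases < 4:
        raise ValueError("need at least 4 MRI phases")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    R = params.base_radius
    half = int(np.floor(R / sample_spacing))
    coords = sample_spacing * np.arange(-half, half + 1)
    gx, gy = np.meshgrid(coords, coords)
    jitter = rng.uniform(-0.15, 0.15, size=(2,) + gx.shape) * sample_spacing
    gx = gx + jitter[0]
    gy = gy + jitter[1]
    r2 = gx**2 + gy**2
    keep = r2 <= (0.98 * R) ** 2
    # inlet plane at s=0: normal +z, in-plane axes x, y
    pos = np.column_stack([gx[keep], gy[keep], np.zeros(keep.sum())])
    rr2 = r2[keep]
    times = np.linspace(0.0, params.cycle_length, n_phases, endpoint=False)
    w = waveform(params, times)
    profile = peak_velocity * (1.0 - rr2 / R**2)
    vel = np.zeros((n_phases, keep.sum(), 3))
    vel[:, :, 2] = w[:, None] * profile[None, :]
    if noise_sigma > 0:
        vel = vel + rng.normal(0.0, noise_sigma, size=vel.shape)
    series = VelocitySampleSeries(
        phase_times=times, positions=pos, velocities=vel,
        plane=Plane(origin=np.zeros(3), normal=FH_AXIS),
    )
    truth = {
        "Q_peak": peak_velocity * np.pi * R**2 / 2.0,
        "Q_t": peak_velocity * np.pi * R**2 / 2.0 * w,
        "peak_velocity": peak_velocity,
        "radius": R,
    }
    return series, truth


# ---------------------------------------------------------------------------
# wall-shear series with closed-form biomarkers
# ---------------------------------------------------------------------------

def make_wss_series(
    node_count: int,
    cycle_length: float = 1.0,
    pattern: str = "mean_plus_sinusoid",
    seed: int = 0,
    n_times: int = 200,
) -> tuple[WallShearSeries, dict]:
    """Per-node shear series plus exact TAWSS/OSI ground truth.

    Patterns: ``constant`` (TAWSS = |tau|, OSI = 0), ``sinusoid`` (zero-mean:
    TAWSS = 2|tau0|/pi, OSI = 0.5), ``mean_plus_sinusoid`` (non-reversing,
    |B| <= |A|: TAWSS = A, OSI = 0), ``reversing`` (|B| > |A|: ground truth
    from dense quadrature of the closed-form signal).
    """
    if node_count < 1:
        raise ValueError("node_count must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, cycle_length, n_times, endpoint=False)
    dirs = rng.normal(size=(node_count, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phase = np.sin(2 * np.pi * t / cycle_length)

    if pattern == "constant":
        amp = rng.uniform(0.5, 3.0, node_count)
        wss = np.broadcast_to((amp[:, None] * dirs)[None], (n_times, node_count, 3)).copy()
        truth = {"tawss": amp, "osi": np.zeros(node_count)}
    elif pattern == "sinusoid":
        amp = rng.uniform(0.5, 3.0, node_count)
        wss = phase[:, None, None] * (amp[:, None] * dirs)[None]
        truth = {"tawss": 2.0 * amp / np.pi, "osi": np.full(node_count, 0.5)}
    elif pattern == "mean_plus_sinusoid":
        A = rng.uniform(1.0, 3.0, node_count)
        B = A * rng.uniform(0.0, 1.0, node_count)
        wss = (A[None, :, None] + B[None, :, None] * phase[:, None, None]) * dirs[None]
        truth = {"tawss": A, "osi": np.zeros(node_count)}
    elif pattern == "reversing":
        A = rng.uniform(0.2, 1.0, node_count)
        B = A * rng.uniform(1.5, 4.0, node_count)
        wss = (A[None, :, None] + B[None, :, None] * phase[:, None, None]) * dirs[None]
        tf = np.linspace(0.0, cycle_length, 200001)
        sig = A[None, :] + B[None, :] * np.sin(2 * np.pi * tf / cycle_length)[:, None]
        mag_int = np.trapezoid(np.abs(sig), tf, axis=0)
        vec_int = np.abs(np.trapezoid(sig, tf, axis=0))
        truth = {"tawss": mag_int / cycle_length,
                 "osi": 0.5 * (1.0 - vec_int / mag_int)}
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    series = WallShearSeries(times=t, wss=np.ascontiguousarray(wss),
                             cycle_length=cycle_length)
    return series, truth
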