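"""Blood rheology and wall-shear-derived biomarkers.

Viscosity follows the Carreau-Yasuda shear-thinning law

    mu_app(gdot) = mu_inf + (mu_0 - mu_inf) [1 + (lambda gdot)^alpha]^((n-1)/alpha)

with the parameter set commonly used for whole blood (mu_inf = 2.2 mPa s,
mu_0 = 22 mPa s, lambda = 0.110 s, alpha = 0.644, n = 0.392, rho = 1060
kg/m^3). The wall biomarkers are the cycle-averaged wall-shear magnitude
(TAWSS), the oscillatory shear index

    OSI = 1/2 (1 - |int tau_w dt| / int |tau_w| dt)  in [0, 1/2],

and the symmetric percentage difference between a static-wall and a
moving-wall result,

    dphi = (phi_stat - phi_dyn) / (0.5 (phi_stat + phi_dyn)) * 100  in [-200, 200].

Cycle integrals use trapezoidal quadrature with an explicit periodic closing
segment from the last sample back to t = T using the first sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RheologyParams:
    """Carreau-Yasuda parameters and density for whole blood."""

    mu_inf: float = 2.2e-3   # Pa s, infinite-shear viscosity
    mu_0: float = 22e-3      # Pa s, zero-shear viscosity
    lam: float = 0.110       # s, relaxation time
    alpha: float = 0.644     # shape parameter
    n_index: float = 0.392   # power-law index (< 1: shear-thinning)
    rho: float = 1060.0      # kg/m^3

    def __post_init__(self) -> None:
        if not (self.mu_0 > self.mu_inf > 0):
            raise ValueError("need mu_0 > mu_inf > 0")
        if self.lam <= 0 or self.alpha <= 0 or self.rho <= 0:
            raise ValueError("lambda, alpha, rho must be positive")
        if not (0 < self.n_index < 1):
            raise ValueError("power-law index must be in (0, 1) for shear-thinning blood")


BLOOD = RheologyParams()


def carreau_yasuda(shear_rate, params: RheologyParams = BLOOD):
    """Apparent viscosity [Pa s] at shear rate(s) gdot >= 0 (inf allowed)."""
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    with np.errstate(over="ignore"):
        term = (1.0 + (params.lam * g) ** params.alpha) ** (
            (params.n_index - 1.0) / params.alpha)
    term = np.where(np.isinf(g), 0.0, term)
    out = params.mu_inf + (params.mu_0 - params.mu_inf) * term
    return float(out) if out.ndim == 0 else out


@dataclass
class WallShearSeries:
    """Per-node wall-shear-stress vectors over one cardiac cycle."""

    times: np.ndarray           # (n_t,), first 0, last <= T
    wss: np.ndarray             # (n_t, n_nodes, 3) Pa
    cycle_length: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wss = np.asarray(self.wss, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0 or self.times[-1] > self.cycle_length:
            raise ValueError("times must start at 0 and end within the cycle")
        if not np.all(np.isfinite(self.wss)):
            raise ValueError("non-finite wall shear stresses")

    @property
    def node_count(self) -> int:
        return self.wss.shape[1]


def _cycle_quadrature(series: WallShearSeries):
    """Times/values closed periodically back to t = T with the first sample."""
    if len(series.times) < 2:
        raise ValueError("need at least two time points for a cycle integral")
    if series.times[-1] < series.cycle_length:
        t = np.concatenate([series.times, [series.cycle_length]])
        w = np.concatenate([series.wss, series.wss[:1]], axis=0)
    else:
        t, w = series.times, series.wss
    return t, w


def tawss(series: WallShearSeries) -> np.ndarray:
    """Time-averaged wall shear stress (1/T) int_0^T |tau_w| dt, per node."""
    t, w = _cycle_quadrature(series)
    mag = np.linalg.norm(w, axis=2)
    return np.trapezoid(mag, t, axis=0) / series.cycle_length


def osi(series: WallShearSeries, denom_floor: float = 1e-30) -> np.ndarray:
    """Oscillatory shear index in [0, 0.5]; undefined nodes return NaN.

    A node whose shear magnitude integrates below ``denom_floor`` (Pa s) has
    no meaningful direction and is flagged NaN rather than raising.
    """
    t, w = _cycle_quadrature(series)
    num = np.linalg.norm(np.trapezoid(w, t, axis=0), axis=1)
    den = np.trapezoid(np.linalg.norm(w, axis=2), t, axis=0)
    out = np.full(series.node_count, np.nan)
    ok = den > denom_floor
    out[ok] = np.clip(0.5 * (1.0 - num[ok] / den[ok]), 0.0, 0.5)
    return out


def percent_difference(phi_stat: np.ndarray, phi_dyn: np.ndarray) -> np.ndarray:
    """Symmetric percentage difference, antisymmetric and bounded in [-200, 200].

    Nodes where both fields vanish are defined as 0 (the 0/0 case).
    The dynamic map is assumed projected onto the peak-systole surface by
    node identity (morphing preserves node ids), so inputs must align.
    """
    a = np.asarray(phi_stat, dtype=float)
    b = np.asarray(phi_dyn, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"node counts differ: {a.shape} vs {b.shape}")
    mean = 0.5 * (a + b)
    out = np.zeros_like(a)
    nz = mean != 0
    out[nz] = (a[nz] - b[nz]) / mean[nz] * 100.0
    return out


def summarize_map(values: np.ndarray, mask: np.ndarray | None = None) -> dict:
    """Mean, std, median of |values| over the masked nodes (side branches off)."""
    v = np.asarray(values, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        v = v[mask]
    elif v.size == 0:
        raise ValueError("empty value array")
    av = np.abs(v)
    return {"mean": float(av.mean()), "std": float(av.std()),
            "median": float(np.median(av))}


def reynolds(D: float, Q: float | None = None, U: float | None = None,
             params: RheologyParams = BLOOD, viscosity: str | float = "mu_inf") -> float:
    """Reynolds number rho U D / mu; U = 4 Q / (pi D^2) when flow is given.

    ``viscosity`` selects ``mu_inf`` (default) or ``mu_0``, or is a value in
    Pa s. Which viscosity underlies a published Re is often unstated, so the
    choice is explicit here.
    """
    if D <= 0:
        raise ValueError("diameter must be positive")
    if (Q is None) == (U is None):
        raise ValueError("give exactly one of Q or U")
    if U is None:
        U = 4.0 * Q / (np.pi * D**2)
    if isinstance(viscosity, str):
        mu = {"mu_inf": params.mu_inf, "mu_0": params.mu_0}[viscosity]
    else:
        mu = float(viscosity)
    return params.rho * U * D / mu
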