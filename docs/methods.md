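# Methods

`aortamorph` implements the pre- and post-processing around an image-based
CFD simulation of a compliant (moving-wall) aorta. The Navier–Stokes solve
itself is assumed to happen in external solver software; this package
produces everything such a solver consumes (moving surface geometry at every
time step, inlet velocity profiles, outlet flow fractions) and everything
one computes from its output (TAWSS, OSI, static-vs-dynamic difference
maps, validation distances).

## The morphing model

The vessel wall motion over one cardiac cycle of length `T` is reconstructed
from a small number of segmented key-frame surfaces (typically four:
mid-acceleration, peak systole, mid-deceleration, early diastole). Dense
surface correspondence between segmentations is never available, so the
motion is encoded sparsely:

1. **Control points.** On each key-frame surface a structured `i x j` grid
   is sampled: `i` cross-sectional planes along a user-supplied lumen path,
   `j` rays per plane cast at equal angles from the path point to the wall.
   The angular phase is carried between planes by the minimal rotation
   between consecutive path tangents (discrete parallel transport), so the
   grid stays coherent around the arch. Defaults are 19 x 6 (18 x 6 for the
   aneurysm preset), matching the density at which this family of methods
   has been validated against 4D-flow MRI.

2. **RBF displacement field.** Control-point displacements from the
   reference grid (peak systole) to a target key-frame grid are interpolated
   to every wall vertex by a radial basis function with an affine polynomial
   term: per component, `d(x) = sum_k w_k phi(|x - x_k|) + c0 + C x`, solved
   from the symmetric augmented system with orthogonality side conditions.
   The default kernel is the cubic polyharmonic `phi(r) = r^3`; linear,
   thin-plate and Gaussian kernels are selectable. With zero smoothing the
   field interpolates the control points exactly, and the affine block
   reproduces translations, rotations and uniform scalings exactly — the
   key correctness anchors tested in the suite. Static regions (branch
   stubs) are pinned both by zero-displacement anchor points in the solve
   and a hard zero on static-labeled vertices.

3. **Temporal spline.** Per vertex and coordinate, a cubic smoothing spline
   (csaps convention, default `p = 0.999`) through the key-frame
   displacements is evaluated at the CFD step (default 1 ms). The aorta is
   held motionless during diastole: frames at or after the early-diastole
   key-frame carry its displacement unchanged, and phantom knots at `t = 0`
   and `t = T` with that same displacement close the cycle periodically.
   Because a spline is linear in its data, evaluation is a single
   `(n_frames x n_knots)` operator applied to all vertex columns at once.

## Control-point station modes

Plane stations can be placed two ways. `arclength` (the default) spaces
them uniformly along the path's arc length — the natural choice on a single
geometry. For *cross-frame correspondence* this is subtly wrong: a feet–head
root translation changes the path's arc length, so the same fractional
station cuts different material cross-sections on different key-frames; on
the synthetic phantom this alone costs ~20 % of peak displacement in
trajectory error. `parameter` mode spaces stations uniformly in the supplied
polyline's own parameterization; when the per-frame centerlines are sampled
at matched parameters (registered centerlines), plane `i` then cuts the same
material station on every frame. The pipeline uses `parameter` mode; with it
the phantom's trajectory is recovered with a median vertex error below 1 %
of the peak displacement.

## Kinematic diagnostics: the space conservation law

A moving-mesh (ALE) solver is only consistent if each control volume's rate
of change equals the sum of its face swept-volume fluxes. The package
verifies the surface-level analogue exactly: for linear per-step vertex
motion, each face sweeps a triangular prism whose signed volume is computed
as the sum of signed origin-tetrahedra over the prism's closed boundary.
Lateral quads are split along the diagonal anchored at the smaller global
vertex id, so the two prisms sharing an edge split their common quad
identically and the lateral contributions cancel over a closed surface.
The per-step residual `|V_{k+1} - V_k - sum_j dV_j|` is then pure round-off
(measured ~1e-19 m^3 against a tolerance of 1e-10 V). Open inlet/outlet
loops are capped by centroid fans for the check, with cap centroids moving
with their rings.

## Boundary conditions

* **Inlet.** Scattered 3-component velocity samples per MRI phase (~30–40 ms
  apart) are linearly interpolated in time to the CFD step; values at phase
  times are exact, and times beyond the last phase wrap toward phase 0 at
  `t = T`. The sample plane is rigidly registered onto the current
  (possibly moving) inlet: centroid to centroid, normal to normal by minimal
  rotation, and the velocity *vectors rotate with the plane* — this is what
  preserves through-plane volumetric flux under any rigid inlet motion
  (tested to 1e-10 relative). Projection onto the inlet nodes uses
  inverse-distance weighting (power 2, 8 nearest neighbors; `k = None`
  switches to all-sources mode, which the tests compare against a
  brute-force IDW oracle).
* **Outlets.** Per-outlet net flows are estimated by differencing the flux
  through planes bracketing each bifurcation (`Q_branch = Q_up - Q_down`).
  Fractions `w_n = Q_n / Q_i` are rescaled to `w_N = w_n / sum(w_n)`, which
  makes the fractions sum to one identically; retrograde (negative) flows
  stay signed and trigger a warning, because a negative fraction changes the
  meaning of an outflow boundary condition.
* **Export.** Profiles are written both as long-format CSV and as an
  s-expression transient-profile dialect with `%.9e` floats, with a bundled
  reader used for round-trip tests.

## Rheology and biomarkers

Blood is shear-thinning; the apparent viscosity follows the Carreau–Yasuda
law `mu = mu_inf + (mu_0 - mu_inf)[1 + (lambda gdot)^alpha]^((n-1)/alpha)`
with the whole-blood parameter set `mu_inf = 2.2 mPa s`, `mu_0 = 22 mPa s`,
`lambda = 0.110 s`, `alpha = 0.644`, `n = 0.392`, `rho = 1060 kg/m^3`. The
implementation handles `gdot = 0` and `gdot = inf` exactly and is verified
against a 30-digit independent evaluation at `gdot = 100 1/s`.

TAWSS is the cycle average of `|tau_w|`; OSI is
`(1 - |int tau_w dt| / int |tau_w| dt)/2`, clipped to `[0, 0.5]`, with nodes
whose shear magnitude integral is below 1e-30 Pa s flagged NaN rather than
crashing. Both use trapezoidal quadrature with an explicit periodic closing
segment from the last sample back to `t = T` using the first sample (the
literature leaves this unstated; with the closure, uniform sampling of
periodic signals integrates band-limited modes exactly). The
static-vs-dynamic comparison `dphi = (phi_s - phi_d)/(0.5(phi_s + phi_d)) x
100` is antisymmetric and bounded in `[-200, 200]`; the 0/0 case is defined
as 0. Dynamic maps are matched to the peak-systole surface by node identity,
valid because morphing never reorders vertices.

Reynolds numbers default to the infinite-shear viscosity (`Re = rho U D /
mu_inf`, `U = 4Q/(pi D^2)`); published aortic Re values rarely state which
viscosity was used, so the choice is an explicit argument.

## Preprocessing

Taubin smoothing with pass-band 0.1 and 100 iterations, using `lambda = 0.5`
and `mu = 1/(k_pb - 1/lambda) ~ -0.526` from the standard pass-band
relation. Boundary (opening) vertices are frozen so cut planes do not
drift. The suite verifies the band-pass property directly: on a noisy
sphere, volume changes < 2 % (fine mesh) while an equal-step pure-lambda
Laplacian shrinks it > 10 %. Note the low-frequency gain of the pass-band
exceeds 1 slightly, so very coarse meshes inflate measurably — a property of
the scheme, not a bug; the test pins it at realistic mesh density.

Subdivision is interpolating butterfly: classic 8-point stencil (w = 1/16)
on edges between two valence-6 vertices, and the modified valence-k stencil
(ring weights from `(1/4 + cos(2 pi j/k) + cos(4 pi j/k)/2)/k`, center 3/4)
where an endpoint is extraordinary — the classic stencil ripples there.
Boundary and incomplete-stencil edges fall back to the midpoint. An
octahedron (all valence 4) refines toward a smooth sphere-like limit; the
radius spread converges geometrically to ~0.095, and is *not* monotonically
decreasing — the limit surface is not a sphere, so the test asserts
convergence, not monotonicity.

Openings are cut by exact plane clipping (crossing triangles split at the
plane; the cut loop lies on the plane to round-off) and extended by
cylindrical extrusions sized by the equivalent diameter `D = 2 sqrt(A/pi)`
(defaults 5 D at outlets, 0.5 D at the inlet). Tet quality uses the
equilateral-volume-deviation skewness `1 - V/V_eq(R_circ)` with the
customary 0.9 re-meshing threshold; it is scale-invariant by construction.

## The synthetic phantom (what it does and does not emulate)

The phantom is a U-bend tube: ascending straight (7 cm), 180-degree arch
(radius 3 cm), descending straight (12 cm), base radius `R0` (1.49 cm
healthy, 1.58 cm aneurysm preset). Its motion combines the two dominant
components of aortic kinematics: radial compliance (`eps = 5 %`, consistent
with reported 1.7–3.6 mm diameter excursions) and a feet–head root
translation (`delta_fh = 9 mm`, the reported root excursion), both decaying
as `exp(-s/0.08 m)` along the arc length so the ascending aorta dominates
and the spine-braced descending aorta barely moves. The waveform is a
half-sine over systole (`t_sys = 0.35 s`) and exactly zero in diastole,
matching the diastolic-freeze modeling assumption; cycle lengths follow the
presets' heart rates (61 / 49 bpm). The aneurysm preset adds a Gaussian
radius bulge reaching a 50 mm diameter near the root. Because radial and
axial motion components are orthogonal at the root, the peak displacement
magnitude is `hypot(eps R0, delta_fh)` — not their sum.

Every generator is a pure function of `(params, seed)` and bitwise
reproducible. Ground truth (exact displacement fields, flow rates,
closed-form TAWSS/OSI) is returned alongside each dataset.

What the phantom does **not** emulate: segmentation error and
inter-observer variability, MRI noise structure beyond additive Gaussian
velocity noise (no VENC aliasing, no k-space effects), twist of the aortic
root, supra-aortic branch vessels, and any actual blood-flow physics. A
green recovery test therefore establishes that the morphing/spline chain is
numerically faithful to smooth kinematics at clinical control-point and
key-frame density — not that it is robust to segmentation artifacts.

## Numerical choices

* Internal unit meters; readers scale by `unit_scale` (default 1e-3,
  millimeter exports). Vertex merge tolerance 1e-9 m.
* RBF duplicate-center tolerance 1e-9 m; systems with condition number
  above 1e14 fall back to least squares with a warning.
* Ray casting accepts barycentric coordinates to 1e-9 (exact edge/vertex
  hits would otherwise be rejected by both adjacent triangles); among
  multiple hits the smallest positive ray parameter wins.
* Smoothing-spline `p` maps to the scipy objective via `lam = (1-p)/p`.
  At `p = 1` an interpolating not-a-knot cubic is used (the natural-BC
  limit of the smoothing spline cannot reproduce cubic polynomials, the
  not-a-knot spline can). Note `p` is unit-dependent, as in csaps: at
  second-scale knots and millimeter-scale displacements, `p = 0.999` is
  nearly lossless for smooth physiological waveforms but visibly smooths
  jagged data.
* Frame count `n = round(T/dt)`; frame 0 sits inside the diastolic hold and
  carries the held displacement exactly, making the sequence periodic to
  machine precision.
* Both-zero `dphi` defined as 0; OSI numerator/denominator share one
  quadrature rule.

## Known limitations

* `generate_control_points` assumes star-shaped cross-sections about the
  path (one positive hit per ray); highly eccentric lumens need manual
  extra points.
* Plane clipping expects a single intersection loop and raises otherwise;
  there is no self-intersection repair or hole filling.
* PLY I/O is ASCII-only; STL cannot carry region labels (warned).
* The transient-profile dialect is this package's own documented format,
  not a byte-level clone of any solver vendor's.
* Surface distances use a k-nearest-vertex candidate prefilter for
  point-to-surface projection; pathological meshes with huge faces adjacent
  to tiny ones could in principle miss the true nearest triangle.
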