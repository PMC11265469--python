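"""Triangulated-surface and tetrahedral-mesh data model with geometric primitives.

All coordinates are stored in meters (SI). Clinical segmentation exports are
typically millimeter STL, hence the ``unit_scale`` hook on the readers in
:mod:`aortamorph.io` (default ``1e-3``).

The :class:`TriSurface` is the unit of geometry exchange for the whole
pipeline: a labeled triangle mesh representing the vessel wall, its inlet and
outlet openings, and any static side-branch stubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

WALL = "wall"
STATIC = "static"
INLET = "inlet"

_LABEL_DTYPE = "<U32"


class TopologyError(ValueError):
    """Raised when a mesh does not satisfy a topological precondition."""


@dataclass
class Plane:
    """Oriented plane given by a point and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0 or not np.all(np.isfinite(n)):
            raise ValueError("plane normal must be a finite non-zero vector")
        self.normal = n / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of ``points`` (positive on the normal side)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.normal


@dataclass
class TriSurface:
    """Labeled triangulated surface at one phase of the cardiac cycle.

    Parameters
    ----------
    vertices : (n, 3) float array, meters.
    faces : (m, 3) int array of vertex indices.
    region_labels : (m,) str array; one of ``wall``, ``inlet``, ``outlet:<k>``,
        ``static`` (or any user tag). Defaults to all-``wall``.
    phase_time : time within the cardiac cycle in seconds, if known.
    openings : mapping label -> ordered boundary-loop vertex indices; populated
        by clipping / extension operations, not serialized.
    """

    vertices: np.ndarray
    faces: np.ndarray
    region_labels: np.ndarray | None = None
    phase_time: float | None = None
    openings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.region_labels is None:
            self.region_labels = np.full(len(self.faces), WALL, dtype=_LABEL_DTYPE)
        else:
            self.region_labels = np.asarray(self.region_labels, dtype=_LABEL_DTYPE)
            if self.region_labels.shape != (len(self.faces),):
                raise ValueError("region_labels must have one entry per face")

    # -- basic properties -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriSurface":
        return TriSurface(
            self.vertices.copy(),
            self.faces.copy(),
            self.region_labels.copy(),
            self.phase_time,
            {k: np.array(v) for k, v in self.openings.items()},
        )

    def validate(self, min_area: float = 1e-16) -> None:
        """Check the TriSurface invariants; raise ``ValueError`` on violation."""
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValueError("face index out of vertex range")
        _, areas = face_normals_areas(self, check_degenerate=False)
        bad = np.nonzero(areas <= min_area)[0]
        if bad.size:
            raise ValueError(f"{bad.size} degenerate (zero-area) faces, e.g. index {bad[0]}")

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    # -- topology ---------------------------------------------------------
    def edges_with_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique undirected edges and their face-incidence counts."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0, return_counts=True)

    def boundary_edge_count(self) -> int:
        _, counts = self.edges_with_counts()
        return int(np.sum(counts == 1))

    def is_closed(self) -> bool:
        return self.boundary_edge_count() == 0

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex loops of each open boundary.

        Directed boundary edges run opposite to the face winding, so the loops
        come out consistently oriented with respect to the surface.
        """
        directed = np.vstack(
            [self.faces[:, [1, 0]], self.faces[:, [2, 1]], self.faces[:, [0, 2]]]
        )
        und = np.sort(directed, axis=1)
        uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        bmask = counts[inv] == 1
        bedges = directed[bmask]
        nxt = {int(u): int(v) for u, v in bedges}
        loops: list[np.ndarray] = []
        seen: set[int] = set()
        for start in list(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt[start]
            while cur != start:
                loop.append(cur)
                seen.add(cur)
                cur = nxt.get(cur)
                if cur is None:  # non-manifold boundary; bail out
                    raise TopologyError("boundary is not a set of simple loops")
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    def vertex_labels(self) -> np.ndarray:
        """Per-vertex label: ``static`` iff every incident face is static."""
        lab = np.full(self.n_vertices, WALL, dtype=_LABEL_DTYPE)
        is_static_face = self.region_labels == STATIC
        touched = np.zeros(self.n_vertices, dtype=bool)
        nonstatic = np.zeros(self.n_vertices, dtype=bool)
        touched[self.faces.ravel()] = True
        nonstatic[self.faces[~is_static_face].ravel()] = True
        lab[touched & ~nonstatic] = STATIC
        return lab


@dataclass
class TetMesh:
    """Tetrahedral volume mesh with named boundary patches."""

    nodes: np.ndarray
    tets: np.ndarray
    boundary_patches: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (m, 4)")

    def signed_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def face_normals_areas(
    surface: TriSurface, check_degenerate: bool = True, area_tol: float = 1e-16
) -> tuple[np.ndarray, np.ndarray]:
    """Per-face unit normals (winding-consistent) and areas.

    Returns ``(normals, areas)``. With ``check_degenerate`` a ``ValueError``
    listing the offending face indices is raised for (near-)zero-area faces.
    """
    tri = surface.vertices[surface.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    if check_degenerate:
        bad = np.nonzero(areas <= area_tol)[0]
        if bad.size:
            raise ValueError(f"degenerate faces at indices {bad.tolist()[:20]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = np.where(areas[:, None] > 0, cross / (2.0 * areas[:, None]), 0.0)
    return normals, areas


def enclosed_volume(surface: TriSurface) -> float:
    """Volume enclosed by a closed, consistently oriented surface.

    Divergence-theorem sum of signed origin tetrahedra; the absolute value is
    returned so inward-oriented input still yields a positive volume.
    """
    nb = surface.boundary_edge_count()
    if nb:
        raise TopologyError(f"surface is not closed: {nb} boundary edges")
    tri = surface.vertices[surface.faces]
    vol = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    return float(abs(vol))


def label_regions(surface: TriSurface, planes: Sequence[tuple[Plane, str]]) -> TriSurface:
    """Label faces whose centroid lies on the positive (normal) side of a plane.

    Later planes override earlier ones; untouched faces keep ``wall``.
    """
    out = surface.copy()
    out.region_labels = np.full(out.n_faces, WALL, dtype=_LABEL_DTYPE)
    centroids = out.face_centroids()
    for plane, lab in planes:
        side = plane.signed_distance(centroids) > 0
        if not side.any():
            logger.warning("plane for label %r misses the surface; no faces labeled", lab)
            continue
        out.region_labels[side] = lab
    return out


def merge_duplicate_vertices(surface: TriSurface, tol: float = 1e-9) -> TriSurface:
    """Merge vertices closer than ``tol``; face count is preserved."""
    if surface.n_vertices == 0:
        return surface.copy()
    key = np.round(surface.vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = surface.vertices[first[order]]
    new_faces = rank[inverse][surface.faces]
    return TriSurface(new_vertices, new_faces, surface.region_labels.copy(), surface.phase_time)


def cap_opening(surface: TriSurface, loop: np.ndarray, label: str) -> TriSurface:
    """Close a boundary loop with a triangle fan about its centroid.

    The fan faces are labeled ``label``; orientation follows the loop
    direction returned by :meth:`TriSurface.boundary_loops`, which keeps the
    capped surface consistently oriented.
    """
    out = surface.copy()
    centroid = out.vertices[loop].mean(axis=0)
    ci = out.n_vertices
    out.vertices = np.vstack([out.vertices, centroid[None]])
    nxt = np.roll(loop, -1)
    fan = np.column_stack([loop, nxt, np.full(len(loop), ci)])
    out.faces = np.vstack([out.faces, fan])
    out.region_labels = np.concatenate(
        [out.region_labels, np.full(len(loop), label, dtype=_LABEL_DTYPE)]
    )
    return out


def cap_all_openings(surface: TriSurface, label: str = "cap") -> TriSurface:
    """Cap every boundary loop (used before volume / conservation checks)."""
    out = surface
    for i, loop in enumerate(surface.boundary_loops()):
        out = cap_opening(out, loop, f"{label}:{i}")
    return out
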